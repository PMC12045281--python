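import numpy as np
import pytest
from scipy import stats

from phyloprof.clustering import MPAConsensus
from phyloprof.profiles import EPOCH_RECENCY, Epoch, ideal_profiles
from phyloprof.significance import (
    CA_GRID,
    CD_GRID,
    ClusterEpochScores,
    SignificanceError,
    assign_epochs,
    calibrate_all_epochs,
    null_cd_exact,
    null_cd_threshold,
    qla_table,
    quality_level_agreement,
    sample_null_pm,
    score_clusters,
    select_nonredundant,
    strictness_grid,
)


class TestNullExact:
    def test_all_ones_ideal_is_plain_binomial(self):
        # k = L: every mismatch is a miss, so PM ~ Binomial(L, 1-q)
        pmf = null_cd_exact(10, 10, 0.5)
        assert pmf == pytest.approx(stats.binom.pmf(np.arange(11), 10, 0.5))
        assert pmf[:2].sum() == pytest.approx(11 / 1024)

    def test_all_zero_ideal_is_plain_binomial(self):
        pmf = null_cd_exact(4, 0, 0.25)
        assert pmf[0] == pytest.approx(0.75**4)

    def test_sums_to_one(self, rng):
        for _ in range(10):
            L = int(rng.integers(2, 200))
            k = int(rng.integers(0, L + 1))
            q = float(rng.uniform(0.05, 0.95))
            pmf = null_cd_exact(L, k, q)
            assert abs(pmf.sum() - 1.0) < 1e-12

    def test_mean_is_linear(self, rng):
        """E[PM] = k(1-q) + (L-k)q by linearity of expectation."""
        for _ in range(10):
            L = int(rng.integers(2, 150))
            k = int(rng.integers(0, L + 1))
            q = float(rng.uniform(0.05, 0.95))
            pmf = null_cd_exact(L, k, q)
            mean = float(pmf @ np.arange(L + 1))
            assert mean == pytest.approx(k * (1 - q) + (L - k) * q)

    def test_degenerate_q_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            pmf = null_cd_exact(5, 2, 0.0)
        assert pmf[2] == pytest.approx(1.0)  # point mass at the k misses


class TestNullThreshold:
    def test_bonferroni_level_exact(self):
        cal = null_cd_threshold(100, 10, 0.25, alpha=0.05, m_tests=5989)
        assert cal.alpha_per_test == 0.05 / 5989

    def test_hand_computed_boundary(self):
        # L=4, k=0, q=0.25: P(PM = 0) = 0.75^4 = 0.3164...
        cal = null_cd_threshold(4, 0, 0.25, alpha=0.3, m_tests=1)
        assert cal.threshold_count == -1  # even PM=0 is too likely
        cal = null_cd_threshold(4, 0, 0.25, alpha=0.32, m_tests=1)
        assert cal.threshold_count == 0

    def test_monte_carlo_matches_exact(self):
        exact = null_cd_threshold(50, 10, 0.25, alpha=0.01, m_tests=10)
        mc = null_cd_threshold(
            50, 10, 0.25, alpha=0.01, m_tests=10, method="montecarlo",
            n_draws=200_000, seed=0,
        )
        assert abs(mc.threshold_count - exact.threshold_count) <= 1

    def test_monte_carlo_resolution_guard(self):
        with pytest.raises(SignificanceError, match="resolution"):
            null_cd_threshold(
                50, 10, 0.25, alpha=0.05, m_tests=10_000,
                method="montecarlo", n_draws=1000,
            )

    def test_empirical_cdf_converges(self):
        """Kolmogorov distance between MC and exact CDFs is < 3/sqrt(n)."""
        L, k, q, n = 60, 20, 0.25, 100_000
        cdf = np.cumsum(null_cd_exact(L, k, q))
        counts = sample_null_pm(L, k, q, n, np.random.default_rng(1))
        ecdf = np.cumsum(counts) / n
        assert np.max(np.abs(ecdf - cdf)) < 3 / np.sqrt(n)


def _mc(cluster_id, member_ids, bits, L):
    bits = np.asarray(bits, dtype=np.uint8)
    mpa = np.tile(bits, (len(member_ids), 1))
    return MPAConsensus(cluster_id, tuple(member_ids), mpa, bits, 1.0)


class TestScoreClusters:
    @pytest.fixture
    def setup(self, toy_table):
        ideals = ideal_profiles(toy_table)
        cals = calibrate_all_epochs(ideals, q=0.4, alpha=0.05, m_tests=5)
        return ideals, cals

    def test_consensus_on_ideal_scores_zero(self, toy_table, setup):
        ideals, cals = setup
        mc = _mc("X", ["a", "b"], ideals[Epoch.SA], 11)
        (s,) = score_clusters([mc], ideals, cals)
        assert s.cd_by_epoch[Epoch.SA] == 0.0
        assert s.closest_epoch is Epoch.SA
        assert s.significant

    def test_all_ones_maps_to_fungi(self, toy_table, setup):
        ideals, cals = setup
        (s,) = score_clusters([_mc("X", ["a"], [1] * 11, 11)], ideals, cals)
        assert s.closest_epoch is Epoch.F
        assert s.cd_by_epoch[Epoch.F] == 0.0

    def test_tie_resolves_to_more_recent_epoch(self, toy_table, setup):
        ideals, cals = setup
        # ones over positions 0-7: one mismatch to Se (7 ones), one to A (9 ones)
        bits = [1] * 8 + [0] * 3
        (s,) = score_clusters([_mc("X", ["a"], bits, 11)], ideals, cals)
        assert s.cd_by_epoch[Epoch.SE] == s.cd_by_epoch[Epoch.A]
        assert s.closest_epoch is Epoch.SE

    def test_length_mismatch_rejected(self, toy_table, setup):
        ideals, cals = setup
        with pytest.raises(SignificanceError, match="length"):
            score_clusters([_mc("X", ["a"], [1, 0], 2)], ideals, cals)


def _scored(cluster_id, members, cd, ca=0.95, epoch=Epoch.SA, significant=True):
    cds = {e: cd if e is epoch else cd + 0.3 for e in EPOCH_RECENCY}
    return ClusterEpochScores(
        cluster_id=cluster_id,
        member_ids=tuple(members),
        ca=ca,
        consensus=np.zeros(10, dtype=np.uint8),
        cd_by_epoch=cds,
        closest_epoch=epoch,
        significant=significant,
    )


class TestSelectNonredundant:
    def test_cd_sorted_greedy_with_size_tie_break(self):
        x = _scored("X", [f"p{i}" for i in range(12)], 0.02)
        y = _scored("Y", ["p0"] + [f"q{i}" for i in range(7)], 0.02)
        z = _scored("Z", [f"r{i}" for i in range(20)], 0.05)
        kept = select_nonredundant([x, y, z])
        assert [s.cluster_id for s in kept] == ["X", "Z"]

    def test_disjoint_clusters_all_kept(self):
        clusters = [_scored(f"C{i}", [f"p{i}_{j}" for j in range(5)], 0.01 * i)
                    for i in range(6)]
        assert len(select_nonredundant(clusters)) == 6

    def test_overlap_chain_keeps_one_per_chain(self):
        # nested candidates sharing members: exactly one survivor
        chain = [
            _scored("A", ["p1", "p2", "p3", "p4"], 0.01),
            _scored("B", ["p3", "p4", "p5"], 0.02),
            _scored("C", ["p5", "p6"], 0.03),
        ]
        kept = select_nonredundant(chain)
        assert [s.cluster_id for s in kept] == ["A", "C"]

    def test_output_is_pairwise_disjoint(self, rng):
        clusters = []
        for i in range(40):
            members = rng.choice(60, size=rng.integers(2, 8), replace=False)
            clusters.append(
                _scored(f"C{i:02d}", [f"p{m}" for m in members],
                        float(rng.uniform(0, 0.2)), ca=float(rng.uniform(0.8, 1.0)))
            )
        kept = select_nonredundant(clusters)
        seen = set()
        for s in kept:
            assert not (set(s.member_ids) & seen)
            seen.update(s.member_ids)

    def test_invariant_to_input_order(self, rng):
        clusters = [
            _scored(f"C{i}", [f"p{i}_{j}" for j in range(3)] + [f"s{i % 3}"],
                    float(rng.uniform(0, 0.1)))
            for i in range(12)
        ]
        a = select_nonredundant(clusters)
        shuffled = list(clusters)
        rng.shuffle(shuffled)
        b = select_nonredundant(shuffled)
        assert [s.cluster_id for s in a] == [s.cluster_id for s in b]

    def test_nonsignificant_dropped(self):
        x = _scored("X", ["p1", "p2"], 0.01, significant=False)
        y = _scored("Y", ["p1", "p3"], 0.05)
        assert [s.cluster_id for s in select_nonredundant([x, y])] == ["Y"]

    def test_nonsignificant_can_block_during_scan(self):
        x = _scored("X", ["p1", "p2"], 0.01, significant=False)
        y = _scored("Y", ["p1", "p3"], 0.05)
        kept = select_nonredundant([x, y], nonsignificant="during")
        assert kept == []

    def test_literal_size_tie_break_mode(self):
        small = _scored("S", ["p1", "p2"], 0.0, ca=1.0)
        big = _scored("B", ["p1"] + [f"q{i}" for i in range(9)], 0.0, ca=0.9)
        kept = select_nonredundant([small, big], tie_break="size")
        assert [s.cluster_id for s in kept] == ["B"]


class TestAssignEpochs:
    def test_threshold_examples(self):
        c = _scored("X", ["p1", "p2"], 0.03, ca=0.96)
        assert len(assign_epochs([c], 0.95, 0.05).clusters) == 1
        assert len(assign_epochs([c], 0.99, 0.02).clusters) == 0

    def test_loose_thresholds_admit_superset(self, rng):
        clusters = [
            _scored(f"C{i}", [f"p{i}_{j}" for j in range(4)],
                    float(rng.uniform(0, 0.25)), ca=float(rng.uniform(0.75, 1.0)))
            for i in range(20)
        ]
        strict = set(assign_epochs(clusters, 0.99, 0.0).protein_to_epoch)
        loose = set(assign_epochs(clusters, 0.8, 0.2).protein_to_epoch)
        assert strict <= loose


class TestStrictnessGrid:
    def test_grid_has_35_cells(self):
        grid = strictness_grid([_scored("X", ["p1", "p2"], 0.01)])
        assert len(grid) == len(CA_GRID) * len(CD_GRID) == 35

    def test_populations_monotone_with_relaxation(self, rng):
        clusters = [
            _scored(f"C{i}", [f"p{i}_{j}" for j in range(rng.integers(2, 9))],
                    float(rng.uniform(0, 0.25)), ca=float(rng.uniform(0.75, 1.0)),
                    epoch=EPOCH_RECENCY[rng.integers(6)])
            for i in range(25)
        ]
        grid = strictness_grid(clusters)
        strictest = grid[(grid.ca_min == 0.99) & (grid.cd_max == 0.0)]
        loosest = grid[(grid.ca_min == 0.8) & (grid.cd_max == 0.2)]
        for e in EPOCH_RECENCY:
            assert loosest[e.value].iloc[0] >= strictest[e.value].iloc[0]

    def test_empty_selection_gives_zero_table(self):
        grid = strictness_grid([])
        assert (grid[[e.value for e in EPOCH_RECENCY]].to_numpy() == 0).all()


class TestQualityLevelAgreement:
    def test_partial_agreement(self):
        members = [f"p{i}" for i in range(10)]
        ref = assign_epochs([_scored("X", members, 0.01)], 0.9, 0.1, "HQ1")
        other = assign_epochs([_scored("X2", members[:9], 0.01)], 0.9, 0.1, "all")
        rec = quality_level_agreement(ref, other, "X")
        assert rec.qla == pytest.approx(0.9)

    def test_identical_assignments_give_one(self):
        members = [f"p{i}" for i in range(6)]
        ref = assign_epochs([_scored("X", members, 0.01)], 0.9, 0.1, "HQ1")
        other = assign_epochs([_scored("X", members, 0.01)], 0.9, 0.1, "HQ2")
        for rec in qla_table(ref, other):
            assert rec.qla == 1.0

    def test_no_overlap_gives_zero(self):
        ref = assign_epochs([_scored("X", ["p1", "p2"], 0.01)], 0.9, 0.1, "HQ1")
        other = assign_epochs([_scored("Y", ["q1", "q2"], 0.01)], 0.9, 0.1, "all")
        assert quality_level_agreement(ref, other, "X").qla == 0.0

    def test_unknown_cluster_rejected(self):
        ref = assign_epochs([_scored("X", ["p1", "p2"], 0.01)], 0.9, 0.1, "HQ1")
        with pytest.raises(SignificanceError, match="not assigned"):
            quality_level_agreement(ref, ref, "nope")
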