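from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from phyloprof.annotation_stats import (
    AnnotationError,
    AnnotationTable,
    TraitRecord,
    cluster_enrichment,
    epoch_trait_summary,
    hypergeom_test,
    idp_def,
    prionlike_call,
    read_annotation_table,
    read_trait_table,
    uyp_def,
    write_trait_table,
)
from phyloprof.profiles import EPOCH_RECENCY, Epoch
from phyloprof.significance import EpochAssignment


class TestHypergeomTest:
    def test_worked_example(self):
        # P(X >= 4) with N=20, K=5, n=5 = (C(5,4)C(15,1)+C(5,5)C(15,0))/C(20,5)
        p_enrich, _ = hypergeom_test(4, 5, 5, 20)
        assert p_enrich == float(Fraction(76, 15504))

    def test_degenerate_zero_term(self):
        p_enrich, p_deplete = hypergeom_test(0, 5, 0, 20)
        assert p_enrich == 1.0 and p_deplete == 1.0

    def test_whole_urn_boundary(self):
        p_enrich, p_deplete = hypergeom_test(5, 5, 5, 5)
        assert p_enrich == 1.0 and p_deplete == 1.0

    def test_matches_scipy_on_random_configurations(self, rng):
        """Independent oracle: scipy's hypergeometric tails, all N <= 25."""
        for _ in range(300):
            N = int(rng.integers(1, 26))
            n = int(rng.integers(0, N + 1))
            K = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            p_enrich, p_deplete = hypergeom_test(k, n, K, N)
            assert p_enrich == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), abs=1e-12
            )
            assert p_deplete == pytest.approx(
                stats.hypergeom.cdf(k, N, K, n), abs=1e-12
            )

    def test_tail_overlap_identity(self, rng):
        """p_enrich + p_deplete = 1 + P(X = k) exactly."""
        for _ in range(50):
            N = int(rng.integers(2, 26))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            p_enrich, p_deplete = hypergeom_test(k, n, K, N)
            pmf = stats.hypergeom.pmf(k, N, K, n)
            assert p_enrich + p_deplete == pytest.approx(1.0 + pmf, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(AnnotationError):
            hypergeom_test(6, 5, 10, 20)
        with pytest.raises(AnnotationError):
            hypergeom_test(2, 5, 1, 20)


class TestClusterEnrichment:
    def _table(self, n_bg=100, k_term=10, term="T", extra_terms=()):
        background = [f"p{i}" for i in range(n_bg)]
        ann = {f"p{i}": {term} for i in range(k_term)}
        for t in extra_terms:
            ann.setdefault("p0", set()).add(t)
        return AnnotationTable(
            {p: frozenset(ts) for p, ts in ann.items()}, frozenset(background)
        )

    def test_strong_enrichment_detected(self):
        table = self._table()
        members = [f"p{i}" for i in range(8)] + ["p50", "p51"]  # 8 of 10 carriers
        (res,) = cluster_enrichment("X", members, table)
        assert res.direction == "enriched"
        assert res.significant
        assert res.p_enrich < 1e-5

    def test_no_annotations_gives_empty_result(self):
        table = AnnotationTable({}, frozenset({"p1", "p2"}))
        assert cluster_enrichment("X", ["p1"], table) == []

    def test_bonferroni_scales_with_terms(self):
        one = self._table()
        two = self._table(extra_terms=("U",))
        members = [f"p{i}" for i in range(8)] + ["p50", "p51"]
        r1 = cluster_enrichment("X", members, one)[0]
        r2 = [r for r in cluster_enrichment("X", members, two) if r.term == "T"][0]
        assert r2.p_bonferroni == pytest.approx(min(1.0, 2 * r1.p_bonferroni))

    def test_member_outside_background_rejected(self):
        with pytest.raises(AnnotationError, match="missing from background"):
            cluster_enrichment("X", ["stranger"], self._table())

    def test_depletion_direction_reported(self):
        table = self._table(n_bg=20, k_term=15)
        res = cluster_enrichment("X", [f"p{i}" for i in range(15, 20)], table)
        assert res[0].direction == "depleted"


class TestPrionlikeCall:
    def test_fraction_thresholds_inclusive(self):
        scores = [(20.0, None)] * 8 + [(1.0, None)] * 2
        assert prionlike_call(scores, 15.0, 0.8)
        assert not prionlike_call(scores, 15.0, 0.9)
        nine = [(20.0, None)] * 9 + [(1.0, None)]
        assert prionlike_call(nine, 15.0, 0.9)

    def test_llr_fallback_when_prd_missing(self):
        scores = [(None, 20.0)] * 9 + [(1.0, None)]
        assert prionlike_call(scores, 15.0, 0.8)

    def test_strict_zero_threshold(self):
        scores = [(0.0, None)] * 10
        assert prionlike_call(scores, 0.0, 0.8)  # inclusive >= passes at 0
        assert not prionlike_call(scores, 0.0, 0.8, strict=True)

    def test_empty_scores_rejected(self):
        with pytest.raises(AnnotationError):
            prionlike_call([], 15.0, 0.8)


def _assignment(mapping):
    from phyloprof.significance import ClusterEpochScores

    clusters = []
    p2e, p2c = {}, {}
    for cid, (epoch, members) in mapping.items():
        clusters.append(
            ClusterEpochScores(
                cluster_id=cid,
                member_ids=tuple(members),
                ca=1.0,
                consensus=np.zeros(4, dtype=np.uint8),
                cd_by_epoch={e: 0.0 for e in EPOCH_RECENCY},
                closest_epoch=epoch,
                significant=True,
            )
        )
        for m in members:
            p2e[m] = epoch
            p2c[m] = cid
    return EpochAssignment("all", 0.9, 0.1, tuple(clusters), p2e, p2c)


def _trait(pid, disorder):
    return TraitRecord(pid, ((20.0, None),), disorder, {1e-2: False, 1e-3: True})


class TestEpochTraitSummary:
    def test_proportions_counted(self):
        assignment = _assignment({"X": (Epoch.SA, [f"p{i}" for i in range(10)])})
        traits = {f"p{i}": _trait(f"p{i}", 0.6 if i < 3 else 0.1) for i in range(10)}
        rows = epoch_trait_summary(assignment, traits, idp_def(0.5))
        sa = next(r for r in rows if r.epoch is Epoch.SA)
        assert sa.population == 10
        assert sa.proportion == pytest.approx(0.3)

    def test_empty_epoch_has_missing_proportion(self):
        assignment = _assignment({"X": (Epoch.SA, ["p0"])})
        rows = epoch_trait_summary(assignment, {"p0": _trait("p0", 0.1)}, idp_def(0.5))
        fungi = next(r for r in rows if r.epoch is Epoch.F)
        assert fungi.population == 0 and fungi.proportion is None

    def test_idp_thresholds_nested(self, rng):
        members = [f"p{i}" for i in range(30)]
        assignment = _assignment({"X": (Epoch.SE, members)})
        traits = {p: _trait(p, float(rng.uniform(0, 1))) for p in members}
        loose = epoch_trait_summary(assignment, traits, idp_def(0.2))
        tight = epoch_trait_summary(assignment, traits, idp_def(0.5))
        for lo, hi in zip(tight, loose):
            if lo.proportion is not None:
                assert hi.proportion >= lo.proportion

    def test_uyp_trait_uses_threshold_flag(self):
        assignment = _assignment({"X": (Epoch.SC, ["p0", "p1"])})
        traits = {p: _trait(p, 0.1) for p in ["p0", "p1"]}
        rows = epoch_trait_summary(assignment, traits, uyp_def(1e-3))
        sc = next(r for r in rows if r.epoch is Epoch.SC)
        assert sc.proportion == 1.0

    def test_missing_records_excluded_from_denominator(self):
        assignment = _assignment({"X": (Epoch.SA, ["p0", "p1", "p2"])})
        traits = {"p0": _trait("p0", 0.6)}
        rows = epoch_trait_summary(assignment, traits, idp_def(0.5))
        sa = next(r for r in rows if r.epoch is Epoch.SA)
        assert sa.population == 3 and sa.n_with_data == 1 and sa.proportion == 1.0


class TestIO:
    def test_trait_table_round_trip(self, tmp_path):
        recs = [
            TraitRecord("p0", ((20.0, None), (None, 12.5)), 0.25,
                        {1e-2: False, 1e-3: True}),
            TraitRecord("p1", (), None, {}),
        ]
        path = tmp_path / "traits.tsv"
        write_trait_table(recs, path)
        back = read_trait_table(path)
        assert back["p0"].prion_scores == ((20.0, None), (None, 12.5))
        assert back["p0"].disorder_fraction == 0.25
        assert back["p0"].uyp == {1e-2: False, 1e-3: True}
        assert back["p1"].disorder_fraction is None

    def test_annotation_table_reader(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("p0\tGO:1\np0\tGO:2\np1\tGO:1\n")
        table = read_annotation_table(path, ["p0", "p1", "p2"])
        assert table.terms("p0") == {"GO:1", "GO:2"}
        assert table.term_universe() == ["GO:1", "GO:2"]
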