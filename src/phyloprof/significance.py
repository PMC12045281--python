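"""Null calibration of consensus distances, redundancy removal, epoch assignment.

The consensus distance (CD) of a cluster is the PM fraction between its
consensus profile and an ideal epoch profile.  To decide which CD values
are small enough to mean anything, the null distribution of CD is taken
over random profiles with the same overall proportion of 1s as the
observed matrix: the mismatch count between an iid Bernoulli(q) profile
and an ideal profile with k ones is the sum of two binomials,

    PM ~ Binomial(k, 1 - q) + Binomial(L - k, q),

available exactly by convolution or empirically by Monte Carlo.  The
significance threshold is the largest CD whose null probability of being
reached is at most a Bonferroni-corrected level alpha / m_tests.

Significant clusters are then sorted on increasing CD (ties: decreasing
size) and greedily selected so that no two selected clusters share a
member.  Each selected cluster is assigned to its closest ideal profile;
stricter (CA, CD) thresholds produce stricter protein-to-epoch maps, and
quality-level agreement (QLA) measures how reproducible a cluster's
assignment is when the analysis is repeated on a different proteome-quality
panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .clustering import MPAConsensus
from .profiles import EPOCH_RECENCY, Epoch, IdealProfileSet


class SignificanceError(ValueError):
    """Raised for invalid calibration or assignment inputs."""


#: strictness grids for (CA minimum, CD maximum) assignment thresholds
CA_GRID: tuple[float, ...] = (0.99, 0.98, 0.95, 0.9, 0.8)
CD_GRID: tuple[float, ...] = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)

_EPS = 1e-12  # tolerance for threshold comparisons on exact rationals


def null_cd_exact(L: int, k: int, q: float) -> np.ndarray:
    """Exact pmf (length L+1) of the null mismatch count to a k-ones ideal.

    Mismatches at the k ideal-1 positions are misses, Binomial(k, 1-q);
    mismatches at the L-k ideal-0 positions are spurious 1s,
    Binomial(L-k, q).  Their convolution is the PM distribution.
    """
    if not (0 <= k <= L):
        raise SignificanceError(f"need 0 <= k <= L, got k={k}, L={L}")
    if not (0.0 <= q <= 1.0):
        raise SignificanceError(f"q must be a probability, got {q}")
    if q in (0.0, 1.0):
        warnings.warn(
            f"degenerate background q={q}: null distribution is a point mass",
            stacklevel=2,
        )
    a = stats.binom.pmf(np.arange(k + 1), k, 1.0 - q)
    b = stats.binom.pmf(np.arange(L - k + 1), L - k, q)
    pmf = np.convolve(a, b)
    assert pmf.shape == (L + 1,)
    return pmf


def sample_null_pm(
    L: int, k: int, q: float, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Counts-of-counts (length L+1) of PM over n_draws random profiles."""
    counts = np.zeros(L + 1, dtype=np.int64)
    chunk = max(1, min(n_draws, 20_000_000 // max(L, 1)))
    remaining = n_draws
    while remaining > 0:
        c = min(chunk, remaining)
        bits = rng.random((c, L)) < q
        pm = (~bits[:, :k]).sum(axis=1) + bits[:, k:].sum(axis=1)
        counts += np.bincount(pm, minlength=L + 1)
        remaining -= c
    return counts


@dataclass(frozen=True)
class NullCalibration:
    """Per-epoch significance threshold for consensus distances."""

    epoch: Optional[Epoch]
    L: int
    k: int
    q: float
    alpha_per_test: float
    threshold_count: int  # significant iff PM count <= this; -1 = nothing passes
    method: str  # "exact" or "montecarlo"
    n_draws: Optional[int] = None
    seed: Optional[int] = None

    @property
    def threshold_cd(self) -> float:
        """Threshold as a PM fraction of the profile length."""
        return self.threshold_count / self.L


def null_cd_threshold(
    L: int,
    k: int,
    q: float,
    alpha: float,
    m_tests: int,
    method: str = "exact",
    n_draws: int = 1_000_000,
    seed: Optional[int] = None,
    epoch: Optional[Epoch] = None,
) -> NullCalibration:
    """Largest CD whose null probability of being reached is <= alpha/m_tests.

    ``method="exact"`` uses the binomial convolution; ``"montecarlo"`` draws
    ``n_draws`` seeded random profiles.  Monte Carlo refuses per-test levels
    below its 1/n_draws resolution.
    """
    if not (0.0 < alpha < 1.0):
        raise SignificanceError(f"alpha must be in (0, 1), got {alpha}")
    if m_tests < 1:
        raise SignificanceError(f"m_tests must be >= 1, got {m_tests}")
    alpha_per_test = alpha / m_tests
    if alpha_per_test >= 1.0:
        return NullCalibration(epoch, L, k, q, alpha_per_test, L, method)
    if method == "exact":
        cdf = np.cumsum(null_cd_exact(L, k, q))
        passing = np.nonzero(cdf <= alpha_per_test + _EPS)[0]
        threshold_count = int(passing[-1]) if passing.size else -1
        return NullCalibration(epoch, L, k, q, alpha_per_test, threshold_count, "exact")
    if method == "montecarlo":
        if alpha_per_test < 1.0 / n_draws:
            raise SignificanceError(
                f"alpha_per_test={alpha_per_test:g} is below the Monte Carlo "
                f"resolution 1/{n_draws}; use method='exact' or more draws"
            )
        rng = np.random.default_rng(seed)
        counts = sample_null_pm(L, k, q, n_draws, rng)
        ecdf = np.cumsum(counts) / n_draws
        passing = np.nonzero(ecdf <= alpha_per_test)[0]
        threshold_count = int(passing[-1]) if passing.size else -1
        return NullCalibration(
            epoch, L, k, q, alpha_per_test, threshold_count, "montecarlo", n_draws, seed
        )
    raise SignificanceError(f"unknown method {method!r}")


def calibrate_all_epochs(
    ideals: IdealProfileSet,
    q: float,
    alpha: float,
    m_tests: int,
    method: str = "exact",
    n_draws: int = 1_000_000,
    seed: Optional[int] = None,
) -> dict:
    """One :class:`NullCalibration` per epoch for a given panel and background."""
    L = len(ideals.species)
    out = {}
    for i, (epoch, bits) in enumerate(ideals.items()):
        sub = None if seed is None else seed + i
        out[epoch] = null_cd_threshold(
            L, int(bits.sum()), q, alpha, m_tests, method, n_draws, sub, epoch
        )
    return out


@dataclass(frozen=True)
class ClusterEpochScores:
    """CD of one cluster's consensus to every ideal profile, plus verdicts."""

    cluster_id: str
    member_ids: tuple[str, ...]
    ca: float
    consensus: np.ndarray
    cd_by_epoch: dict
    closest_epoch: Epoch
    significant: bool

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def closest_cd(self) -> float:
        return self.cd_by_epoch[self.closest_epoch]

    @property
    def min_cd(self) -> float:
        return min(self.cd_by_epoch.values())


def score_clusters(
    consensi: Sequence[MPAConsensus],
    ideals: IdealProfileSet,
    calibrations: dict,
) -> list[ClusterEpochScores]:
    """CD to each ideal, closest epoch (ties to the more recent), significance.

    A cluster is significant when its CD at the closest epoch is at or below
    that epoch's calibrated threshold.
    """
    for epoch in EPOCH_RECENCY:
        if epoch not in calibrations:
            raise SignificanceError(f"missing calibration for epoch {epoch.value}")
    L = len(ideals.species)
    scored = []
    for mc in consensi:
        if mc.consensus.shape[0] != L:
            raise SignificanceError(
                f"cluster {mc.cluster_id}: consensus length {mc.consensus.shape[0]} "
                f"!= ideal profile length {L}"
            )
        counts = {
            epoch: int(np.count_nonzero(mc.consensus != bits))
            for epoch, bits in ideals.items()
        }
        # argmin scanning in recency order: ties resolve to the more recent epoch
        closest = EPOCH_RECENCY[0]
        for epoch in EPOCH_RECENCY[1:]:
            if counts[epoch] < counts[closest]:
                closest = epoch
        significant = counts[closest] <= calibrations[closest].threshold_count
        scored.append(
            ClusterEpochScores(
                cluster_id=mc.cluster_id,
                member_ids=mc.member_ids,
                ca=mc.ca,
                consensus=mc.consensus,
                cd_by_epoch={e: c / L for e, c in counts.items()},
                closest_epoch=closest,
                significant=significant,
            )
        )
    return scored


def select_nonredundant(
    scored: Iterable[ClusterEpochScores],
    nonsignificant: str = "before",
    tie_break: str = "coherence",
) -> list[ClusterEpochScores]:
    """Greedy redundancy removal over CD-sorted clusters.

    Clusters are sorted on increasing minimum CD over the ideals and the
    sorted list is scanned: a cluster is kept only if it shares no member
    with any cluster already kept.  ``nonsignificant="before"`` (default)
    drops non-significant clusters before the scan; ``"during"`` lets them
    block overlapping clusters further down the list but excludes them
    from the output.

    Equal-CD ties are resolved by ``tie_break``:

    * ``"coherence"`` (default): higher size-adjusted consensus agreement
      first (CA shrunk by ``0.1 / sqrt(size)``), then larger size.  With
      candidates drawn from *both* sides of every tree bipartition, large
      heterogeneous sides that mix several epochs can reach CD = 0 exactly
      (the positionwise majority of a mixture lands on an ideal profile);
      preferring coherent clusters at CD ties stops such mixtures from
      absorbing the members of the tight clusters inside them, while the
      small-sample shrinkage stops 2-3-member fragments with a perfect CA
      from fragmenting large coherent clusters.
    * ``"size"``: larger clusters first -- the literal redundancy-removal
      ordering, appropriate when candidates are already clade-like.

    Both orderings end with cluster_id, so the selection is total-order
    deterministic and invariant to input order.
    """
    if nonsignificant not in ("before", "during"):
        raise SignificanceError("nonsignificant must be 'before' or 'during'")
    pool = list(scored)
    if nonsignificant == "before":
        pool = [s for s in pool if s.significant]
    if tie_break == "coherence":
        pool.sort(
            key=lambda s: (
                s.min_cd,
                -(s.ca - 0.1 / math.sqrt(s.size)),
                -s.size,
                s.cluster_id,
            )
        )
    elif tie_break == "size":
        pool.sort(key=lambda s: (s.min_cd, -s.size, s.cluster_id))
    else:
        raise SignificanceError("tie_break must be 'coherence' or 'size'")
    taken: set[str] = set()
    kept = []
    for s in pool:
        if any(p in taken for p in s.member_ids):
            continue
        taken.update(s.member_ids)
        if s.significant:
            kept.append(s)
    return kept


@dataclass(frozen=True)
class EpochAssignment:
    """Protein-to-epoch map at one quality level and strictness."""

    quality_level: str
    ca_min: float
    cd_max: float
    clusters: tuple[ClusterEpochScores, ...]
    protein_to_epoch: dict
    protein_to_cluster: dict

    def epoch_populations(self) -> dict:
        pops = {e: 0 for e in EPOCH_RECENCY}
        for c in self.clusters:
            pops[c.closest_epoch] += c.size
        return pops


def assign_epochs(
    selection: Sequence[ClusterEpochScores],
    ca_min: float,
    cd_max: float,
    quality_level: str = "all",
    min_size: int = 1,
) -> EpochAssignment:
    """Keep selected clusters with CA >= ca_min and closest CD <= cd_max."""
    clusters = tuple(
        s
        for s in selection
        if s.ca >= ca_min - _EPS and s.closest_cd <= cd_max + _EPS and s.size >= min_size
    )
    p2e: dict[str, Epoch] = {}
    p2c: dict[str, str] = {}
    for s in clusters:
        for pid in s.member_ids:
            if pid in p2e:
                raise SignificanceError(
                    f"protein {pid} in two selected clusters; selection not disjoint"
                )
            p2e[pid] = s.closest_epoch
            p2c[pid] = s.cluster_id
    return EpochAssignment(quality_level, ca_min, cd_max, clusters, p2e, p2c)


def strictness_grid(
    selection: Sequence[ClusterEpochScores],
    quality_level: str = "all",
    ca_grid: Sequence[float] = CA_GRID,
    cd_grid: Sequence[float] = CD_GRID,
    min_size: int = 1,
):
    """Per-epoch protein populations over the full (ca_min, cd_max) grid.

    Returns a pandas DataFrame with one row per grid cell (35 by default).
    """
    import pandas as pd

    rows = []
    for ca_min in ca_grid:
        for cd_max in cd_grid:
            assignment = assign_epochs(selection, ca_min, cd_max, quality_level, min_size)
            pops = assignment.epoch_populations()
            row = {"quality_level": quality_level, "ca_min": ca_min, "cd_max": cd_max}
            row.update({e.value: pops[e] for e in EPOCH_RECENCY})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QLARecord:
    """Cross-quality-level agreement for one cluster."""

    cluster_id: str
    reference_level: str
    other_level: str
    epoch: Epoch
    size: int
    qla: float


def quality_level_agreement(
    assign_ref: EpochAssignment, assign_other: EpochAssignment, cluster_id: str
) -> QLARecord:
    """Fraction of a reference cluster's members assigned to the same epoch
    at the other quality level.

    Members unassigned at the other level count as disagreements: agreement
    requires a significant assignment to the same closest ideal profile.
    """
    target = None
    for c in assign_ref.clusters:
        if c.cluster_id == cluster_id:
            target = c
            break
    if target is None:
        raise SignificanceError(
            f"cluster {cluster_id!r} not assigned at reference level "
            f"{assign_ref.quality_level!r}"
        )
    agree = sum(
        1
        for pid in target.member_ids
        if assign_other.protein_to_epoch.get(pid) == target.closest_epoch
    )
    return QLARecord(
        cluster_id=cluster_id,
        reference_level=assign_ref.quality_level,
        other_level=assign_other.quality_level,
        epoch=target.closest_epoch,
        size=target.size,
        qla=agree / target.size,
    )


def qla_table(
    assign_ref: EpochAssignment, assign_other: EpochAssignment
) -> list[QLARecord]:
    """QLA for every cluster assigned at the reference level."""
    return [
        quality_level_agreement(assign_ref, assign_other, c.cluster_id)
        for c in assign_ref.clusters
    ]
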