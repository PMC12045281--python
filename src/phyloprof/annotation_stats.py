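"""Hypergeometric GO enrichment for clusters and epoch-wise trait summaries.

Functional enrichment of a profile cluster is tested against the whole
focal proteome: for a GO term annotated to K of N background proteins and
k of the cluster's n members, the enrichment p-value is the upper
hypergeometric tail P(X >= k) and the depletion p-value the lower tail
P(X <= k), Bonferroni-corrected for the number of terms examined.  Tail
probabilities are computed by exact integer summation (no floating-point
cancellation), so they agree with brute-force enumeration to machine
precision.

Trait aggregation summarises, per assigned epoch, the proportion of
proteins that are prion-like (PLAAC-style PRD/LLR composition scores over
an ortholog set), intrinsically disordered (precomputed disorder
fraction), or "unique" (no non-self hit at a given e-value threshold).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

from .profiles import EPOCH_RECENCY, Epoch
from .significance import EpochAssignment

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for inconsistent annotation or trait inputs."""


def hypergeom_test(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities (enrichment, depletion).

    Drawing n from an urn of N with K successes: returns
    ``(P(X >= k), P(X <= k))``.  Exact integer arithmetic throughout.
    """
    if not (0 <= k <= n <= N):
        raise AnnotationError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise AnnotationError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    if n - k > N - K:
        raise AnnotationError(
            f"impossible counts: {n - k} non-carriers drawn but only {N - K} exist"
        )
    denom = comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(n, K)
    upper = sum(comb(K, i) * comb(N - K, n - i) for i in range(max(k, lo), hi + 1))
    lower = sum(comb(K, i) * comb(N - K, n - i) for i in range(lo, min(k, hi) + 1))
    return float(Fraction(upper, denom)), float(Fraction(lower, denom))


@dataclass(frozen=True)
class AnnotationTable:
    """Protein -> GO term sets over a fixed background proteome."""

    annotations: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self):
        stray = set(self.annotations) - set(self.background)
        if stray:
            raise AnnotationError(
                f"annotated proteins outside the background: {sorted(stray)[:5]}"
            )

    def terms(self, protein_id: str) -> frozenset:
        return self.annotations.get(protein_id, frozenset())

    def term_universe(self) -> list[str]:
        """Terms with at least one background annotation, sorted."""
        universe: set[str] = set()
        for terms in self.annotations.values():
            universe |= terms
        return sorted(universe)


def read_annotation_table(path, background: Iterable[str]) -> AnnotationTable:
    """Two-column TSV (protein_id, term); proteins outside background rejected."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}: line {lineno}: expected 2 columns")
            ann.setdefault(fields[0], set()).add(fields[1])
    return AnnotationTable(
        {p: frozenset(t) for p, t in ann.items()}, frozenset(background)
    )


def read_gaf(path, background: Iterable[str]) -> AnnotationTable:
    """GAF 2.x reader using the DB-object-id and GO-id columns (2 and 5)."""
    ann: dict[str, set[str]] = {}
    bg = frozenset(background)
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            pid, term = fields[1], fields[4]
            if pid in bg:
                ann.setdefault(pid, set()).add(term)
    return AnnotationTable({p: frozenset(t) for p, t in ann.items()}, bg)


@dataclass(frozen=True)
class EnrichmentResult:
    """One (cluster, term) hypergeometric test in both directions."""

    cluster_id: str
    term: str
    k: int
    n: int
    K: int
    N: int
    p_enrich: float
    p_deplete: float
    direction: str  # "enriched" or "depleted", whichever tail is smaller
    p_bonferroni: float
    significant: bool


def cluster_enrichment(
    cluster_id: str,
    members: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 background annotation, Bonferroni-corrected.

    Both enrichment and depletion are examined; the reported direction and
    corrected p-value follow the smaller tail.  The correction factor is
    the number of terms tested.
    """
    member_set = set(members)
    missing = member_set - set(annotations.background)
    if missing:
        raise AnnotationError(
            f"cluster {cluster_id}: members missing from background: "
            f"{sorted(missing)[:5]}"
        )
    terms = annotations.term_universe()
    if not terms:
        return []
    N = len(annotations.background)
    n = len(member_set)
    term_bg: dict[str, int] = {t: 0 for t in terms}
    term_in: dict[str, int] = {t: 0 for t in terms}
    for pid in annotations.background:
        for t in annotations.terms(pid):
            term_bg[t] += 1
            if pid in member_set:
                term_in[t] += 1
    m_terms = len(terms)
    results = []
    for t in terms:
        p_enrich, p_deplete = hypergeom_test(term_in[t], n, term_bg[t], N)
        p = min(p_enrich, p_deplete)
        p_bonf = min(1.0, p * m_terms)
        results.append(
            EnrichmentResult(
                cluster_id=cluster_id,
                term=t,
                k=term_in[t],
                n=n,
                K=term_bg[t],
                N=N,
                p_enrich=p_enrich,
                p_deplete=p_deplete,
                direction="enriched" if p_enrich <= p_deplete else "depleted",
                p_bonferroni=p_bonf,
                significant=p_bonf <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.term))
    return results


# ---------------------------------------------------------------------------
# Traits


@dataclass(frozen=True)
class TraitRecord:
    """Per-protein trait data consumed from upstream predictors.

    ``prion_scores`` holds one (PRD, LLR) tuple per ortholog in the
    protein's ortholog set (either component may be None); ``uyp`` maps
    e-value thresholds to uniqueness flags.
    """

    protein_id: str
    prion_scores: tuple
    disorder_fraction: Optional[float]
    uyp: Mapping[float, bool]

    def __post_init__(self):
        if self.disorder_fraction is not None and not (
            0.0 <= self.disorder_fraction <= 1.0
        ):
            raise AnnotationError(
                f"disorder_fraction {self.disorder_fraction} out of [0, 1] "
                f"for {self.protein_id}"
            )


def prionlike_call(
    scores: Sequence[tuple],
    score_min: float,
    frac_min: float,
    strict: bool = False,
) -> bool:
    """Is a protein prion-like across its ortholog set?

    Each ortholog contributes its PRD score when present, failing that its
    LLR score.  The call is true when the fraction of orthologs whose score
    passes ``score_min`` (``>=`` by default, ``>`` when ``strict``) reaches
    ``frac_min``.  The focal protein's own score is one of the orthologs.
    """
    if not scores:
        raise AnnotationError("prionlike_call requires at least one ortholog score")
    passing = 0
    for prd, llr in scores:
        s = prd if prd is not None else llr
        if s is None:
            continue
        if (s > score_min) if strict else (s >= score_min):
            passing += 1
    return passing / len(scores) >= frac_min


@dataclass(frozen=True)
class TraitDef:
    """A named trait definition used for epoch-wise aggregation."""

    kind: str  # "prion", "idp" or "uyp"
    params: tuple

    @property
    def name(self) -> str:
        if self.kind == "prion":
            score_min, frac_min, strict = self.params
            op = ">" if strict else ">="
            return f"prion({op}{score_min:g},frac>={frac_min:g})"
        if self.kind == "idp":
            return f"idp(>={self.params[0]:g})"
        return f"uyp({self.params[0]:g})"

    def evaluate(self, rec: TraitRecord) -> Optional[bool]:
        """Trait flag for one protein; None when the needed data is missing."""
        if self.kind == "prion":
            score_min, frac_min, strict = self.params
            if not rec.prion_scores:
                return None
            return prionlike_call(rec.prion_scores, score_min, frac_min, strict)
        if self.kind == "idp":
            if rec.disorder_fraction is None:
                return None
            return rec.disorder_fraction >= self.params[0]
        if self.kind == "uyp":
            return rec.uyp.get(self.params[0])
        raise AnnotationError(f"unknown trait kind {self.kind!r}")


def prion_def(score_min: float, frac_min: float, strict: bool = False) -> TraitDef:
    return TraitDef("prion", (score_min, frac_min, strict))


def idp_def(min_fraction: float) -> TraitDef:
    return TraitDef("idp", (min_fraction,))


def uyp_def(threshold: float) -> TraitDef:
    return TraitDef("uyp", (threshold,))


#: trait definitions matching the standard analysis panels
STANDARD_TRAIT_DEFS: tuple[TraitDef, ...] = (
    prion_def(0.0, 0.8, strict=True),
    prion_def(15.0, 0.8),
    prion_def(15.0, 0.9),
    idp_def(0.5),
    idp_def(0.2),
    uyp_def(1e-2),
    uyp_def(1e-3),
)


@dataclass(frozen=True)
class EpochTraitSummary:
    """Population size and trait proportion for one epoch at one strictness."""

    epoch: Epoch
    quality_level: str
    ca_min: float
    cd_max: float
    trait: str
    population: int
    n_with_data: int
    proportion: Optional[float]


def epoch_trait_summary(
    assignment: EpochAssignment,
    traits: Mapping[str, TraitRecord],
    trait_def: TraitDef,
) -> list[EpochTraitSummary]:
    """Per-epoch proportion of assigned proteins carrying a trait.

    Proteins without usable trait data are excluded from the proportion's
    denominator (their count is logged); an empty epoch yields a missing
    proportion.
    """
    rows = []
    missing_total = 0
    by_epoch: dict[Epoch, list[str]] = {e: [] for e in EPOCH_RECENCY}
    for pid, epoch in assignment.protein_to_epoch.items():
        by_epoch[epoch].append(pid)
    for epoch in EPOCH_RECENCY:
        pids = by_epoch[epoch]
        flags = []
        for pid in pids:
            rec = traits.get(pid)
            flag = trait_def.evaluate(rec) if rec is not None else None
            if flag is None:
                missing_total += 1
            else:
                flags.append(flag)
        rows.append(
            EpochTraitSummary(
                epoch=epoch,
                quality_level=assignment.quality_level,
                ca_min=assignment.ca_min,
                cd_max=assignment.cd_max,
                trait=trait_def.name,
                population=len(pids),
                n_with_data=len(flags),
                proportion=(sum(flags) / len(flags)) if flags else None,
            )
        )
    if missing_total:
        logger.info(
            "epoch_trait_summary(%s): %d assigned proteins lacked trait data",
            trait_def.name,
            missing_total,
        )
    return rows


def trait_grid(
    selection,
    traits: Mapping[str, TraitRecord],
    trait_def: TraitDef,
    quality_level: str = "all",
    ca_grid=None,
    cd_grid=None,
    min_size: int = 1,
):
    """Trait summaries over the full strictness grid, as a long DataFrame."""
    import pandas as pd

    from .significance import CA_GRID, CD_GRID, assign_epochs

    ca_grid = CA_GRID if ca_grid is None else ca_grid
    cd_grid = CD_GRID if cd_grid is None else cd_grid
    rows = []
    for ca_min in ca_grid:
        for cd_max in cd_grid:
            assignment = assign_epochs(selection, ca_min, cd_max, quality_level, min_size)
            for s in epoch_trait_summary(assignment, traits, trait_def):
                rows.append(
                    {
                        "quality_level": s.quality_level,
                        "ca_min": s.ca_min,
                        "cd_max": s.cd_max,
                        "epoch": s.epoch.value,
                        "trait": s.trait,
                        "population": s.population,
                        "n_with_data": s.n_with_data,
                        "proportion": s.proportion,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait table I/O

_TRAIT_COLUMNS = ("protein_id", "prion_scores", "disorder_fraction", "uyp_flags")


def write_trait_table(records: Iterable[TraitRecord], path) -> None:
    """TSV with packed per-ortholog scores ("prd|llr" pairs, comma-separated)
    and "threshold=flag" UYP pairs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRAIT_COLUMNS)
        for rec in records:
            scores = ",".join(
                f"{'' if prd is None else format(prd, 'g')}|"
                f"{'' if llr is None else format(llr, 'g')}"
                for prd, llr in rec.prion_scores
            )
            uyp = ",".join(
                f"{t:g}={'1' if flag else '0'}" for t, flag in sorted(rec.uyp.items())
            )
            writer.writerow(
                [
                    rec.protein_id,
                    scores,
                    ""
                    if rec.disorder_fraction is None
                    else f"{rec.disorder_fraction:.6f}",
                    uyp,
                ]
            )


def read_trait_table(path) -> dict:
    """Read the TSV written by :func:`write_trait_table`; protein_id keyed."""
    out: dict[str, TraitRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != _TRAIT_COLUMNS:
            raise AnnotationError(f"{path}: unexpected trait-table header")
        for row in reader:
            if not row:
                continue
            pid, scores_raw, dis_raw, uyp_raw = row
            scores = []
            if scores_raw:
                for pair in scores_raw.split(","):
                    prd_s, llr_s = pair.split("|")
                    scores.append(
                        (float(prd_s) if prd_s else None, float(llr_s) if llr_s else None)
                    )
            uyp = {}
            if uyp_raw:
                for pair in uyp_raw.split(","):
                    t, flag = pair.split("=")
                    uyp[float(t)] = flag == "1"
            out[pid] = TraitRecord(
                protein_id=pid,
                prion_scores=tuple(scores),
                disorder_fraction=float(dis_raw) if dis_raw else None,
                uyp=uyp,
            )
    return out


def write_enrichment(results: Iterable[EnrichmentResult], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            (
                "cluster_id",
                "term",
                "k",
                "n",
                "K",
                "N",
                "direction",
                "p",
                "p_bonferroni",
                "significant",
            )
        )
        for r in results:
            p = r.p_enrich if r.direction == "enriched" else r.p_deplete
            writer.writerow(
                [
                    r.cluster_id,
                    r.term,
                    r.k,
                    r.n,
                    r.K,
                    r.N,
                    r.direction,
                    f"{p:.6g}",
                    f"{r.p_bonferroni:.6g}",
                    "true" if r.significant else "false",
                ]
            )
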