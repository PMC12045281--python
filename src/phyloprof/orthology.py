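"""Bidirectional best hits, profile-matrix construction, unique-protein labels.

Orthologs are called by the bidirectional (reciprocal) best-hit criterion
on BLASTP tabular output: a is orthologous to b when b is a's best eligible
hit in the other proteome and a is b's best eligible hit back, with hits
eligible when their e-value is at or below a cutoff (default 1e-03).
"Best" is fully deterministic: lowest e-value, ties broken by highest
bitscore, remaining ties by lexicographically smallest subject id.

"Unique" focal-species proteins (UYPs) are those with no non-self hit in a
search of the focal proteome against itself, evaluated at e-value cutoffs
1e-02, 1e-03 and 1e-04.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_taxa import SpeciesTable
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-3
UYP_THRESHOLDS: tuple[float, ...] = (1e-2, 1e-3, 1e-4)


class OrthologyError(ValueError):
    """Raised for malformed hit files or inconsistent ortholog sets."""


@dataclass(frozen=True)
class HitRecord:
    """One BLAST tabular hit (query, subject, e-value, bitscore)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise OrthologyError(
                f"negative evalue {self.evalue} for {self.query_id}->{self.subject_id}"
            )


def read_blast_tab(path) -> list[HitRecord]:
    """Parse BLAST outfmt-6 (12 columns; query, subject, e-value, bitscore used)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise OrthologyError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(fields[0], fields[1], float(fields[10]), float(fields[11]))
                )
            except ValueError:
                raise OrthologyError(
                    f"{path}: line {lineno}: cannot parse evalue/bitscore"
                ) from None
    return hits


def _collapse_hsps(hits: Iterable[HitRecord]) -> dict:
    """Keep the minimum-evalue record per (query, subject) pair.

    Ties on e-value keep the higher bitscore, matching the best-hit rule.
    """
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    return best


def best_hits(
    hits: Iterable[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    filter_first: bool = True,
) -> dict:
    """Map each query to its best eligible subject.

    ``filter_first=True`` applies the e-value cutoff before picking the
    best hit; ``False`` picks the best hit over all hits and then requires
    it to pass the cutoff.
    """
    per_pair = _collapse_hsps(hits)
    if filter_first:
        per_pair = {k: h for k, h in per_pair.items() if h.evalue <= evalue_max}
    best: dict[str, HitRecord] = {}
    for (query, subject), h in sorted(per_pair.items()):
        cur = best.get(query)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[query] = h
    if not filter_first:
        best = {q: h for q, h in best.items() if h.evalue <= evalue_max}
    return {q: h.subject_id for q, h in best.items()}


def bidirectional_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    filter_first: bool = True,
) -> set:
    """Reciprocal best-hit pairs (a, b) between proteomes A and B."""
    ab = best_hits(hits_ab, evalue_max, filter_first)
    ba = best_hits(hits_ba, evalue_max, filter_first)
    return {(a, b) for a, b in ab.items() if ba.get(b) == a}


@dataclass(frozen=True)
class OrthologSet:
    """Species carrying an ortholog of one focal protein."""

    focal_protein_id: str
    present_in: frozenset


def ortholog_sets_from_bdbh(
    focal_species_id: str,
    pairs_by_species: dict,
) -> list[OrthologSet]:
    """Assemble per-protein ortholog sets from per-species BDBH pair sets.

    ``pairs_by_species`` maps species_id -> set of (focal_protein, other_protein)
    reciprocal pairs against that species.
    """
    present: dict[str, set[str]] = {}
    for species_id, pairs in sorted(pairs_by_species.items()):
        for focal_protein, _ in pairs:
            present.setdefault(focal_protein, set()).add(species_id)
    return [
        OrthologSet(pid, frozenset(spp | {focal_species_id}))
        for pid, spp in sorted(present.items())
    ]


def build_profile_matrix(
    ortholog_sets: Sequence[OrthologSet], table: SpeciesTable
) -> ProfileMatrix:
    """One profile row per focal protein; bit j = ortholog present in species j.

    The focal bit (position 0) is always 1.  A species named in an ortholog
    set but absent from the panel is an error.
    """
    L = len(table)
    ids, rows = [], []
    for oset in ortholog_sets:
        bits = np.zeros(L, dtype=np.uint8)
        for sp in oset.present_in:
            if sp not in table:
                raise OrthologyError(
                    f"protein {oset.focal_protein_id}: species {sp!r} not in panel"
                )
            bits[table.position(sp)] = 1
        bits[0] = 1
        ids.append(oset.focal_protein_id)
        rows.append(bits)
    return ProfileMatrix(table, ids, np.array(rows, dtype=np.uint8))


@dataclass(frozen=True)
class UypLabel:
    """Uniqueness flags for one protein across e-value thresholds."""

    protein_id: str
    is_uyp_at: dict

    def __getitem__(self, threshold: float) -> bool:
        return self.is_uyp_at[threshold]


def label_uyp(
    self_hits: Sequence[HitRecord],
    thresholds: Sequence[float] = UYP_THRESHOLDS,
    proteins: Optional[Sequence[str]] = None,
) -> list[UypLabel]:
    """Label proteins with no non-self hit in a self-vs-self search.

    A protein is a UYP at threshold t iff it has no hit with e-value <= t
    to any subject other than itself.  Self matches (query == subject) are
    excluded.  ``proteins`` extends the label set beyond proteins appearing
    as queries; absentees are treated as having no hits, with a warning.
    """
    min_nonself: dict[str, float] = {}
    queried: set[str] = set()
    for h in self_hits:
        queried.add(h.query_id)
        if h.query_id == h.subject_id:
            continue
        cur = min_nonself.get(h.query_id)
        if cur is None or h.evalue < cur:
            min_nonself[h.query_id] = h.evalue
    universe = sorted(queried)
    if proteins is not None:
        extra = sorted(set(proteins) - queried)
        if extra:
            logger.warning(
                "%d proteins absent from the self-search; treated as having no hits",
                len(extra),
            )
        universe = sorted(set(proteins) | queried)
    labels = []
    for pid in universe:
        e = min_nonself.get(pid)
        labels.append(
            UypLabel(pid, {t: (e is None or e > t) for t in thresholds})
        )
    return labels
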