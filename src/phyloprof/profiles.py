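"""Phylogenetic profiles, mismatch distances, ideal epoch profiles.

A profile is an ordered 0/1 vector over the species panel recording
presence (1) / absence (0) of an ortholog of one focal-species protein.
The distance between two profiles is the plain Hamming mismatch count,
called PM (profile mismatches), optionally expressed as a fraction of the
profile length.

Ideal epoch profiles have 1s exactly on the species of one nested clade:
Sc (the focal species), WGD (descendants of the whole-genome duplication),
Sa (the family), Se (the class), A (the phylum), F (all species).  Clade
nesting makes them bitwise contained in recency order
Sc < WGD < Sa < Se < A < F.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

from .io_taxa import SpeciesTable, SpeciesTableError


class ProfileError(ValueError):
    """Raised for malformed or incompatible profiles."""


class Epoch(enum.Enum):
    """Origination epochs, ordered from most recent to most ancient."""

    SC = "Sc"
    WGD = "WGD"
    SA = "Sa"
    SE = "Se"
    A = "A"
    F = "F"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: epochs from most recent to most ancient (nested clade size order)
EPOCH_RECENCY: tuple[Epoch, ...] = (
    Epoch.SC,
    Epoch.WGD,
    Epoch.SA,
    Epoch.SE,
    Epoch.A,
    Epoch.F,
)

_EPOCH_BY_VALUE = {e.value: e for e in Epoch}


def epoch_from_string(s: str) -> Epoch:
    try:
        return _EPOCH_BY_VALUE[s]
    except KeyError:
        raise ProfileError(f"unknown epoch {s!r}") from None


def _as_bits(x) -> np.ndarray:
    bits = np.asarray(x.bits if isinstance(x, Profile) else x, dtype=np.uint8)
    if bits.ndim != 1:
        raise ProfileError("profile bits must be one-dimensional")
    if not np.all((bits == 0) | (bits == 1)):
        raise ProfileError("profile bits must be 0/1")
    return bits


@dataclass(frozen=True)
class Profile:
    """One protein's presence/absence vector over the species panel."""

    protein_id: str
    bits: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bits", _as_bits(self.bits))

    def __len__(self) -> int:
        return len(self.bits)


class PMValue(NamedTuple):
    """Mismatch count between two profiles and its fraction of the length."""

    count: int
    fraction: float


def profile_mismatches(p, q) -> PMValue:
    """PM between two equal-length profiles: Hamming count and fraction."""
    a, b = _as_bits(p), _as_bits(q)
    if a.shape != b.shape:
        raise ProfileError(f"profile length mismatch: {a.size} vs {b.size}")
    count = int(np.count_nonzero(a != b))
    return PMValue(count, count / a.size)


class ProfileMatrix:
    """A stack of equal-length profiles tied to a species panel."""

    def __init__(self, species: SpeciesTable, protein_ids: Sequence[str], data):
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2:
            raise ProfileError("profile matrix must be two-dimensional")
        if data.shape[1] != len(species):
            raise ProfileError(
                f"matrix width {data.shape[1]} != panel size {len(species)}"
            )
        if data.shape[0] != len(protein_ids):
            raise ProfileError("one protein_id required per row")
        if not np.all((data == 0) | (data == 1)):
            raise ProfileError("profile matrix entries must be 0/1")
        ids = tuple(protein_ids)
        if len(set(ids)) != len(ids):
            raise ProfileError("duplicate protein_ids in profile matrix")
        self.species = species
        self.protein_ids = ids
        self.data = data
        self._row = {pid: i for i, pid in enumerate(ids)}

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        """Profile length L (species-panel size)."""
        return self.data.shape[1]

    def row(self, protein_id: str) -> np.ndarray:
        return self.data[self._row[protein_id]]

    def profile(self, protein_id: str) -> Profile:
        return Profile(protein_id, self.row(protein_id))

    def rows(self, protein_ids: Iterable[str]) -> np.ndarray:
        return self.data[[self._row[p] for p in protein_ids]]

    def project(self, subtable: SpeciesTable) -> "ProfileMatrix":
        """Restrict columns to a (filtered) species panel, keeping its order."""
        try:
            cols = [self.species.position(s) for s in subtable.species_ids]
        except SpeciesTableError as exc:
            raise ProfileError(f"cannot project: {exc}") from None
        return ProfileMatrix(subtable, self.protein_ids, self.data[:, cols])

    @property
    def ones_fraction(self) -> float:
        """Global fraction of 1s; the null-calibration background probability."""
        return float(self.data.mean())


def distance_matrix(m: ProfileMatrix) -> np.ndarray:
    """Symmetric matrix of pairwise PM counts (zero diagonal).

    Uses the bilinear identity ``PM(a, b) = |a| + |b| - 2 a.b`` so the whole
    matrix is two matrix products, not an O(n^2 L) elementwise sweep.
    """
    if len(m) < 2:
        raise ProfileError("distance matrix requires at least 2 profiles")
    x = m.data.astype(np.int32)
    s = x.sum(axis=1)
    d = s[:, None] + s[None, :] - 2 * (x @ x.T)
    np.fill_diagonal(d, 0)
    return d


@dataclass(frozen=True)
class IdealProfileSet:
    """Ideal epoch profiles over one species panel, keyed by :class:`Epoch`."""

    species: SpeciesTable
    profiles: dict

    def __getitem__(self, epoch: Epoch) -> np.ndarray:
        return self.profiles[epoch]

    def items(self):
        """(epoch, bits) pairs in recency order."""
        return [(e, self.profiles[e]) for e in EPOCH_RECENCY]

    def ones_count(self, epoch: Epoch) -> int:
        return int(self.profiles[epoch].sum())


def ideal_profiles(table: SpeciesTable, sc_scope: str = "focal") -> IdealProfileSet:
    """Build the six ideal epoch profiles for a species panel.

    ``sc_scope`` controls the most recent epoch: ``"focal"`` puts a single 1
    at the focal species, ``"genus"`` covers the whole genus.  The WGD
    profile covers species flagged as descendants of the whole-genome
    duplication; flags inconsistent with clade nesting raise an error.
    """
    L = len(table)
    range_idx = np.array([r.range_index for r in table.records])
    wgd = np.zeros(L, dtype=np.uint8)
    wgd[table.wgd_positions()] = 1

    if sc_scope == "focal":
        sc = np.zeros(L, dtype=np.uint8)
        sc[0] = 1
    elif sc_scope == "genus":
        sc = (range_idx <= 0).astype(np.uint8)
    else:
        raise ProfileError(f"sc_scope must be 'focal' or 'genus', got {sc_scope!r}")

    profiles = {
        Epoch.SC: sc,
        Epoch.WGD: wgd,
        Epoch.SA: (range_idx <= 1).astype(np.uint8),
        Epoch.SE: (range_idx <= 2).astype(np.uint8),
        Epoch.A: (range_idx <= 3).astype(np.uint8),
        Epoch.F: np.ones(L, dtype=np.uint8),
    }
    # clade nesting must give bitwise containment along the recency order
    for inner, outer in zip(EPOCH_RECENCY[:-1], EPOCH_RECENCY[1:]):
        if np.any(profiles[inner] > profiles[outer]):
            raise ProfileError(
                f"ideal profile containment violated: {inner.value} not within "
                f"{outer.value} (check WGD membership flags)"
            )
    return IdealProfileSet(table, profiles)


def random_profile(
    length: int,
    p_one: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """IID Bernoulli(p_one) profile from a seeded generator."""
    if not (0.0 <= p_one <= 1.0):
        raise ProfileError(f"p_one must be in [0, 1], got {p_one}")
    if rng is None:
        rng = np.random.default_rng(seed)
    return (rng.random(length) < p_one).astype(np.uint8)


def random_reference_profiles(length: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """The two fixed random reference profiles (P(1)=0.25 and P(1)=0.75).

    Observed profiles can be compared against these instead of the ideal
    profiles to check that epoch trends are not an artifact of the ideals.
    """
    rng = np.random.default_rng(seed)
    return random_profile(length, 0.25, rng=rng), random_profile(length, 0.75, rng=rng)


# ---------------------------------------------------------------------------
# TSV I/O


def write_profile_matrix(m: ProfileMatrix, path) -> None:
    """TSV: first column protein_id, one 0/1 column per species."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("protein_id",) + m.species.species_ids)
        for pid, bits in zip(m.protein_ids, m.data):
            writer.writerow([pid] + [str(int(b)) for b in bits])


def read_profile_matrix(path, table: SpeciesTable) -> ProfileMatrix:
    """Read the TSV written by :func:`write_profile_matrix`.

    The file's species columns must match the panel exactly (same order).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[0] != "protein_id":
            raise ProfileError(f"{path}: first column must be protein_id")
        if tuple(header[1:]) != table.species_ids:
            raise ProfileError(f"{path}: species columns do not match the panel")
        ids, rows = [], []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            ids.append(row[0])
            try:
                rows.append([int(v) for v in row[1:]])
            except ValueError:
                raise ProfileError(f"{path}: row {rownum}: non-integer bit") from None
    return ProfileMatrix(table, ids, np.array(rows, dtype=np.uint8))


def write_distance_matrix(d: np.ndarray, ids: Sequence[str], path, fmt: str = "tsv") -> None:
    """Write a square PM-count matrix as TSV or PHYLIP square format."""
    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(("",) + tuple(ids))
            for name, row in zip(ids, d):
                writer.writerow([name] + [str(int(v)) for v in row])
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(ids)}\n")
            for name, row in zip(ids, d):
                vals = " ".join(f"{float(v):g}" for v in row)
                fh.write(f"{name:<10s} {vals}\n")
    else:
        raise ProfileError(f"unknown distance-matrix format {fmt!r}")
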