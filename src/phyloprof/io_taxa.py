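"""Species panel I/O, proteome-quality filtering and the canonical profile order.

The species panel is the coordinate system shared by every phylogenetic
profile.  Species are grouped into five nested taxonomic ranges around the
focal species -- genus, family, class, phylum, kingdom -- and ordered from
the innermost range outwards, with the focal species always at position 0.
Within a range the order carries no meaning and the input order is kept.

Two proteome-quality annotations travel with each species: the BUSCO
completeness score (percentage of universal single-copy orthologs found
complete) and UniProt's CPD (Complete Proteome Detector) class.  Quality
levels ("all", "HQ1", "HQ2") filter the panel by a disjunction of the two:
a proteome stays if its BUSCO C score clears the level's cutoff *or* its
CPD class is in the level's accepted set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

#: nested ranges, innermost first; this order defines profile coordinates
RANGE_ORDER: tuple[str, ...] = ("genus", "family", "class", "phylum", "kingdom")
_RANGE_INDEX = {r: i for i, r in enumerate(RANGE_ORDER)}

CPD_CLASSES = frozenset(
    {
        "Standard",
        "CloseToStandard",
        "CloseToStandardHighValue",
        "Outlier",
        "OutlierHighValue",
        "Unknown",
    }
)

#: mapping from UniProt-style CPD strings (lower-cased) to the internal enum
CPD_ALIASES = {
    "standard": "Standard",
    "close to standard": "CloseToStandard",
    "close to standard (high value)": "CloseToStandardHighValue",
    "close to standard (low value)": "CloseToStandard",
    "outlier": "Outlier",
    "outlier (high value)": "OutlierHighValue",
    "outlier (low value)": "Outlier",
    "unknown": "Unknown",
}

SPECIES_COLUMNS = (
    "species_id",
    "proteome_id",
    "range_label",
    "wgd_member",
    "busco_c",
    "cpd_class",
    "is_focal",
)


class SpeciesTableError(ValueError):
    """Raised for malformed species tables or invalid records."""


def normalize_cpd(value: str) -> str:
    """Map a CPD class string (internal or UniProt dialect) to the enum."""
    v = value.strip()
    if v in CPD_CLASSES:
        return v
    alias = CPD_ALIASES.get(v.lower())
    if alias is None:
        raise SpeciesTableError(f"unknown CPD class {value!r}")
    return alias


@dataclass(frozen=True)
class SpeciesRecord:
    """One proteome in the panel with its range and quality annotations."""

    species_id: str
    proteome_id: str
    range_label: str
    wgd_member: bool
    busco_c: Optional[float]
    cpd_class: str
    is_focal: bool = False

    def __post_init__(self) -> None:
        if self.range_label not in _RANGE_INDEX:
            raise SpeciesTableError(
                f"unknown range_label {self.range_label!r} for species "
                f"{self.species_id!r} (expected one of {RANGE_ORDER})"
            )
        if self.cpd_class not in CPD_CLASSES:
            raise SpeciesTableError(
                f"unknown cpd_class {self.cpd_class!r} for species {self.species_id!r}"
            )
        if self.busco_c is not None and not (0.0 <= self.busco_c <= 100.0):
            raise SpeciesTableError(
                f"busco_c {self.busco_c} out of [0, 100] for species {self.species_id!r}"
            )
        if self.wgd_member and self.range_label not in ("genus", "family"):
            raise SpeciesTableError(
                f"species {self.species_id!r} is a WGD member but lies in range "
                f"{self.range_label!r}; the WGD clade is confined to genus/family"
            )

    @property
    def range_index(self) -> int:
        return _RANGE_INDEX[self.range_label]


@dataclass(frozen=True)
class QualityLevel:
    """A proteome-quality filter: BUSCO cutoff OR accepted CPD classes.

    ``busco_min=None`` with an empty ``cpd_accept`` means "no filter".
    """

    name: str
    busco_min: Optional[float]
    cpd_accept: frozenset

    def passes(self, rec: SpeciesRecord) -> bool:
        if self.busco_min is None and not self.cpd_accept:
            return True
        busco_ok = rec.busco_c is not None and rec.busco_c >= self.busco_min
        return busco_ok or rec.cpd_class in self.cpd_accept


QUALITY_LEVELS: dict[str, QualityLevel] = {
    "all": QualityLevel("all", None, frozenset()),
    "HQ1": QualityLevel(
        "HQ1",
        95.0,
        frozenset(
            {"Standard", "CloseToStandard", "CloseToStandardHighValue", "OutlierHighValue"}
        ),
    ),
    "HQ2": QualityLevel(
        "HQ2", 97.0, frozenset({"Standard", "CloseToStandardHighValue"})
    ),
}


class SpeciesTable:
    """Ordered species panel; the record order is the profile coordinate system.

    Construction applies the canonical ordering: stable sort by range
    (genus < family < class < phylum < kingdom) with the focal species
    pulled to the front of the genus block, hence position 0 overall.
    """

    def __init__(self, records: Sequence[SpeciesRecord], *, _sorted: bool = False):
        recs = list(records)
        focal = [r for r in recs if r.is_focal]
        if len(focal) == 0:
            raise SpeciesTableError("no focal species in table")
        if len(focal) > 1:
            ids = ", ".join(r.species_id for r in focal)
            raise SpeciesTableError(f"multiple focal species: {ids}")
        if focal[0].range_label != "genus":
            raise SpeciesTableError(
                f"focal species {focal[0].species_id!r} must be in the genus range"
            )
        seen: set[str] = set()
        for r in recs:
            if r.species_id in seen:
                raise SpeciesTableError(f"duplicate species_id {r.species_id!r}")
            seen.add(r.species_id)
        if not _sorted:
            recs.sort(key=lambda r: (r.range_index, not r.is_focal))
        self.records: tuple[SpeciesRecord, ...] = tuple(recs)
        self._index = {r.species_id: i for i, r in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesTable) and self.records == other.records

    @property
    def focal(self) -> SpeciesRecord:
        return self.records[0]

    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(r.species_id for r in self.records)

    def position(self, species_id: str) -> int:
        try:
            return self._index[species_id]
        except KeyError:
            raise SpeciesTableError(f"species {species_id!r} not in panel") from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def range_positions(self, range_label: str) -> list[int]:
        """Positions of all species in one range (focal included for genus)."""
        if range_label not in _RANGE_INDEX:
            raise SpeciesTableError(f"unknown range_label {range_label!r}")
        return [i for i, r in enumerate(self.records) if r.range_label == range_label]

    def wgd_positions(self) -> list[int]:
        return [i for i, r in enumerate(self.records) if r.wgd_member]


def filter_quality(table: SpeciesTable, level: QualityLevel) -> SpeciesTable:
    """Subtable of species passing the level's filter; focal always kept.

    The filter is a disjunction: BUSCO C >= busco_min OR CPD class accepted.
    A focal species that fails the filter is retained with a warning -- every
    profile's focal bit is 1 by construction, so dropping it would invalidate
    the coordinate system.
    """
    kept = []
    for rec in table.records:
        if rec.is_focal:
            if not level.passes(rec):
                logger.warning(
                    "focal species %s fails quality level %s; retained anyway",
                    rec.species_id,
                    level.name,
                )
            kept.append(rec)
        elif level.passes(rec):
            kept.append(rec)
    return SpeciesTable(kept, _sorted=True)


def _parse_bool(value: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no", ""):
        return False
    raise SpeciesTableError(f"row {row}: cannot parse {column}={value!r} as boolean")


def read_species_table(path) -> SpeciesTable:
    """Read a TSV species table and return it in canonical order.

    Expected header: species_id, proteome_id, range_label, wgd_member,
    busco_c, cpd_class, is_focal.  Distinct invariant violations raise
    distinct :class:`SpeciesTableError` messages naming the offending row.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SpeciesTableError(f"{path}: empty species table") from None
        missing = [c for c in SPECIES_COLUMNS if c not in header]
        if missing:
            raise SpeciesTableError(f"{path}: missing columns {missing}")
        col = {c: header.index(c) for c in SPECIES_COLUMNS}
        records = []
        focal_rows: list[int] = []
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                busco_raw = row[col["busco_c"]].strip()
                rec = SpeciesRecord(
                    species_id=row[col["species_id"]].strip(),
                    proteome_id=row[col["proteome_id"]].strip(),
                    range_label=row[col["range_label"]].strip().lower(),
                    wgd_member=_parse_bool(row[col["wgd_member"]], rownum, "wgd_member"),
                    busco_c=float(busco_raw) if busco_raw else None,
                    cpd_class=normalize_cpd(row[col["cpd_class"]]),
                    is_focal=_parse_bool(row[col["is_focal"]], rownum, "is_focal"),
                )
            except IndexError:
                raise SpeciesTableError(f"{path}: row {rownum}: too few columns") from None
            except SpeciesTableError as exc:
                raise SpeciesTableError(f"{path}: row {rownum}: {exc}") from None
            except ValueError as exc:
                raise SpeciesTableError(f"{path}: row {rownum}: {exc}") from None
            if rec.is_focal:
                focal_rows.append(rownum)
            records.append(rec)
    if len(focal_rows) > 1:
        raise SpeciesTableError(
            f"{path}: multiple focal species (rows {', '.join(map(str, focal_rows))})"
        )
    if not focal_rows:
        raise SpeciesTableError(f"{path}: no focal species (is_focal=true) found")
    return SpeciesTable(records)


def write_species_table(table: SpeciesTable, path) -> None:
    """Write a species table in the same TSV dialect ``read_species_table`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SPECIES_COLUMNS)
        for r in table.records:
            writer.writerow(
                [
                    r.species_id,
                    r.proteome_id,
                    r.range_label,
                    "true" if r.wgd_member else "false",
                    "" if r.busco_c is None else f"{r.busco_c:g}",
                    r.cpd_class,
                    "true" if r.is_focal else "false",
                ]
            )
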