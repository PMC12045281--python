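"""End-to-end orchestration: profiles -> NJ -> clusters -> calibration ->
selection -> assignment -> QLA -> enrichment -> traits.

Every stage is a library call; this module wires them together for each
requested proteome-quality level, writes the intermediate tables as TSV,
and records a manifest (row counts, thresholds, seeds, file hashes) so two
runs with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import annotation_stats as ann
from .clustering import candidate_clusters, cluster_consensus, neighbor_joining, write_newick
from .io_taxa import QUALITY_LEVELS, SpeciesTable, filter_quality, read_species_table
from .profiles import (
    EPOCH_RECENCY,
    ProfileMatrix,
    distance_matrix,
    ideal_profiles,
    read_profile_matrix,
)
from .significance import (
    CA_GRID,
    CD_GRID,
    EpochAssignment,
    assign_epochs,
    calibrate_all_epochs,
    qla_table,
    score_clusters,
    select_nonredundant,
    strictness_grid,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """Raised for invalid pipeline configurations."""


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds and seeds for one full run."""

    species_path: Path
    profiles_path: Path
    out_dir: Path
    levels: Sequence[str] = ("all", "HQ1", "HQ2")
    alpha: float = 0.05
    null_method: str = "exact"
    n_draws: int = 1_000_000
    m_tests: Optional[int] = None  # default: number of candidate clusters
    min_cluster_size: int = 2
    min_report_size: int = 10
    ca_min: float = 0.9
    cd_max: float = 0.1
    ca_grid: Sequence[float] = CA_GRID
    cd_grid: Sequence[float] = CD_GRID
    sc_scope: str = "focal"
    seed: int = 0
    traits_path: Optional[Path] = None
    annotations_path: Optional[Path] = None

    def validate(self) -> None:
        for p in (self.species_path, self.profiles_path):
            if not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")
        for p in (self.traits_path, self.annotations_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"input file not found: {p}")
        for level in self.levels:
            if level not in QUALITY_LEVELS:
                raise PipelineError(f"unknown quality level {level!r}")
        for v in list(self.ca_grid) + list(self.cd_grid) + [self.ca_min, self.cd_max]:
            if not (0.0 <= v <= 1.0):
                raise PipelineError(f"grid threshold {v} outside [0, 1]")


@dataclass
class LevelResult:
    """In-memory products of one quality level's run."""

    level: str
    table: SpeciesTable
    matrix: ProfileMatrix
    scored: list
    selection: list
    assignment: EpochAssignment


@dataclass
class PipelineResult:
    out_dir: Path
    levels: Mapping[str, LevelResult]
    manifest: dict


def _write_clusters_tsv(scored, path: Path) -> None:
    with open(path, "w") as fh:
        epochs = [e.value for e in EPOCH_RECENCY]
        fh.write(
            "cluster_id\tsize\tca\tclosest_epoch\tsignificant\t"
            + "\t".join(f"cd_{e}" for e in epochs)
            + "\tconsensus\tmembers\n"
        )
        for s in scored:
            cds = "\t".join(f"{s.cd_by_epoch[e]:.6f}" for e in EPOCH_RECENCY)
            cons = "".join(str(int(b)) for b in s.consensus)
            fh.write(
                f"{s.cluster_id}\t{s.size}\t{s.ca:.6f}\t{s.closest_epoch.value}\t"
                f"{'true' if s.significant else 'false'}\t{cds}\t{cons}\t"
                f"{','.join(s.member_ids)}\n"
            )


def _write_calibration_tsv(calibrations, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tL\tk\tq\talpha_per_test\tthreshold_count\tthreshold_cd\tmethod\n")
        for epoch in EPOCH_RECENCY:
            c = calibrations[epoch]
            fh.write(
                f"{epoch.value}\t{c.L}\t{c.k}\t{c.q:.6f}\t{c.alpha_per_test:.6g}\t"
                f"{c.threshold_count}\t{c.threshold_cd:.6f}\t{c.method}\n"
            )


def _write_assignment_tsv(assignment: EpochAssignment, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tquality_level\tca_min\tcd_max\tepoch\tcluster_id\n")
        for pid in sorted(assignment.protein_to_epoch):
            fh.write(
                f"{pid}\t{assignment.quality_level}\t{assignment.ca_min:.6f}\t"
                f"{assignment.cd_max:.6f}\t{assignment.protein_to_epoch[pid].value}\t"
                f"{assignment.protein_to_cluster[pid]}\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_level(
    cfg: PipelineConfig, level: str, full_table: SpeciesTable, full_matrix: ProfileMatrix
) -> tuple[LevelResult, dict]:
    """All stages for one quality level; returns results and manifest counts."""
    table = filter_quality(full_table, QUALITY_LEVELS[level])
    matrix = full_matrix.project(table)
    logger.info("[%s] %d species, %d profiles", level, len(table), len(matrix))

    d = distance_matrix(matrix)
    tree = neighbor_joining(d, matrix.protein_ids)
    candidates = candidate_clusters(tree, min_size=cfg.min_cluster_size)
    consensi = [cluster_consensus(matrix, c) for c in candidates]

    ideals = ideal_profiles(table, sc_scope=cfg.sc_scope)
    m_tests = cfg.m_tests if cfg.m_tests is not None else max(1, len(candidates))
    calibrations = calibrate_all_epochs(
        ideals,
        q=matrix.ones_fraction,
        alpha=cfg.alpha,
        m_tests=m_tests,
        method=cfg.null_method,
        n_draws=cfg.n_draws,
        seed=cfg.seed,
    )
    scored = score_clusters(consensi, ideals, calibrations)
    selection = select_nonredundant(scored)
    assignment = assign_epochs(selection, cfg.ca_min, cfg.cd_max, quality_level=level)
    logger.info(
        "[%s] %d candidates, %d significant, %d selected, %d proteins assigned",
        level,
        len(candidates),
        sum(s.significant for s in scored),
        len(selection),
        len(assignment.protein_to_epoch),
    )

    out = Path(cfg.out_dir)
    write_newick(tree, out / f"tree_{level}.nwk")
    _write_calibration_tsv(calibrations, out / f"calibration_{level}.tsv")
    _write_clusters_tsv(scored, out / f"clusters_{level}.tsv")
    _write_assignment_tsv(assignment, out / f"assignment_{level}.tsv")
    grid = strictness_grid(
        selection,
        quality_level=level,
        ca_grid=cfg.ca_grid,
        cd_grid=cfg.cd_grid,
        min_size=cfg.min_report_size,
    )
    grid.to_csv(out / f"grid_{level}.tsv", sep="\t", index=False, float_format="%.6f")

    counts = {
        "species": len(table),
        "profiles": len(matrix),
        "candidate_clusters": len(candidates),
        "significant_clusters": int(sum(s.significant for s in scored)),
        "selected_clusters": len(selection),
        "assigned_proteins": len(assignment.protein_to_epoch),
        "grid_cells": int(len(grid)),
    }
    return LevelResult(level, table, matrix, scored, selection, assignment), counts


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage for each requested quality level.

    Identical configuration and seed produce byte-identical outputs; the
    manifest records per-stage row counts and SHA-256 hashes of every file.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "null_method": cfg.null_method,
        "ca_min": cfg.ca_min,
        "cd_max": cfg.cd_max,
        "levels": list(cfg.levels),
        "complete": False,
        "stages": {},
    }

    full_table = read_species_table(cfg.species_path)
    full_matrix = read_profile_matrix(cfg.profiles_path, full_table)

    levels: dict[str, LevelResult] = {}
    for level in cfg.levels:
        try:
            result, counts = run_level(cfg, level, full_table, full_matrix)
        except Exception as exc:
            manifest["failed_stage"] = level
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {level!r} failed: {exc}") from exc
        levels[level] = result
        manifest["stages"][level] = counts

    # cross-level agreement at the configured strictness
    qla_path = out / "qla.tsv"
    with open(qla_path, "w") as fh:
        fh.write("reference_level\tother_level\tcluster_id\tepoch\tsize\tqla\n")
        for ref in cfg.levels:
            for other in cfg.levels:
                if ref == other:
                    continue
                for r in qla_table(levels[ref].assignment, levels[other].assignment):
                    fh.write(
                        f"{r.reference_level}\t{r.other_level}\t{r.cluster_id}\t"
                        f"{r.epoch.value}\t{r.size}\t{r.qla:.6f}\n"
                    )

    # optional annotation enrichment and trait summaries on the first level
    first = levels[cfg.levels[0]]
    if cfg.annotations_path is not None:
        table = ann.read_annotation_table(cfg.annotations_path, first.matrix.protein_ids)
        results = []
        for s in first.assignment.clusters:
            if s.size >= cfg.min_report_size:
                results.extend(
                    ann.cluster_enrichment(s.cluster_id, s.member_ids, table, cfg.alpha)
                )
        ann.write_enrichment(results, out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {"tests": len(results)}
    if cfg.traits_path is not None:
        traits = ann.read_trait_table(cfg.traits_path)
        frames = []
        for trait_def in ann.STANDARD_TRAIT_DEFS:
            frames.append(
                ann.trait_grid(
                    first.selection,
                    traits,
                    trait_def,
                    quality_level=first.level,
                    ca_grid=cfg.ca_grid,
                    cd_grid=cfg.cd_grid,
                    min_size=cfg.min_report_size,
                )
            )
        import pandas as pd

        pd.concat(frames, ignore_index=True).to_csv(
            out / "traits.tsv", sep="\t", index=False, float_format="%.6f"
        )
        manifest["stages"]["traits"] = {"rows": int(sum(len(f) for f in frames))}

    manifest["complete"] = True
    manifest["files"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(out, levels, manifest)
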