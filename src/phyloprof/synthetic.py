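"""Synthetic profile matrices with planted epochs of gene origination.

The generator emulates the structure a real ortholog presence/absence
matrix would show around a focal species: each gene is born at the
ancestor of one of the six nested epochs (its noiseless profile is that
epoch's ideal profile), may then lose a contiguous sub-clade of species
(clade-specific loss), and finally suffers iid bit-flip noise -- false
negatives at rate eps_fn (inflated for low-quality proteomes) and false
positives at rate eps_fp.  The planted truth (per-gene epoch, loss
events, per-species quality, trait flags) is recorded so recovery by the
full clustering pipeline can be measured.

All randomness flows from one seed through named substreams, so each
stage is independently reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .annotation_stats import AnnotationTable, TraitRecord
from .io_taxa import SpeciesRecord, SpeciesTable
from .profiles import (
    EPOCH_RECENCY,
    Epoch,
    ProfileMatrix,
    epoch_from_string,
    ideal_profiles,
)


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


# substream tags: one per generator stage
_STREAM_SPECIES = 1
_STREAM_BIRTH = 2
_STREAM_LOSS = 3
_STREAM_NOISE = 4
_STREAM_TRAITS = 5
_STREAM_ANNOT = 6


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


@dataclass(frozen=True)
class TraitModel:
    """Per-epoch trait probabilities (ordered Sc, WGD, Sa, Se, A, F).

    ``p_idp20_extra`` is the probability of mild-but-not-high disorder, so
    the >=20% class is the union of the >=50% class and this extra mass.
    Defaults plant the qualitative trends the analysis is meant to expose:
    prion-like and highly disordered proteins peak among the most recent
    genes, mildly disordered and unique proteins peak at the family epoch.
    """

    p_prion: tuple = (0.10, 0.05, 0.05, 0.05, 0.04, 0.03)
    p_idp50: tuple = (0.15, 0.10, 0.08, 0.06, 0.04, 0.03)
    p_idp20_extra: tuple = (0.20, 0.22, 0.40, 0.25, 0.20, 0.15)
    p_uyp: tuple = (0.30, 0.40, 0.70, 0.40, 0.30, 0.20)

    def for_epoch(self, epoch: Epoch) -> tuple:
        i = EPOCH_RECENCY.index(epoch)
        return (
            self.p_prion[i],
            self.p_idp50[i],
            self.p_idp20_extra[i],
            self.p_uyp[i],
        )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated panel and matrix.

    Default sizes give a 100-species panel (5 genus + 10 family + 15 class
    + 30 phylum + 40 kingdom) with a 10-species WGD clade, 50 genes born
    per epoch, 2% false-negative and 0.2% false-positive bit noise, and a
    20% chance per gene of one contiguous clade loss of 2-10 species.
    """

    n_genus: int = 5
    n_family: int = 10
    n_class: int = 15
    n_phylum: int = 30
    n_kingdom: int = 40
    wgd_size: int = 10
    genes_per_epoch: Mapping[Epoch, int] = field(
        default_factory=lambda: {e: 50 for e in EPOCH_RECENCY}
    )
    clade_loss: float = 0.2
    loss_size_min: int = 2
    loss_size_max: int = 10
    eps_fn: float = 0.02
    eps_fp: float = 0.002
    low_quality_fraction: float = 0.1
    lowq_eps_fn: float = 0.10
    trait_model: TraitModel = field(default_factory=TraitModel)
    sc_scope: str = "focal"
    seed: int = 0

    def __post_init__(self):
        for name in ("clade_loss", "eps_fn", "eps_fp", "low_quality_fraction", "lowq_eps_fn"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SimulationError(f"{name}={v} is not a probability")
        for name in ("n_genus", "n_family", "n_class", "n_phylum", "n_kingdom"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if any(v < 0 for v in self.genes_per_epoch.values()):
            raise SimulationError("gene counts must be >= 0")
        if self.wgd_size < self.n_genus or self.wgd_size > self.n_genus + self.n_family:
            raise SimulationError(
                "wgd_size must cover the genus and fit within genus+family "
                f"(got {self.wgd_size} for genus {self.n_genus}, family {self.n_family})"
            )

    @property
    def n_species(self) -> int:
        return self.n_genus + self.n_family + self.n_class + self.n_phylum + self.n_kingdom


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated matrix."""

    epochs: Mapping[str, Epoch]  # gene -> true origination epoch
    losses: Mapping[str, Optional[tuple]]  # gene -> (start, size) block or None
    lowq_species: frozenset
    traits: Mapping[str, Mapping[str, bool]]  # gene -> {prion, idp50, idp20, uyp}


def simulate_species_table(cfg: SimConfig) -> SpeciesTable:
    """Deterministic synthetic species panel matching the configuration.

    WGD membership covers the whole genus plus a leading block of the
    family, so every ideal clade is a contiguous prefix of the panel.
    Low-quality species draw BUSCO scores below the HQ1 cutoff and CPD
    "Outlier"; the rest sit above the HQ2 cutoff, so all three quality
    levels are exercised.
    """
    rng = _stream(cfg.seed, _STREAM_SPECIES)
    blocks = [
        ("genus", cfg.n_genus),
        ("family", cfg.n_family),
        ("class", cfg.n_class),
        ("phylum", cfg.n_phylum),
        ("kingdom", cfg.n_kingdom),
    ]
    n = cfg.n_species
    # low-quality species among the non-focal panel
    n_lowq = int(round(cfg.low_quality_fraction * (n - 1)))
    lowq_idx = set(rng.choice(np.arange(1, n), size=n_lowq, replace=False).tolist())
    records = []
    pos = 0
    n_wgd_family = cfg.wgd_size - cfg.n_genus
    for range_label, count in blocks:
        for i in range(count):
            is_focal = pos == 0
            wgd = range_label == "genus" or (range_label == "family" and i < n_wgd_family)
            lowq = pos in lowq_idx
            busco = float(rng.uniform(70, 90)) if lowq else float(rng.uniform(98, 100))
            records.append(
                SpeciesRecord(
                    species_id=f"sp{pos:04d}",
                    proteome_id=f"UP{pos:06d}",
                    range_label=range_label,
                    wgd_member=wgd,
                    busco_c=round(busco, 1),
                    cpd_class="Outlier" if lowq else "Standard",
                    is_focal=is_focal,
                )
            )
            pos += 1
    return SpeciesTable(records)


def simulate_profiles(
    table: SpeciesTable, cfg: SimConfig
) -> tuple[ProfileMatrix, SimTruth]:
    """Plant genes at epoch ancestors, apply clade loss and bit-flip noise."""
    ideals = ideal_profiles(table, sc_scope=cfg.sc_scope)
    L = len(table)
    lowq = frozenset(
        r.species_id for r in table.records if r.cpd_class == "Outlier"
    )
    eps_fn_vec = np.full(L, cfg.eps_fn)
    for i, r in enumerate(table.records):
        if r.species_id in lowq:
            eps_fn_vec[i] = cfg.lowq_eps_fn

    birth_rng = _stream(cfg.seed, _STREAM_BIRTH)  # reserved for future birth models
    loss_rng = _stream(cfg.seed, _STREAM_LOSS)
    noise_rng = _stream(cfg.seed, _STREAM_NOISE)

    ids, rows = [], []
    epochs: dict[str, Epoch] = {}
    losses: dict[str, Optional[tuple]] = {}
    g = 0
    for epoch in EPOCH_RECENCY:
        ideal = ideals[epoch]
        k = int(ideal.sum())
        for _ in range(cfg.genes_per_epoch.get(epoch, 0)):
            gene = f"Y{g:04d}"
            g += 1
            bits = ideal.copy()
            loss = None
            if k >= 3 and loss_rng.random() < cfg.clade_loss:
                # contiguous block inside the 1-region, never touching the focal bit
                max_size = min(cfg.loss_size_max, k - 1)
                size = int(loss_rng.integers(min(cfg.loss_size_min, max_size), max_size + 1))
                start = int(loss_rng.integers(1, k - size + 1))
                bits[start : start + size] = 0
                loss = (start, size)
            u = noise_rng.random(L)
            flip_down = (bits == 1) & (u < eps_fn_vec)
            flip_up = (bits == 0) & (u < cfg.eps_fp)
            bits = bits.copy()
            bits[flip_down] = 0
            bits[flip_up] = 1
            bits[0] = 1
            ids.append(gene)
            rows.append(bits)
            epochs[gene] = epoch
            losses[gene] = loss

    traits = _simulate_traits(epochs, cfg)
    matrix = ProfileMatrix(table, ids, np.array(rows, dtype=np.uint8))
    return matrix, SimTruth(epochs, losses, lowq, traits)


def _simulate_traits(epochs: Mapping[str, Epoch], cfg: SimConfig) -> dict:
    rng = _stream(cfg.seed, _STREAM_TRAITS)
    out: dict[str, dict[str, bool]] = {}
    for gene in sorted(epochs):
        p_prion, p_idp50, p_idp20_extra, p_uyp = cfg.trait_model.for_epoch(epochs[gene])
        idp50 = bool(rng.random() < p_idp50)
        idp20 = idp50 or bool(rng.random() < p_idp20_extra)
        out[gene] = {
            "prion": bool(rng.random() < p_prion),
            "idp50": idp50,
            "idp20": idp20,
            "uyp": bool(rng.random() < p_uyp),
        }
    return out


def trait_records_from_truth(
    truth: SimTruth, matrix: ProfileMatrix, cfg: SimConfig
) -> dict:
    """Concrete :class:`TraitRecord` inputs consistent with the planted flags.

    Prion-like genes get PLAAC-style scores passing on ~95% of their
    orthologs (with occasional missing PRD exercising the LLR fallback);
    non-prion genes pass on ~20%.  Disorder fractions are drawn inside the
    band the flag pair (idp50, idp20) dictates.  UYP flags are monotone
    across the three e-value thresholds by construction.
    """
    rng = _stream(cfg.seed, _STREAM_TRAITS + 100)
    out: dict[str, TraitRecord] = {}
    for gene in sorted(truth.epochs):
        flags = truth.traits[gene]
        n_orth = max(3, min(12, int(matrix.row(gene).sum())))
        p_pass = 0.95 if flags["prion"] else 0.20
        scores = []
        for _ in range(n_orth):
            passing = rng.random() < p_pass
            value = float(rng.uniform(15.0, 40.0)) if passing else float(rng.uniform(-5.0, 0.0))
            if rng.random() < 0.1:
                scores.append((None, value))  # PRD missing, LLR carries the score
            else:
                scores.append((value, float(rng.uniform(-5.0, 5.0))))
        if flags["idp50"]:
            dis = float(rng.uniform(0.5, 0.9))
        elif flags["idp20"]:
            dis = float(rng.uniform(0.2, 0.5))
        else:
            dis = float(rng.uniform(0.0, 0.2))
        if flags["uyp"]:
            uyp = {1e-2: True, 1e-3: True, 1e-4: True}
        elif rng.random() < 0.15:
            uyp = {1e-2: False, 1e-3: False, 1e-4: True}
        else:
            uyp = {1e-2: False, 1e-3: False, 1e-4: False}
        out[gene] = TraitRecord(gene, tuple(scores), dis, uyp)
    return out


def generate_annotations(truth: SimTruth, cfg: SimConfig) -> AnnotationTable:
    """Annotation table with one term enriched in each epoch's gene set.

    Term ``GO:EP<epoch>`` is given to genes of that epoch with probability
    0.5 and to others with probability 0.02; ten background terms are
    sprinkled uniformly at 5%.
    """
    rng = _stream(cfg.seed, _STREAM_ANNOT)
    background = sorted(truth.epochs)
    ann: dict[str, set[str]] = {g: set() for g in background}
    for epoch in EPOCH_RECENCY:
        term = f"GO:EP{epoch.value}"
        for gene in background:
            p = 0.5 if truth.epochs[gene] == epoch else 0.02
            if rng.random() < p:
                ann[gene].add(term)
    for t in range(10):
        term = f"GO:BG{t:02d}"
        for gene in background:
            if rng.random() < 0.05:
                ann[gene].add(term)
    return AnnotationTable(
        {g: frozenset(ts) for g, ts in ann.items() if ts}, frozenset(background)
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Accuracy of epoch assignment against the planted truth."""

    n_genes: int
    n_assigned: int
    n_correct: int
    per_epoch: Mapping[Epoch, tuple]  # epoch -> (n_true, n_assigned, n_correct)

    @property
    def coverage(self) -> float:
        return self.n_assigned / self.n_genes if self.n_genes else 0.0

    @property
    def accuracy(self) -> Optional[float]:
        return self.n_correct / self.n_assigned if self.n_assigned else None


def evaluate_recovery(assignment, truth: SimTruth) -> RecoveryReport:
    """Fraction of assigned genes whose assigned epoch matches the truth."""
    per_epoch: dict[Epoch, list[int]] = {e: [0, 0, 0] for e in EPOCH_RECENCY}
    n_assigned = n_correct = 0
    for gene, true_epoch in truth.epochs.items():
        per_epoch[true_epoch][0] += 1
        assigned = assignment.protein_to_epoch.get(gene)
        if assigned is not None:
            n_assigned += 1
            per_epoch[true_epoch][1] += 1
            if assigned == true_epoch:
                n_correct += 1
                per_epoch[true_epoch][2] += 1
    return RecoveryReport(
        n_genes=len(truth.epochs),
        n_assigned=n_assigned,
        n_correct=n_correct,
        per_epoch={e: tuple(v) for e, v in per_epoch.items()},
    )


# ---------------------------------------------------------------------------
# Truth I/O and config files


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ("gene", "epoch", "loss_start", "loss_size", "prion", "idp50", "idp20", "uyp")
        )
        for gene in sorted(truth.epochs):
            loss = truth.losses.get(gene)
            flags = truth.traits[gene]
            writer.writerow(
                [
                    gene,
                    truth.epochs[gene].value,
                    "" if loss is None else loss[0],
                    "" if loss is None else loss[1],
                    int(flags["prion"]),
                    int(flags["idp50"]),
                    int(flags["idp20"]),
                    int(flags["uyp"]),
                ]
            )


def read_truth(path, lowq_species=()) -> SimTruth:
    epochs, losses, traits = {}, {}, {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            if not row:
                continue
            gene = row[0]
            epochs[gene] = epoch_from_string(row[1])
            losses[gene] = (int(row[2]), int(row[3])) if row[2] else None
            traits[gene] = {
                "prion": row[4] == "1",
                "idp50": row[5] == "1",
                "idp20": row[6] == "1",
                "uyp": row[7] == "1",
            }
    return SimTruth(epochs, losses, frozenset(lowq_species), traits)


def write_sim_config(cfg: SimConfig, path) -> None:
    """Plain key = value config file covering every simulation field."""
    with open(path, "w") as fh:
        for name in (
            "n_genus",
            "n_family",
            "n_class",
            "n_phylum",
            "n_kingdom",
            "wgd_size",
            "loss_size_min",
            "loss_size_max",
            "seed",
        ):
            fh.write(f"{name} = {getattr(cfg, name)}\n")
        for name in ("clade_loss", "eps_fn", "eps_fp", "low_quality_fraction", "lowq_eps_fn"):
            fh.write(f"{name} = {getattr(cfg, name):g}\n")
        fh.write(f"sc_scope = {cfg.sc_scope}\n")
        genes = ",".join(f"{e.value}:{cfg.genes_per_epoch.get(e, 0)}" for e in EPOCH_RECENCY)
        fh.write(f"genes_per_epoch = {genes}\n")
        tm = cfg.trait_model
        for name in ("p_prion", "p_idp50", "p_idp20_extra", "p_uyp"):
            fh.write(f"{name} = {','.join(f'{v:g}' for v in getattr(tm, name))}\n")


def read_sim_config(path) -> SimConfig:
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    kwargs: dict = {}
    for name in (
        "n_genus",
        "n_family",
        "n_class",
        "n_phylum",
        "n_kingdom",
        "wgd_size",
        "loss_size_min",
        "loss_size_max",
        "seed",
    ):
        if name in raw:
            kwargs[name] = int(raw[name])
    for name in ("clade_loss", "eps_fn", "eps_fp", "low_quality_fraction", "lowq_eps_fn"):
        if name in raw:
            kwargs[name] = float(raw[name])
    if "sc_scope" in raw:
        kwargs["sc_scope"] = raw["sc_scope"]
    if "genes_per_epoch" in raw:
        genes = {}
        for part in raw["genes_per_epoch"].split(","):
            name, _, count = part.partition(":")
            genes[epoch_from_string(name.strip())] = int(count)
        kwargs["genes_per_epoch"] = genes
    tm_kwargs = {}
    for name in ("p_prion", "p_idp50", "p_idp20_extra", "p_uyp"):
        if name in raw:
            tm_kwargs[name] = tuple(float(v) for v in raw[name].split(","))
    if tm_kwargs:
        kwargs["trait_model"] = TraitModel(**tm_kwargs)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Random additive distance matrices (for validating tree reconstruction)


def random_additive_matrix(
    n_leaves: int, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """A random binary tree's additive leaf-distance matrix and its newick.

    Branch lengths are uniform on [0.5, 2.0], so the four-point condition
    holds exactly and neighbour joining must recover the topology.
    """
    if n_leaves < 4:
        raise SimulationError("need at least 4 leaves for a non-trivial topology")
    labels = [f"L{i}" for i in range(n_leaves)]
    # adjacency with branch lengths; nodes 0..n-1 are leaves
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    nodes = list(range(n_leaves))
    newick = {i: labels[i] for i in range(n_leaves)}
    nxt = n_leaves
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.5, 2.0, size=2)
        adj[nxt] = []
        adj[nxt].append((a, float(la)))
        adj[nxt].append((b, float(lb)))
        adj[a].append((nxt, float(la)))
        adj[b].append((nxt, float(lb)))
        newick[nxt] = f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [nxt]
        nxt += 1
    root = nodes[0]
    d = np.zeros((n_leaves, n_leaves))
    for leaf in range(n_leaves):
        # BFS accumulating path lengths
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other in range(n_leaves):
            d[leaf, other] = dist[other]
    return d, newick[root] + ";"
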