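"""Synthetic data with planted ground truth for every pipeline input.

The generators emulate the statistical structure the analysis assumes: a
signed causal knowledge base with designated transcript targets, ternary
observations produced by planted active regulators plus background change,
a 6-timepoint / 3-replicate tri-omic time course with H3K4me3-coupled and
-decoupled genes and planted repressive miRNA-gene pairs, miRNA-target
catalogs mixing curated and predicted evidence, and Poisson read piles
around TSS windows. All generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .causal_kb import (
    AMBIGUOUS,
    CausalGraph,
    CausalStatement,
    Hypothesis,
    build_graph,
    predict_downstream,
)
from .errors import ConfigurationError
from .scoring import ObservationSet
from .preprocess import TimecourseMatrix

__all__ = [
    "SyntheticTruth",
    "simulate_knowledge_base",
    "simulate_observations",
    "simulate_timecourse_triomics",
    "simulate_target_catalog",
    "simulate_reads_for_tss",
]

#: Timepoint labels mirroring a 6-stage differentiation design.
DEFAULT_TIMEPOINTS = ("D0", "D1", "D2", "D5", "D8", "D11")
REPLICATE_LABELS = "ABCDEFGH"


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every synthetic data set."""

    seed: int | None = None
    planted_regulators: list[dict] = field(default_factory=list)
    sign_fidelity: float | None = None
    background_change_rate: float | None = None
    planted_mirna_pairs: list[dict] = field(default_factory=list)
    coupling: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_knowledge_base(
    n_nodes: int = 200,
    n_statements: int = 2000,
    sign_balance: float = 0.5,
    hub_targets: int = 0,
    seed: int | None = None,
) -> tuple[CausalGraph, SyntheticTruth]:
    """Random signed directed multigraph standing in for a curated KB.

    Sources and targets are drawn uniformly (no self-loops), so out-degrees
    are binomial(n_statements, 1/n_nodes). Every target is a
    transcript-layer node; ``sign_balance`` is the probability of an
    "increases" edge. ``hub_targets > 0`` dedicates that many statements to
    a hub regulator (the first node) with that many distinct targets -
    the natural host for a planted active regulator in recovery studies.
    """
    if n_statements < n_nodes - 1:
        raise ConfigurationError("need at least n_nodes - 1 statements")
    if not 0 <= sign_balance <= 1:
        raise ConfigurationError("sign_balance must be in [0, 1]")
    if hub_targets >= min(n_nodes, n_statements):
        raise ConfigurationError("hub_targets must be < n_nodes and < n_statements")
    rng = _rng(seed)
    width = len(str(n_nodes - 1))
    names = [f"G{i:0{width}d}" for i in range(n_nodes)]
    n_random = n_statements - hub_targets
    src = rng.integers(0, n_nodes, size=n_random)
    tgt = rng.integers(0, n_nodes - 1, size=n_random)
    tgt = np.where(tgt >= src, tgt + 1, tgt)  # uniform over nodes != source
    sign = np.where(rng.random(n_statements) < sign_balance, 1, -1)
    statements = []
    if hub_targets:
        hub_tgt = 1 + rng.choice(n_nodes - 1, size=hub_targets, replace=False)
        statements.extend(
            CausalStatement(names[0], int(sign[i]), names[t], "transcript", "SYN")
            for i, t in enumerate(hub_tgt)
        )
    statements.extend(
        CausalStatement(names[s], int(g), names[t], "transcript", "SYN")
        for s, g, t in zip(src, sign[hub_targets:], tgt)
    )
    truth = SyntheticTruth(seed=seed)
    if hub_targets:
        truth.planted_regulators = [{"node": names[0], "n_targets": int(hub_targets)}]
    return build_graph(statements), truth


def simulate_observations(
    graph: CausalGraph,
    planted: Sequence[Hypothesis],
    fidelity: float = 0.9,
    background_rate: float = 0.05,
    flip_share: float = 0.5,
    depth: int = 1,
    seed: int | None = None,
    interval_label: str = "synthetic",
) -> tuple[ObservationSet, SyntheticTruth]:
    """Ternary observations driven by planted active regulators.

    Each transcript non-ambiguously predicted by a planted hypothesis
    changes in the predicted direction with probability ``fidelity``, flips
    sign with probability ``(1 - fidelity) * flip_share``, and is otherwise
    unchanged. Every other transcript changes with ``background_rate``
    (sign uniform). The universe is the graph's transcript-node set.
    """
    for h in planted:
        if h.node not in graph.nodes:
            raise ConfigurationError(f"planted node {h.node!r} not in graph")
    rng = _rng(seed)
    target_sign: dict[str, int] = {}
    for h in planted:
        profile = predict_downstream(h, graph, depth=depth)
        for t, v in profile.predictions.items():
            if v != AMBIGUOUS:
                target_sign.setdefault(t, v)
    calls: dict[str, int] = {}
    for t in sorted(graph.transcript_nodes):
        if t in target_sign:
            u = rng.random()
            if u < fidelity:
                calls[t] = target_sign[t]
            elif u < fidelity + (1 - fidelity) * flip_share:
                calls[t] = -target_sign[t]
            else:
                calls[t] = 0
        else:
            if rng.random() < background_rate:
                calls[t] = 1 if rng.random() < 0.5 else -1
            else:
                calls[t] = 0
    truth = SyntheticTruth(
        seed=seed,
        planted_regulators=[
            {"node": h.node, "direction": h.direction} for h in planted
        ],
        sign_fidelity=fidelity,
        background_change_rate=background_rate,
    )
    return ObservationSet(calls, interval_label=interval_label), truth


def _latent_trajectories(rng, n: int, n_timepoints: int, amplitude: float) -> np.ndarray:
    """Smooth random trajectories over the time course.

    Each trajectory is a random combination of a linear ramp and the first
    two cosine/sine harmonics - monotone ramps, single bursts and
    rise-and-fall shapes akin to developmental time courses, with enough
    effective degrees of freedom that independent trajectories are not
    spuriously correlated. Centered and scaled to standard deviation
    ``amplitude`` across timepoints.
    """
    t = np.linspace(0.0, 1.0, n_timepoints)
    coefs = rng.normal(size=(n, 5))
    basis = np.vstack(
        [
            t,
            np.cos(np.pi * t),
            np.sin(np.pi * t),
            np.cos(2 * np.pi * t),
            np.sin(2 * np.pi * t),
        ]
    )
    traj = coefs @ basis
    traj -= traj.mean(axis=1, keepdims=True)
    sd = traj.std(axis=1, keepdims=True)
    sd[sd < 1e-9] = 1.0
    return amplitude * traj / sd


def _with_replicates(
    rng, latent: np.ndarray, n_reps: int, noise_sd: float
) -> np.ndarray:
    n, n_tp = latent.shape
    wide = np.repeat(latent, n_reps, axis=1)
    if noise_sd > 0:
        wide = wide + rng.normal(scale=noise_sd, size=wide.shape)
    return wide


def simulate_timecourse_triomics(
    n_genes: int = 1000,
    n_mirnas: int = 100,
    n_timepoints: int = 6,
    n_reps: int = 3,
    n_planted_pairs: int = 20,
    coupled_fraction: float = 0.9,
    noise_sd: float = 0.2,
    amplitude: float = 2.0,
    seed: int | None = None,
) -> tuple[TimecourseMatrix, TimecourseMatrix, TimecourseMatrix, SyntheticTruth]:
    """Coupled gene / miRNA / H3K4me3 time courses with planted structure.

    Genes follow smooth latent trajectories (log2 scale, baseline 8,
    trajectory sd ``amplitude``). H3K4me3-*coupled* genes get a promoter
    mark tracking their expression (scaled latent + replicate noise);
    *decoupled* genes get a flat low mark (insulin-like: expression moves,
    the mark does not). The first ``n_planted_pairs`` decoupled genes are
    paired with dedicated miRNAs whose trajectories mirror the gene
    (repression); remaining miRNAs evolve independently. Replicate noise is
    i.i.d. N(0, noise_sd) everywhere.
    """
    rng = _rng(seed)
    if n_planted_pairs > min(n_genes, n_mirnas):
        raise ConfigurationError("more planted pairs than genes or miRNAs")
    tps = (
        list(DEFAULT_TIMEPOINTS)
        if n_timepoints == len(DEFAULT_TIMEPOINTS)
        else [f"T{i}" for i in range(n_timepoints)]
    )
    reps = [REPLICATE_LABELS[i] for i in range(n_reps)]
    cols = pd.MultiIndex.from_product([tps, reps], names=["timepoint", "replicate"])
    gw = len(str(n_genes - 1))
    mw = len(str(n_mirnas - 1))
    genes = [f"GENE{i:0{gw}d}" for i in range(n_genes)]
    mirnas = [f"miR-{i:0{mw}d}" for i in range(n_mirnas)]

    gene_latent = _latent_trajectories(rng, n_genes, n_timepoints, amplitude)

    # Coupling assignment: planted-pair genes are decoupled by construction
    # (their changes are to be explained by the miRNA, not the mark).
    planted_gene_idx = np.arange(n_planted_pairs)
    coupled = rng.random(n_genes) < coupled_fraction
    coupled[planted_gene_idx] = False

    gene_baseline = 8.0
    mark_baseline = 4.0
    mark_floor = 1.5  # "below background" flat level for decoupled genes
    mirna_baseline = 6.0

    gene_vals = gene_baseline + _with_replicates(rng, gene_latent, n_reps, noise_sd)

    mark_latent = np.where(
        coupled[:, None],
        mark_baseline + 0.8 * gene_latent,
        mark_floor + np.zeros_like(gene_latent),
    )
    mark_vals = _with_replicates(rng, mark_latent, n_reps, noise_sd)

    mirna_latent = _latent_trajectories(rng, n_mirnas, n_timepoints, amplitude)
    mirna_latent[:n_planted_pairs] = -gene_latent[planted_gene_idx]
    mirna_vals = mirna_baseline + _with_replicates(rng, mirna_latent, n_reps, noise_sd)

    gene_tm = TimecourseMatrix(pd.DataFrame(gene_vals, index=genes, columns=cols), "mrna")
    mirna_tm = TimecourseMatrix(
        pd.DataFrame(mirna_vals, index=mirnas, columns=cols), "mirna"
    )
    mark_tm = TimecourseMatrix(
        pd.DataFrame(mark_vals, index=genes, columns=cols), "h3k4me3"
    )
    truth = SyntheticTruth(
        seed=seed,
        planted_mirna_pairs=[
            {"mirna": mirnas[i], "gene": genes[i], "effect": 1.0}
            for i in range(n_planted_pairs)
        ],
        coupling={
            g: ("coupled" if c else "decoupled") for g, c in zip(genes, coupled)
        },
    )
    return gene_tm, mirna_tm, mark_tm, truth


def simulate_target_catalog(
    truth: SyntheticTruth,
    genes: Sequence[str],
    mirnas: Sequence[str],
    n_decoys: int = 100,
    n_single_db: int = 20,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Curated + per-database predicted tables containing the planted pairs.

    Planted pairs are split between the curated table and >= 2 prediction
    databases, so all survive catalog assembly. ``n_decoys`` random
    non-planted pairs are added with assembly-passing evidence, plus
    ``n_single_db`` pairs supported by a single database only (these should
    be dropped by the two-database rule).
    """
    rng = _rng(seed)
    planted = [(p["mirna"], p["gene"]) for p in truth.planted_mirna_pairs]
    planted_set = set(planted)
    dbs = ["mirbase", "pictar", "targetscan"]

    def random_pairs(k: int) -> list[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        while len(pairs) < k:
            m = mirnas[rng.integers(len(mirnas))]
            g = genes[rng.integers(len(genes))]
            if (m, g) not in planted_set:
                pairs.add((m, g))
        return sorted(pairs)

    curated_rows: list[tuple[str, str]] = []
    pred_rows: dict[str, list[tuple[str, str]]] = {db: [] for db in dbs}
    for i, pair in enumerate(planted):
        if i % 2 == 0:
            curated_rows.append(pair)
        else:
            for db in rng.choice(dbs, size=2, replace=False):
                pred_rows[db].append(pair)
    for pair in random_pairs(n_decoys):
        if rng.random() < 0.3:
            curated_rows.append(pair)
        else:
            for db in rng.choice(dbs, size=2, replace=False):
                pred_rows[db].append(pair)
    for pair in random_pairs(n_single_db):
        pred_rows[dbs[rng.integers(len(dbs))]].append(pair)

    curated = pd.DataFrame(curated_rows, columns=["mirna", "gene"])
    predicted = {
        db: pd.DataFrame(rows, columns=["mirna", "gene"])
        for db, rows in pred_rows.items()
    }
    return curated, predicted


def simulate_reads_for_tss(
    tss: pd.DataFrame,
    rpkm_targets: Sequence[float] | pd.Series,
    total_mapped: int = 10_000_000,
    window_bp: int = 5000,
    read_length: int = 36,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson read piles around each TSS hitting configured RPKM targets.

    The per-window read count is Poisson with mean
    ``rpkm * (window_bp/1000) * (total_mapped/1e6)`` (the inversion of the
    RPKM formula), with read start positions uniform inside the window.
    Returns a BED-like frame (chrom, start, end) sorted by coordinate.
    """
    targets = np.asarray(rpkm_targets, dtype=float)
    if (targets < 0).any():
        raise ConfigurationError("rpkm targets must be non-negative")
    if len(targets) != len(tss):
        raise ConfigurationError("one RPKM target per TSS row required")
    rng = _rng(seed)
    scale = (window_bp / 1000.0) * (total_mapped / 1e6)
    half = window_bp // 2
    chroms, starts = [], []
    for (row, target) in zip(tss.itertuples(index=False), targets):
        center = int(row.start)
        n = rng.poisson(target * scale)
        if n == 0:
            continue
        lo = max(0, center - half)
        hi = center + half - read_length
        pos = rng.integers(lo, max(hi, lo + 1), size=n)
        chroms.extend([row.chrom] * n)
        starts.extend(pos.tolist())
    out = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": np.array(starts, dtype=int) + read_length}
    )
    return out.sort_values(["chrom", "start"], ignore_index=True)
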