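"""Preprocessing of time-course omics layers.

Covers the shared plumbing of the tri-omic analysis: log2/quantile
normalization of expression matrices, the detection filter, per-interval
ternary differential calls, H3K4me3 quantification in fixed-width windows
around transcription start sites (RPKM), level/change correlation matrices
between layers, per-gene cross-layer correlations, and peak-set overlaps.

Sample columns follow the ``D8_A_1`` convention: timepoint label, then
replicate labels, underscore-separated. Genomic intervals are 0-based
half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    ContractViolation,
    InsufficientReplication,
    UndefinedFraction,
)
from .scoring import ObservationSet

__all__ = [
    "TimecourseMatrix",
    "PeakSet",
    "normalize",
    "quantile_normalize",
    "detection_filter",
    "differential_calls",
    "read_bed",
    "write_bed",
    "tss_window_rpkm",
    "rpkm_from_counts",
    "background_level",
    "correlation_matrix",
    "per_gene_correlation",
    "peak_overlap_fraction",
]

_PRESETS = {
    # (min |log2 fold change|, p threshold, use BH-adjusted p)
    "headline": (1.0, 0.01, True),  # FC >= 2, adjusted P < 0.01
    "toptable": (np.log2(1.5), 0.01, False),  # FC > 1.5, raw P < 0.01
}


# ---------------------------------------------------------------------------
# Time-course container


@dataclass
class TimecourseMatrix:
    """Features x samples abundance table on log2 scale.

    ``values`` has features as the index and a two-level column MultiIndex
    (timepoint, replicate); timepoint order is the column order of the
    source data, not lexicographic.
    """

    values: pd.DataFrame
    layer: str = "mrna"

    def __post_init__(self):
        if not isinstance(self.values.columns, pd.MultiIndex):
            self.values = self.values.copy()
            self.values.columns = parse_sample_codes(self.values.columns)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> list[str]:
        seen: dict[str, None] = {}
        for tp, _ in self.values.columns:
            seen.setdefault(tp, None)
        return list(seen)

    def replicates(self, timepoint: str) -> pd.DataFrame:
        return self.values.xs(timepoint, axis=1, level=0)

    def timepoint_means(self) -> pd.DataFrame:
        """Features x timepoints matrix of replicate means (column order kept)."""
        means = self.values.T.groupby(level=0, sort=False).mean().T
        return means[self.timepoints]

    def sample_codes(self) -> list[str]:
        return ["_".join(c) for c in self.values.columns]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = self.sample_codes()
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, layer: str = "mrna") -> "TimecourseMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, layer=layer)


def parse_sample_codes(codes: Iterable[str]) -> pd.MultiIndex:
    """``D8_A_1`` -> (timepoint ``D8``, replicate ``A_1``)."""
    pairs = []
    for code in codes:
        parts = str(code).split("_")
        pairs.append((parts[0], "_".join(parts[1:]) if len(parts) > 1 else "1"))
    return pd.MultiIndex.from_tuples(pairs, names=["timepoint", "replicate"])


# ---------------------------------------------------------------------------
# Normalization and filtering


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization across columns.

    After the transform every column has the same sorted value profile (the
    per-rank mean of the input columns). Ties within a column receive the
    mean of the values they span, which makes the transform idempotent.
    """
    ranks = df.rank(method="average", axis=0)
    sorted_means = pd.DataFrame(
        np.sort(df.values, axis=0), columns=df.columns
    ).mean(axis=1)

    def interp(col_ranks: pd.Series) -> np.ndarray:
        # rank r (1-based, possibly fractional for ties) -> mean profile value
        return np.interp(
            col_ranks.values, np.arange(1, len(sorted_means) + 1), sorted_means.values
        )

    out = df.copy()
    for col in df.columns:
        out[col] = interp(ranks[col])
    return out


def normalize(
    raw: pd.DataFrame,
    layer: str = "mrna",
    log_transform: bool = True,
    offset: float = 0.0,
) -> TimecourseMatrix:
    """log2 transform then quantile normalization across samples.

    ``raw`` holds strictly positive abundances (after adding ``offset`` if
    one is supplied); columns are sample codes like ``D0_A_1``.
    """
    df = raw.astype(float) + offset
    if log_transform:
        if (df.values <= 0).any():
            raise ValueError(
                "non-positive abundances; supply a positive `offset` before log2"
            )
        df = np.log2(df)
    return TimecourseMatrix(quantile_normalize(df), layer=layer)


def detection_filter(
    matrix: TimecourseMatrix,
    detection_flags: pd.DataFrame,
    min_samples: int = 3,
) -> tuple[TimecourseMatrix, pd.Index]:
    """Drop features detected in fewer than ``min_samples`` samples.

    ``detection_flags`` is a boolean features x samples frame aligned with
    the matrix (e.g. detection P < 0.01 calls). Returns the filtered matrix
    and the index of removed features.
    """
    flags = detection_flags
    if not isinstance(flags.columns, pd.MultiIndex):
        flags = flags.copy()
        flags.columns = parse_sample_codes(flags.columns)
    if not flags.index.equals(matrix.values.index) or flags.shape != matrix.values.shape:
        raise ContractViolation("detection flags are not aligned with the matrix")
    n_detected = flags.astype(bool).sum(axis=1)
    keep = n_detected >= min_samples
    removed = matrix.values.index[~keep]
    return TimecourseMatrix(matrix.values.loc[keep], layer=matrix.layer), removed


# ---------------------------------------------------------------------------
# Differential calls


def differential_calls(
    matrix: TimecourseMatrix,
    interval: tuple[str, str],
    preset: str = "headline",
) -> tuple[pd.DataFrame, ObservationSet]:
    """Per-feature ternary calls for one time interval.

    log2 fold change is mean(t_j) - mean(t_i) over replicate samples; the
    per-feature test is Welch's two-sample t with Benjamini-Hochberg
    adjustment across features. The ``headline`` preset calls +1/-1 when
    |FC| >= 2 and adjusted P < 0.01; ``toptable`` uses |FC| > 1.5 and raw
    P < 0.01. Returns the per-feature table and the ternary
    :class:`ObservationSet` over all features of the matrix.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; expected {sorted(_PRESETS)}")
    min_lfc, p_max, adjusted = _PRESETS[preset]
    t_i, t_j = interval
    for t in (t_i, t_j):
        if t not in matrix.timepoints:
            raise ContractViolation(f"timepoint {t!r} not present in matrix")
    x = matrix.replicates(t_i)
    y = matrix.replicates(t_j)
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise InsufficientReplication(
            f"need >= 2 replicates per timepoint, got {x.shape[1]} and {y.shape[1]}"
        )
    lfc = y.mean(axis=1) - x.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(y.values, x.values, axis=1, equal_var=False)
    p = pd.Series(p, index=matrix.features).fillna(1.0)
    adj_p = pd.Series(
        multipletests(p.values, method="fdr_bh")[1], index=matrix.features
    )
    p_used = adj_p if adjusted else p
    call = pd.Series(0, index=matrix.features, dtype=int)
    call[(lfc >= min_lfc) & (p_used < p_max)] = 1
    call[(lfc <= -min_lfc) & (p_used < p_max)] = -1

    label = f"{t_i}-{t_j}"
    table = pd.DataFrame(
        {
            "feature": matrix.features,
            "interval": label,
            "log2fc": lfc.values,
            "p": p.values,
            "adj_p": adj_p.values,
            "call": call.values,
        }
    ).set_index("feature")
    obs = ObservationSet(dict(call.items()), interval_label=label)
    return table, obs


# ---------------------------------------------------------------------------
# H3K4me3 windows and peaks


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ name, score, strand if present)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def _tss_positions(tss: pd.DataFrame) -> pd.Series:
    """TSS coordinate per annotation row: start on + strand, end-1 on -."""
    if "strand" in tss.columns:
        return pd.Series(
            np.where(tss["strand"] == "-", tss["end"] - 1, tss["start"]),
            index=tss.index,
        )
    return tss["start"].copy()


def tss_window_rpkm(
    reads: pd.DataFrame,
    tss: pd.DataFrame,
    window_bp: int = 5000,
    total_mapped: int | None = None,
) -> pd.Series:
    """RPKM of reads in fixed windows centered on each TSS.

    A read overlapping the window by >= 1 bp counts once toward that window.
    ``total_mapped`` defaults to the number of reads supplied. Windows are
    symmetric around the TSS (strand only picks the TSS coordinate), clipped
    at zero. Returns a series indexed by the TSS ``name`` column (or row
    number if absent).
    """
    if total_mapped is None:
        total_mapped = len(reads)
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    # Sorted start/end arrays per chromosome: the number of reads overlapping
    # [lo, hi) is n - #(end <= lo) - #(start >= hi). Unlike an interval tree
    # (a set), this honors duplicate reads.
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in reads.groupby("chrom", sort=False):
        by_chrom[chrom] = (
            np.sort(grp["start"].to_numpy(int)),
            np.sort(grp["end"].to_numpy(int)),
        )
    centers = _tss_positions(tss)
    half = window_bp // 2
    names = tss["name"] if "name" in tss.columns else pd.Series(tss.index, index=tss.index)
    scale = (window_bp / 1000.0) * (total_mapped / 1e6)
    out = {}
    for idx in tss.index:
        chrom = tss.at[idx, "chrom"]
        c = int(centers.at[idx])
        lo, hi = max(0, c - half), c + half
        if chrom in by_chrom:
            starts, ends = by_chrom[chrom]
            n = len(starts)
            n -= np.searchsorted(ends, lo, side="right")
            n -= len(starts) - np.searchsorted(starts, hi, side="left")
        else:
            n = 0
        out[names.at[idx]] = n / scale
    return pd.Series(out, name="rpkm")


def rpkm_from_counts(
    counts: pd.DataFrame,
    total_mapped: Mapping[str, int] | pd.Series | None = None,
    window_bp: int = 5000,
) -> pd.DataFrame:
    """Convert a per-TSS read-count table (genes x timepoints) to RPKM.

    Matches the layout of a per-TSS count TSV with one column per timepoint
    (a ``CTRL`` column, if present, is converted alongside the rest).
    ``total_mapped`` gives the per-column library sizes; by default each
    column's sum is used.
    """
    if total_mapped is None:
        total = counts.sum(axis=0)
    else:
        total = pd.Series(total_mapped)[counts.columns]
    if (total <= 0).any():
        raise ValueError("total_mapped must be positive for every column")
    return counts / (window_bp / 1000.0) / (total / 1e6)


def background_level(control_rpkm: Iterable[float]) -> float:
    """Background promoter-mark level: median RPKM over control windows.

    Control windows are user-supplied (a genuine input control track, or
    shuffled windows generated alongside the TSS annotation).
    """
    arr = np.asarray(list(control_rpkm), dtype=float)
    if arr.size == 0:
        raise UndefinedFraction("no control windows supplied")
    return float(np.median(arr))


@dataclass
class PeakSet:
    """Labelled collection of genomic intervals (0-based half-open)."""

    intervals: pd.DataFrame  # columns chrom, start, end
    label: str = ""

    def __post_init__(self):
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.intervals = df.sort_values(["chrom", "start", "end"], ignore_index=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path, label: str = "") -> "PeakSet":
        return cls(read_bed(path)[["chrom", "start", "end"]], label=label)


def peak_overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Fraction of intervals in ``a`` overlapping (>= 1 bp) any interval of ``b``.

    Asymmetric: ``a`` is the query set.
    """
    if len(a) == 0:
        raise UndefinedFraction("query peak set is empty")
    trees = {
        chrom: IntervalTree.from_tuples(zip(grp["start"], grp["end"]))
        for chrom, grp in b.intervals.groupby("chrom", sort=False)
    }
    hits = 0
    for row in a.intervals.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlaps(row.start, row.end):
            hits += 1
    return hits / len(a)


# ---------------------------------------------------------------------------
# Cross-layer correlations


def _mode_vectors(tm: TimecourseMatrix, mode: str) -> tuple[pd.DataFrame, list[str]]:
    means = tm.timepoint_means()
    if mode == "levels":
        return means, list(means.columns)
    if mode == "changes":
        tps = list(means.columns)
        diffs = {
            f"{tps[i]}-{tps[i + 1]}": means[tps[i + 1]] - means[tps[i]]
            for i in range(len(tps) - 1)
        }
        df = pd.DataFrame(diffs)
        return df, list(df.columns)
    raise ValueError(f"unknown mode {mode!r}")


def correlation_matrix(
    x: TimecourseMatrix,
    y: TimecourseMatrix,
    mode: str = "levels",
) -> pd.DataFrame:
    """Pearson R between x and y across shared features, per timepoint pair.

    ``levels``: entry (i, j) correlates x's timepoint-i mean vector with y's
    timepoint-j mean vector over shared features. ``changes`` does the same
    for consecutive-interval difference vectors.
    """
    xv, x_labels = _mode_vectors(x, mode)
    yv, y_labels = _mode_vectors(y, mode)
    shared = xv.index.intersection(yv.index)
    if len(shared) < 3:
        raise ContractViolation(
            f"need >= 3 shared features, got {len(shared)}"
        )
    xa = xv.loc[shared].values
    ya = yv.loc[shared].values
    n_x, n_y = xa.shape[1], ya.shape[1]
    full = np.corrcoef(xa.T, ya.T)
    return pd.DataFrame(full[:n_x, n_x:], index=x_labels, columns=y_labels)


def per_gene_correlation(
    x: TimecourseMatrix,
    y: TimecourseMatrix,
    on: str = "auto",
) -> pd.Series:
    """Per-gene Pearson R between two layers across time.

    ``on='samples'`` correlates matched (timepoint, replicate) columns,
    ``on='timepoint_means'`` correlates replicate-averaged profiles, and
    ``'auto'`` uses samples when both layers share an identical sample
    layout, falling back to timepoint means otherwise. Genes with zero
    variance in either track are returned as NaN (undefined) - callers
    building distributions should drop them.
    """
    if on == "auto":
        on = (
            "samples"
            if x.values.columns.equals(y.values.columns)
            else "timepoint_means"
        )
    if on == "samples":
        xv, yv = x.values, y.values[x.values.columns]
    elif on == "timepoint_means":
        xm, ym = x.timepoint_means(), y.timepoint_means()
        shared_t = [t for t in xm.columns if t in set(ym.columns)]
        if len(shared_t) < 3:
            raise ContractViolation("need >= 3 shared timepoints")
        xv, yv = xm[shared_t], ym[shared_t]
    else:
        raise ValueError(f"unknown correlation basis {on!r}")
    shared = xv.index.intersection(yv.index)
    xa = xv.loc[shared].values.astype(float)
    ya = yv.loc[shared].values.astype(float)
    xa = xa - xa.mean(axis=1, keepdims=True)
    ya = ya - ya.mean(axis=1, keepdims=True)
    sx = np.sqrt((xa**2).sum(axis=1))
    sy = np.sqrt((ya**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xa * ya).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return pd.Series(r, index=shared, name="r")
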