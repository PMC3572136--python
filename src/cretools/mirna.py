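"""miRNA-gene regulatory integration.

Three-stage filter: (1) assemble a candidate catalog from literature-curated
associations plus in-silico predictions supported by at least two prediction
databases; (2) keep only pairs whose miRNA and gene expression are
anti-correlated across the time course (miRNAs predominantly act by target
degradation); (3) classify survivors by epigenetic parsimony - if a gene's
expression already tracks its promoter H3K4me3 level, the mark suffices to
explain the changes and the miRNA explanation is deprioritized (tier B);
genes whose expression is decoupled from H3K4me3 are the primary candidates
(tier A).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import TimecourseMatrix, per_gene_correlation

__all__ = [
    "PREDICTED_DATABASES",
    "assemble_associations",
    "anticorrelation_filter",
    "epigenetic_parsimony_classify",
    "rank_candidates",
    "read_catalog",
    "write_candidates",
]

PREDICTED_DATABASES = frozenset({"targetscan", "pictar", "mirbase"})
ALLOWED_SOURCES = PREDICTED_DATABASES | {"curated"}


def _norm_pairs(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"mirna", "gene"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"catalog lacks columns {sorted(missing)}")
    return df[["mirna", "gene"]].astype(str)


def assemble_associations(
    curated: pd.DataFrame,
    predicted: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Union of curated pairs and pairs predicted by >= 2 databases.

    ``curated`` and each value of ``predicted`` are tables with columns
    ``mirna, gene``; ``predicted`` keys name the databases (targetscan,
    pictar, mirbase). Returns one row per retained (mirna, gene) pair with a
    comma-joined ``sources`` column preserving provenance.
    """
    unknown = set(predicted) - PREDICTED_DATABASES
    if unknown:
        raise ConfigurationError(
            f"unknown prediction databases {sorted(unknown)}; "
            f"expected {sorted(PREDICTED_DATABASES)}"
        )
    sources: dict[tuple[str, str], set[str]] = {}
    for row in _norm_pairs(curated).itertuples(index=False):
        sources.setdefault((row.mirna, row.gene), set()).add("curated")
    pred_sources: dict[tuple[str, str], set[str]] = {}
    for db, table in predicted.items():
        for row in _norm_pairs(table).itertuples(index=False):
            pred_sources.setdefault((row.mirna, row.gene), set()).add(db)
    for pair, dbs in pred_sources.items():
        if len(dbs) >= 2:
            sources.setdefault(pair, set()).update(dbs)
        elif pair in sources:  # curated pair: keep the extra evidence label
            sources[pair].update(dbs)
    rows = [
        {"mirna": m, "gene": g, "sources": ",".join(sorted(dbs))}
        for (m, g), dbs in sorted(sources.items())
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "sources"])


def anticorrelation_filter(
    catalog: pd.DataFrame,
    mirna_matrix: TimecourseMatrix,
    gene_matrix: TimecourseMatrix,
    r_max: float = -0.5,
    on: str = "timepoint_means",
) -> pd.DataFrame:
    """Keep associations whose miRNA/gene Pearson R across time is <= r_max.

    Correlations use replicate-averaged timepoint profiles by default.
    Associations whose miRNA or gene is absent from its matrix are skipped
    with a warning (they cannot be evaluated, which is not an error of the
    catalog). Adds column ``r_mirna_gene``.
    """
    mirna_prof = mirna_matrix.timepoint_means()
    gene_prof = gene_matrix.timepoint_means()
    if on == "samples":
        mirna_prof = mirna_matrix.values.copy()
        mirna_prof.columns = mirna_matrix.sample_codes()
        gene_prof = gene_matrix.values.copy()
        gene_prof.columns = gene_matrix.sample_codes()
    shared_cols = [c for c in mirna_prof.columns if c in set(gene_prof.columns)]
    if len(shared_cols) < 3:
        raise ConfigurationError("need >= 3 shared timepoints/samples")
    kept = []
    skipped = 0
    for row in catalog.itertuples(index=False):
        if row.mirna not in mirna_prof.index or row.gene not in gene_prof.index:
            skipped += 1
            continue
        x = mirna_prof.loc[row.mirna, shared_cols].values.astype(float)
        y = gene_prof.loc[row.gene, shared_cols].values.astype(float)
        if x.std() == 0 or y.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        if np.isfinite(r) and r <= r_max:
            kept.append({**row._asdict(), "r_mirna_gene": r})
    if skipped:
        warnings.warn(
            f"{skipped} associations skipped: miRNA or gene not measured",
            stacklevel=2,
        )
    return pd.DataFrame(kept, columns=list(catalog.columns) + ["r_mirna_gene"])


def epigenetic_parsimony_classify(
    filtered: pd.DataFrame,
    gene_matrix: TimecourseMatrix,
    h3k4_matrix: TimecourseMatrix,
    rho_max: float = 0.5,
) -> pd.DataFrame:
    """Two-tier classification by whether H3K4me3 explains the gene's changes.

    Tier A (primary candidates): gene expression is decoupled from promoter
    H3K4me3 - Pearson R < rho_max, or undefined because the mark track is
    flat (e.g. stays below background throughout). Tier B: expression tracks
    the mark closely (R >= rho_max), so parsimony favors the epigenetic
    explanation; these are retained and labelled, not discarded. Adds
    columns ``r_gene_h3k4`` and ``tier``.
    """
    r_by_gene = per_gene_correlation(gene_matrix, h3k4_matrix)
    out = filtered.copy()
    rs, tiers = [], []
    for gene in out["gene"]:
        r = r_by_gene.get(gene, np.nan)
        rs.append(r)
        tiers.append("B" if (np.isfinite(r) and r >= rho_max) else "A")
    out["r_gene_h3k4"] = rs
    out["tier"] = tiers
    return out


def rank_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Tier A before tier B; within tier ascending R; ties by (mirna, gene)."""
    return candidates.sort_values(
        ["tier", "r_mirna_gene", "mirna", "gene"],
        ascending=[True, True, True, True],
        ignore_index=True,
    )


def read_catalog(path) -> pd.DataFrame:
    """Read a ``mirna, gene, source`` TSV (``source`` optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df.get("source", pd.Series(dtype=str)).dropna()) - ALLOWED_SOURCES
    if bad:
        raise ConfigurationError(f"unknown source labels {sorted(bad)}")
    return df


def write_candidates(candidates: pd.DataFrame, path) -> None:
    cols = ["mirna", "gene", "r_mirna_gene", "r_gene_h3k4", "tier", "sources"]
    out = candidates[[c for c in cols if c in candidates.columns]]
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")
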