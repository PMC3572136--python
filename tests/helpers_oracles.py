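"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: label-placement
enumeration for the correctness null, exact combinatorial sums for the
hypergeometric tail, per-read scans for window counts, and all-pairs scans
for interval overlap.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def enumerate_placements(n_total: int, n_up: int, n_down: int) -> np.ndarray:
    """All assignments of n_up (+1) and n_down (-1) labels to N slots.

    Returns an (n_placements, n_total) int matrix with entries in
    {-1, 0, +1}; each row is one equally likely assignment.
    """
    rows = []
    slots = list(range(n_total))
    for up in combinations(slots, n_up):
        remaining = [s for s in slots if s not in set(up)]
        for down in combinations(remaining, n_down):
            row = np.zeros(n_total, dtype=np.int8)
            row[list(up)] = 1
            row[list(down)] = -1
            rows.append(row)
    return np.array(rows) if rows else np.zeros((1, n_total), dtype=np.int8)


def null_pmf_by_enumeration(q_up, q_down, n_total, n_up, n_down):
    """Exact pmf of S = (a-b)+(d-c) by exhaustive enumeration.

    The first q_up slots are the predicted-up set and the next q_down the
    predicted-down set (which slots they are is irrelevant by symmetry).
    Returns (scores, pmf) with pmf as exact ratios cast to float.
    """
    placements = enumerate_placements(n_total, n_up, n_down)
    s = (
        placements[:, :q_up].sum(axis=1)
        - placements[:, q_up : q_up + q_down].sum(axis=1)
    )
    scores, counts = np.unique(s, return_counts=True)
    return scores, counts / len(placements)


def permutation_pvalue(
    q_up, q_down, n_total, n_up, n_down, observed, n_draws=20_000, seed=0
):
    """Monte-Carlo estimate of P(S >= observed) with its standard error."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_total, dtype=np.int8)
    labels[:n_up] = 1
    labels[n_up : n_up + n_down] = -1
    mat = np.tile(labels, (n_draws, 1))
    mat = rng.permuted(mat, axis=1)
    s = mat[:, :q_up].sum(axis=1) - mat[:, q_up : q_up + q_down].sum(axis=1)
    p_hat = float((s >= observed).mean())
    se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
    return p_hat, se


def hypergeom_sf_exact(k, n_total, n_changed, n_draw) -> float:
    """P(X >= k) for X hypergeometric, by direct combinatorial summation."""
    denom = math.comb(n_total, n_draw)
    num = 0
    for j in range(k, min(n_changed, n_draw) + 1):
        if n_draw - j <= n_total - n_changed:
            num += math.comb(n_changed, j) * math.comb(n_total - n_changed, n_draw - j)
    return num / denom


def window_count_bruteforce(reads, lo, hi) -> int:
    """Per-read scan: reads (start, end half-open) overlapping [lo, hi) by >=1bp."""
    return sum(1 for start, end in reads if start < hi and end > lo)


def overlap_fraction_bruteforce(a_intervals, b_intervals) -> float:
    """All-pairs scan version of the asymmetric peak overlap fraction."""
    hits = 0
    for chrom_a, s_a, e_a in a_intervals:
        for chrom_b, s_b, e_b in b_intervals:
            if chrom_a == chrom_b and s_a < e_b and e_a > s_b:
                hits += 1
                break
    return hits / len(a_intervals)
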