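"""Hypothesis scoring: correctness score, exact null p-value, enrichment p-value.

A hypothesis h predicts a set of downstream transcripts up (q+) or down (q-),
with conflicting-path transcripts counted ambiguous (q0). Against ternary
observed calls (+1/-1/0 over a universe of N measured transcripts, of which
n+ are up and n- down) its *correctness score* is

    S = #correct - #incorrect,

counting only non-ambiguous predictions of transcripts that actually changed.
Significance is assessed under the null of randomly re-assigning the n+ up
and n- down labels to arbitrary transcripts of the universe, uniformly and
without replacement. Writing (a, b) for the up/down labels landing in the
predicted-up set and (c, d) for those landing in the predicted-down set,

    S = (a - b) + (d - c),

and (a, b, c, d) follow a multivariate hypergeometric law whose full
distribution is computed analytically in polynomial time. The *enrichment*
p-value ignores direction: it is the one-sided Fisher/hypergeometric tail for
finding that many changed transcripts inside the downstream set at all.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .causal_kb import (
    AMBIGUOUS,
    CausalGraph,
    Hypothesis,
    PredictionProfile,
    enumerate_hypotheses,
    predict_downstream,
)
from .errors import ContractViolation

__all__ = [
    "ObservationSet",
    "ScoreBreakdown",
    "HypothesisResult",
    "classify_predictions",
    "correctness_null",
    "correctness_pvalue",
    "enrichment_pvalue",
    "score_all_hypotheses",
    "annotation_proportion",
    "results_to_frame",
    "write_results",
]


@dataclass
class ObservationSet:
    """Ternary differential calls over a measured transcript universe."""

    calls: dict[str, int]
    interval_label: str = ""

    def __post_init__(self):
        bad = {v for v in self.calls.values() if v not in (-1, 0, 1)}
        if bad:
            raise ValueError(f"calls must be in {{-1, 0, +1}}; got {sorted(bad)}")

    @property
    def universe(self) -> set[str]:
        return set(self.calls)

    @property
    def n_total(self) -> int:
        return len(self.calls)

    @property
    def n_up(self) -> int:
        return sum(1 for v in self.calls.values() if v == 1)

    @property
    def n_down(self) -> int:
        return sum(1 for v in self.calls.values() if v == -1)

    @property
    def n_changed(self) -> int:
        return self.n_up + self.n_down

    def changed(self) -> set[str]:
        return {t for t, v in self.calls.items() if v != 0}


@dataclass(frozen=True)
class ScoreBreakdown:
    """Correct / incorrect / ambiguous explanation counts of one hypothesis."""

    correct: int
    incorrect: int
    ambiguous: int

    @property
    def score(self) -> int:
        return self.correct - self.incorrect


@dataclass
class HypothesisResult:
    """One row of a ranked driver table."""

    hypothesis: Hypothesis
    breakdown: ScoreBreakdown
    correctness_p: float
    enrichment_p: float
    q_up: int
    q_down: int
    q_ambiguous: int

    @property
    def score(self) -> int:
        return self.breakdown.score


def classify_predictions(profile: PredictionProfile, obs: ObservationSet) -> ScoreBreakdown:
    """Count correctly, incorrectly and ambiguously explained observations.

    Only transcripts that changed (call != 0) can be explained; ambiguous
    predictions of changed transcripts are tallied separately and contribute
    to neither side of the score.
    """
    outside = set(profile.predictions) - obs.universe
    if outside:
        raise ContractViolation(
            f"profile predicts transcripts outside the observation universe: "
            f"{sorted(outside)[:5]}..."
        )
    correct = incorrect = ambiguous = 0
    for t, pred in profile.predictions.items():
        call = obs.calls[t]
        if call == 0:
            continue
        if pred == AMBIGUOUS:
            ambiguous += 1
        elif pred == call:
            correct += 1
        else:
            incorrect += 1
    return ScoreBreakdown(correct, incorrect, ambiguous)


@dataclass
class NullDistribution:
    """Exact null law of the correctness score S for given margins."""

    scores: np.ndarray  # integer support, ascending
    pmf: np.ndarray

    def pvalue(self, observed: int) -> float:
        """Upper tail P(S >= observed), clipped to [0, 1] against float drift."""
        return float(min(1.0, max(0.0, self.pmf[self.scores >= observed].sum())))

    def mean(self) -> float:
        return float((self.scores * self.pmf).sum())

    def total_mass(self) -> float:
        return float(self.pmf.sum())


def _check_margins(q_up: int, q_down: int, n_total: int, n_up: int, n_down: int) -> None:
    if min(q_up, q_down, n_total, n_up, n_down) < 0:
        raise ContractViolation("all margins must be non-negative")
    if q_up + q_down > n_total:
        raise ContractViolation(
            f"downstream sets (q+={q_up}, q-={q_down}) exceed universe N={n_total}"
        )
    if n_up + n_down > n_total:
        raise ContractViolation(
            f"changed counts (n+={n_up}, n-={n_down}) exceed universe N={n_total}"
        )


def _null_exact_int(q_up, q_down, n_total, n_up, n_down) -> NullDistribution:
    """Reference O(n+^2 n-^2) summation in exact integer arithmetic."""
    r = n_total - q_up - q_down
    denom = math.comb(n_total, n_up) * math.comb(n_total - n_up, n_down)
    offset = n_up + n_down
    numer = [0] * (2 * offset + 1)
    for a in range(min(q_up, n_up) + 1):
        for b in range(min(q_up - a, n_down) + 1):
            w_plus = math.comb(q_up, a) * math.comb(q_up - a, b)
            for c in range(min(q_down, n_up - a) + 1):
                for d in range(min(q_down - c, n_down - b) + 1):
                    u_rest = n_up - a - c
                    d_rest = n_down - b - d
                    if u_rest > r or d_rest > r - u_rest:
                        continue
                    w = (
                        w_plus
                        * math.comb(q_down, c)
                        * math.comb(q_down - c, d)
                        * math.comb(r, u_rest)
                        * math.comb(r - u_rest, d_rest)
                    )
                    numer[(a - b) + (d - c) + offset] += w
    scores = np.arange(-offset, offset + 1)
    pmf = np.array([n / denom for n in numer], dtype=float)
    keep = pmf > 0
    if not keep.any():  # degenerate: no mass (cannot happen for valid margins)
        raise ContractViolation("inconsistent margins: empty null support")
    return NullDistribution(scores[keep], pmf[keep])


def _null_vectorized(q_up, q_down, n_total, n_up, n_down) -> NullDistribution:
    """Broadcast log-space evaluation of the same summation (large margins)."""
    r = n_total - q_up - q_down

    def lcomb(n, k):
        n = np.asarray(n, dtype=float)
        k = np.asarray(k, dtype=float)
        bad = (k < 0) | (k > n) | (n < 0)
        kk = np.where(bad, 0.0, k)
        nn = np.where(bad, 0.0, n)
        out = gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)
        return np.where(bad, -np.inf, out)

    a = np.arange(min(q_up, n_up) + 1)[:, None, None, None]
    b = np.arange(min(q_up, n_down) + 1)[None, :, None, None]
    c = np.arange(min(q_down, n_up) + 1)[None, None, :, None]
    d = np.arange(min(q_down, n_down) + 1)[None, None, None, :]
    u_rest = n_up - a - c
    d_rest = n_down - b - d
    logw = (
        lcomb(q_up, a)
        + lcomb(q_up - a, b)
        + lcomb(q_down, c)
        + lcomb(q_down - c, d)
        + lcomb(r, u_rest)
        + lcomb(r - u_rest, d_rest)
        - lcomb(n_total, n_up)
        - lcomb(n_total - n_up, n_down)
    )
    w = np.exp(logw)
    offset = n_up + n_down
    s_idx = ((a - b) + (d - c) + offset) * np.ones_like(w, dtype=int)
    pmf = np.zeros(2 * offset + 1)
    np.add.at(pmf, s_idx.ravel(), w.ravel())
    scores = np.arange(-offset, offset + 1)
    keep = pmf > 0
    return NullDistribution(scores[keep], pmf[keep])


def correctness_null(
    q_up: int,
    q_down: int,
    n_total: int,
    n_up: int,
    n_down: int,
    method: str = "auto",
) -> NullDistribution:
    """Exact null distribution of S under random label re-assignment.

    ``method``: "exact" (integer reference summation), "vectorized"
    (log-space broadcast, identical to the reference within 1e-12), or
    "auto" (exact for small problems, vectorized beyond ~20k terms).
    """
    _check_margins(q_up, q_down, n_total, n_up, n_down)
    if q_up + q_down == 0 or n_up + n_down == 0:
        # Degenerate null: no label can land downstream, S is identically 0.
        return NullDistribution(np.array([0]), np.array([1.0]))
    cells = (
        (min(q_up, n_up) + 1)
        * (min(q_up, n_down) + 1)
        * (min(q_down, n_up) + 1)
        * (min(q_down, n_down) + 1)
    )
    if method == "exact" or (method == "auto" and cells <= 20_000):
        return _null_exact_int(q_up, q_down, n_total, n_up, n_down)
    if method in ("vectorized", "auto"):
        return _null_vectorized(q_up, q_down, n_total, n_up, n_down)
    raise ValueError(f"unknown method {method!r}")


def correctness_pvalue(
    breakdown: ScoreBreakdown,
    sizes: tuple[int, int],
    obs_margins: tuple[int, int, int],
    method: str = "auto",
) -> tuple[float, NullDistribution]:
    """P(S >= observed score) under the exact re-assignment null.

    ``sizes`` is (q+, q-), the non-ambiguous downstream set sizes;
    ``obs_margins`` is (N, n+, n-).
    """
    q_up, q_down = sizes
    n_total, n_up, n_down = obs_margins
    if breakdown.correct + breakdown.incorrect > q_up + q_down:
        raise ContractViolation("correct+incorrect exceeds the downstream set size")
    if breakdown.correct + breakdown.incorrect > n_up + n_down:
        raise ContractViolation("correct+incorrect exceeds the number of changed transcripts")
    null = correctness_null(q_up, q_down, n_total, n_up, n_down, method=method)
    return null.pvalue(breakdown.score), null


def enrichment_pvalue(
    breakdown: ScoreBreakdown,
    downstream_size: int,
    obs_margins: tuple[int, int],
    include_ambiguous: bool = False,
) -> float:
    """One-sided hypergeometric tail for the downstream/changed 2x2 overlap.

    Probability of drawing at least (correct + incorrect) changed transcripts
    when ``downstream_size`` transcripts are drawn from a universe of N
    containing ``n_changed`` changed ones. By default the draw is the
    non-ambiguous downstream set (the only place correct/incorrect counts can
    arise); ``include_ambiguous`` widens both the draw and the overlap.
    """
    n_total, n_changed = obs_margins
    if downstream_size > n_total or n_changed > n_total:
        raise ContractViolation("downstream or changed count exceeds universe size")
    overlap = breakdown.correct + breakdown.incorrect
    if include_ambiguous:
        overlap += breakdown.ambiguous
    if overlap > downstream_size:
        raise ContractViolation("overlap exceeds downstream set size")
    return float(hypergeom.sf(overlap - 1, n_total, n_changed, downstream_size))


def score_hypothesis(
    h: Hypothesis,
    graph: CausalGraph,
    obs: ObservationSet,
    depth: int = 1,
    include_ambiguous_in_enrichment: bool = False,
) -> HypothesisResult:
    """Score a single hypothesis against the observations."""
    profile = predict_downstream(h, graph, depth=depth, universe=obs.universe)
    breakdown = classify_predictions(profile, obs)
    q_up, q_down, q_amb = profile.q_up, profile.q_down, profile.q_ambiguous
    cp, _ = correctness_pvalue(
        breakdown, (q_up, q_down), (obs.n_total, obs.n_up, obs.n_down)
    )
    draw = q_up + q_down + (q_amb if include_ambiguous_in_enrichment else 0)
    ep = enrichment_pvalue(
        breakdown,
        draw,
        (obs.n_total, obs.n_changed),
        include_ambiguous=include_ambiguous_in_enrichment,
    )
    return HypothesisResult(h, breakdown, cp, ep, q_up, q_down, q_amb)


def score_all_hypotheses(
    graph: CausalGraph,
    obs: ObservationSet,
    depth: int = 1,
    thresholds: tuple[float, float] = (1e-5, 1e-5),
    add_bh: bool = False,
) -> list[HypothesisResult]:
    """Score every hypothesis and return the ranked significant survivors.

    Hypotheses failing either p-value threshold (correctness, enrichment) are
    removed; survivors are sorted by score descending, ties broken by
    enrichment p ascending, then node id, then Up before Down. Thresholds of
    1.0 keep everything. ``add_bh`` attaches Benjamini-Hochberg adjusted
    correctness p-values (over all hypotheses, pre-filter) as attribute
    ``correctness_p_bh`` on each result.
    """
    correctness_p_max, enrichment_p_max = thresholds
    results = [
        score_hypothesis(h, graph, obs, depth=depth)
        for h in enumerate_hypotheses(graph)
    ]
    if add_bh and results:
        _, bh, _, _ = multipletests(
            [r.correctness_p for r in results], method="fdr_bh"
        )
        for r, p in zip(results, bh):
            r.correctness_p_bh = float(p)
    survivors = [
        r
        for r in results
        if r.correctness_p <= correctness_p_max and r.enrichment_p <= enrichment_p_max
    ]
    survivors.sort(
        key=lambda r: (-r.score, r.enrichment_p, r.hypothesis.node, -r.hypothesis.direction)
    )
    return survivors


def annotation_proportion(
    results: Sequence[HypothesisResult] | pd.DataFrame,
    annotated: Iterable[str],
    k: int,
) -> float:
    """Fraction of the top-k ranked driver nodes present in an annotation list."""
    if k <= 0:
        raise ContractViolation("k must be positive")
    if isinstance(results, pd.DataFrame):
        nodes = list(results["node"])
    else:
        nodes = [r.hypothesis.node for r in results]
    if k > len(nodes):
        raise ContractViolation(f"k={k} exceeds the number of results ({len(nodes)})")
    annotated = set(annotated)
    return sum(1 for n in nodes[:k] if n in annotated) / k


def results_to_frame(results: Sequence[HypothesisResult]) -> pd.DataFrame:
    """Ranked results as a driver table (one row per retained hypothesis)."""
    return pd.DataFrame(
        {
            "node": [r.hypothesis.node for r in results],
            "direction": [r.hypothesis.label for r in results],
            "correct": [r.breakdown.correct for r in results],
            "incorrect": [r.breakdown.incorrect for r in results],
            "ambiguous": [r.breakdown.ambiguous for r in results],
            "score": [r.score for r in results],
            "correctness_p": [r.correctness_p for r in results],
            "enrichment_p": [r.enrichment_p for r in results],
            "q_up": [r.q_up for r in results],
            "q_down": [r.q_down for r in results],
            "q_ambig": [r.q_ambiguous for r in results],
        }
    )


def write_results(results: Sequence[HypothesisResult], path, fmt: str = "tsv") -> None:
    """Serialize a ranked result table as TSV or JSON (identical fields)."""
    df = results_to_frame(results)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")
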