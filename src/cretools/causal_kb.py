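"""Signed causal knowledge bases and downstream-prediction profiles.

A knowledge base is a multiset of curated causal statements of the form
"A increases B" / "A decreases B", each tied to a literature reference.
Statements form a signed directed multigraph over biological entities.
A *hypothesis* is an entity together with an assumed direction of activity
change (Up or Down); its *prediction profile* is the ternary pattern of
transcriptional changes (+1, -1, or ambiguous) it implies for transcripts
reachable within a configurable propagation radius.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, ContractViolation, StatementParseError

#: Sentinel for a prediction whose shortest signed paths disagree. Zero is
#: convenient: it can never be mistaken for a directional prediction, and the
#: scoring layer treats it as "reachable but uninformative".
AMBIGUOUS = 0

UP = 1
DOWN = -1

_RELATION_TOKENS = {"increases": UP, "decreases": DOWN}

#: Default column names of a statement TSV.
STATEMENT_COLUMNS = ("source", "relation", "target", "target_layer", "provenance")


@dataclass(frozen=True)
class CausalStatement:
    """One signed edge: ``source`` increases (+1) or decreases (-1) ``target``."""

    source: str
    relation: int
    target: str
    target_layer: str = "transcript"
    provenance: str = ""

    def __post_init__(self):
        if self.relation not in (UP, DOWN):
            raise ValueError(f"relation must be +1 or -1, got {self.relation!r}")
        if not self.source or not self.target:
            raise ValueError("statement endpoints must be non-empty identifiers")

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class Hypothesis:
    """A candidate upstream driver: an entity plus an assumed activity direction."""

    node: str
    direction: int

    def __post_init__(self):
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be +1 or -1, got {self.direction!r}")

    @property
    def label(self) -> str:
        return "Up" if self.direction == UP else "Down"

    def flipped(self) -> "Hypothesis":
        return Hypothesis(self.node, -self.direction)


class CausalGraph:
    """Signed directed multigraph built from causal statements.

    Parallel edges are retained (the statement collection is a multiset);
    parallel edges of opposing sign between the same ordered pair are legal
    and later induce ambiguous predictions.
    """

    def __init__(self, statements: Sequence[CausalStatement]):
        if not statements:
            raise ValueError("cannot build a causal graph from zero statements")
        self.statements: tuple[CausalStatement, ...] = tuple(statements)
        self.nodes: set[str] = set()
        self.transcript_nodes: set[str] = set()
        # adjacency: source -> target -> set of edge signs (dedup same-sign parallels)
        self._adj: dict[str, dict[str, set[int]]] = {}
        for s in self.statements:
            self.nodes.add(s.source)
            self.nodes.add(s.target)
            if s.target_layer == "transcript":
                self.transcript_nodes.add(s.target)
            self._adj.setdefault(s.source, {}).setdefault(s.target, set()).add(s.relation)

    @property
    def n_edges(self) -> int:
        return len(self.statements)

    def out_signs(self, node: str) -> Mapping[str, set[int]]:
        """Deduplicated edge signs from ``node`` to each direct target."""
        return self._adj.get(node, {})

    def source_nodes(self) -> list[str]:
        """Nodes with at least one outgoing edge, sorted."""
        return sorted(self._adj)

    def sign_conflicts(self) -> list[tuple[str, str]]:
        """Ordered pairs connected by parallel edges of opposing sign."""
        return sorted(
            (u, v)
            for u, targets in self._adj.items()
            for v, signs in targets.items()
            if len(signs) == 2
        )

    def self_loops(self) -> list[CausalStatement]:
        return [s for s in self.statements if s.is_self_loop]


@dataclass
class PredictionProfile:
    """Ternary downstream predictions of one hypothesis.

    ``predictions`` maps transcript id -> +1 / -1 / AMBIGUOUS. The hypothesis
    node itself is never a key (a driver does not explain its own transcript).
    """

    hypothesis: Hypothesis
    predictions: dict[str, int]
    depth: int = 1

    @property
    def q_up(self) -> int:
        return sum(1 for v in self.predictions.values() if v == UP)

    @property
    def q_down(self) -> int:
        return sum(1 for v in self.predictions.values() if v == DOWN)

    @property
    def q_ambiguous(self) -> int:
        return sum(1 for v in self.predictions.values() if v == AMBIGUOUS)

    def restricted_to(self, universe: Iterable[str]) -> "PredictionProfile":
        allowed = set(universe)
        return PredictionProfile(
            self.hypothesis,
            {t: v for t, v in self.predictions.items() if t in allowed},
            self.depth,
        )


def parse_statement_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[CausalStatement]:
    """Read a causal-statement TSV into a list of :class:`CausalStatement`.

    The file must carry a header with columns ``source, relation, target`` and
    optionally ``target_layer`` and ``provenance``; ``dialect`` maps these
    canonical names to the file's actual column names. Lines starting with
    ``#`` are comments. Relation tokens are matched case-insensitively.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    colmap = {canon: dialect.get(canon, canon) for canon in STATEMENT_COLUMNS}
    for canon in ("source", "relation", "target"):
        if colmap[canon] not in df.columns:
            raise ConfigurationError(
                f"statement table {path} lacks required column {colmap[canon]!r}"
            )
    has_layer = colmap["target_layer"] in df.columns
    has_prov = colmap["provenance"] in df.columns

    statements: list[CausalStatement] = []
    # +2: one for the header line, one for 1-based numbering.
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        token = rowd[colmap["relation"]].strip().lower()
        if token not in _RELATION_TOKENS:
            raise StatementParseError(
                f"unknown relation token {rowd[colmap['relation']]!r} "
                f"(expected increases/decreases)",
                line=i + 2,
            )
        source = rowd[colmap["source"]].strip()
        target = rowd[colmap["target"]].strip()
        if not source or not target:
            raise StatementParseError("empty source or target identifier", line=i + 2)
        statements.append(
            CausalStatement(
                source=source,
                relation=_RELATION_TOKENS[token],
                target=target,
                target_layer=(rowd[colmap["target_layer"]].strip() or "transcript")
                if has_layer
                else "transcript",
                provenance=rowd[colmap["provenance"]].strip() if has_prov else "",
            )
        )
    return statements


def write_statement_table(statements: Sequence[CausalStatement], path) -> None:
    """Write statements in the canonical five-column TSV layout."""
    df = pd.DataFrame(
        {
            "source": [s.source for s in statements],
            "relation": ["increases" if s.relation == UP else "decreases" for s in statements],
            "target": [s.target for s in statements],
            "target_layer": [s.target_layer for s in statements],
            "provenance": [s.provenance for s in statements],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def build_graph(statements: Sequence[CausalStatement]) -> CausalGraph:
    """Assemble the signed multigraph; see :class:`CausalGraph`."""
    if not statements:
        raise ValueError("cannot build a causal graph from zero statements")
    return CausalGraph(statements)


def enumerate_hypotheses(graph: CausalGraph) -> list[Hypothesis]:
    """Two hypotheses (Up then Down) per node with outgoing edges, node-sorted."""
    return [
        Hypothesis(node, direction)
        for node in graph.source_nodes()
        for direction in (UP, DOWN)
    ]


def predict_downstream(
    h: Hypothesis,
    graph: CausalGraph,
    depth: int = 1,
    universe: Iterable[str] | None = None,
) -> PredictionProfile:
    """Ternary predictions for transcripts reachable within ``depth`` edges.

    Sign propagation follows shortest paths only: the predicted change of a
    transcript t at distance d is ``h.direction`` times the product of edge
    signs along a shortest path; if shortest paths disagree in sign the
    prediction is :data:`AMBIGUOUS`. Same-sign parallel edges count once.
    Transcripts beyond ``depth`` are absent; the hypothesis node itself is
    excluded. ``universe=None`` means all transcript nodes of the graph.
    """
    if h.node not in graph.nodes:
        raise KeyError(f"hypothesis node {h.node!r} not in graph")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    # BFS over nodes tracking the set of achievable shortest-path signs.
    # signs[v] is {+1}, {-1} or {+1,-1}; a node at a strictly shorter distance
    # is final and never revisited.
    dist: dict[str, int] = {h.node: 0}
    signs: dict[str, set[int]] = {h.node: {1}}
    frontier = deque([h.node])
    while frontier:
        u = frontier.popleft()
        d = dist[u]
        if d >= depth:
            continue
        for v, edge_signs in graph.out_signs(u).items():
            new = {su * se for su in signs[u] for se in edge_signs}
            if v not in dist:
                dist[v] = d + 1
                signs[v] = set(new)
                frontier.append(v)
            elif dist[v] == d + 1:
                signs[v] |= new

    predictions: dict[str, int] = {}
    for v, sgn in signs.items():
        if v == h.node or v not in graph.transcript_nodes:
            continue
        predictions[v] = AMBIGUOUS if len(sgn) > 1 else h.direction * next(iter(sgn))

    profile = PredictionProfile(h, predictions, depth)
    if universe is not None:
        profile = profile.restricted_to(universe)
    return profile


def predict_downstream_bruteforce(
    h: Hypothesis, graph: CausalGraph, depth: int = 1
) -> dict[str, int]:
    """All-simple-paths reference for :func:`predict_downstream` (tests only).

    Enumerates every simple path of length <= depth, keeps only the paths of
    minimal length per endpoint, and combines their sign products. Exponential;
    intended for graphs of a dozen nodes.
    """
    best_len: dict[str, int] = {}
    best_signs: dict[str, set[int]] = {}

    def walk(node: str, length: int, sign: int, visited: set[str]):
        if length > 0 and node in graph.transcript_nodes and node != h.node:
            if node not in best_len or length < best_len[node]:
                best_len[node] = length
                best_signs[node] = {sign}
            elif length == best_len[node]:
                best_signs[node].add(sign)
        if length == depth:
            return
        for v, edge_signs in graph.out_signs(node).items():
            if v in visited:
                continue
            for es in edge_signs:
                walk(v, length + 1, sign * es, visited | {v})

    walk(h.node, 0, h.direction, {h.node})
    # Cycles can make a "simple shortest path" differ from BFS shortest only
    # when revisiting is involved; self-avoidance matches BFS on DAG-like KBs.
    return {
        t: (AMBIGUOUS if len(s) > 1 else next(iter(s))) for t, s in best_signs.items()
    }
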