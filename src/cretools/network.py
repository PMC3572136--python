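"""Driver networks: connecting significant upstream regulators through the KB.

Significant hypotheses are linked by any knowledge-base statement between
their entities (either sign, either direction - the sign matters for
prediction, not for connectivity), partitioned into connected components,
and summarized by how much of the observed transcriptional change they
jointly explain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .causal_kb import AMBIGUOUS, CausalGraph, Hypothesis, predict_downstream
from .errors import ContractViolation, UndefinedFraction
from .scoring import HypothesisResult, ObservationSet

__all__ = [
    "DriverNetwork",
    "build_driver_network",
    "largest_connected_component",
    "shared_downstream_targets",
    "explained_fraction",
]


@dataclass
class DriverNetwork:
    """Undirected view of the causal links among significant driver nodes."""

    graph: nx.Graph
    components: list[list[str]]  # each sorted; list sorted by (-size, first member)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "relation": d.get("relation", "")}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "relation"]).sort_values(
            ["source", "target"], ignore_index=True
        )

    def component_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": range(len(self.components)),
                "size": [len(c) for c in self.components],
                "members": [",".join(c) for c in self.components],
            }
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def _sorted_components(g: nx.Graph) -> list[list[str]]:
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def build_driver_network(
    results: Sequence[HypothesisResult],
    graph: CausalGraph,
    p_max: float = 1e-4,
    p_field: str = "correctness_p",
) -> DriverNetwork:
    """Network over hypothesis nodes with ``p_field`` < ``p_max``.

    Edges are KB statements between retained nodes, ignoring sign and
    orientation for connectivity. When both directions of a node survive, the
    one with the smaller p (then higher score) labels the node.
    """
    if p_field not in ("correctness_p", "enrichment_p"):
        raise ValueError(f"unknown p_field {p_field!r}")
    best: dict[str, HypothesisResult] = {}
    for r in results:
        if getattr(r, p_field) >= p_max:
            continue
        node = r.hypothesis.node
        prev = best.get(node)
        if prev is None or (getattr(r, p_field), -r.score) < (
            getattr(prev, p_field),
            -prev.score,
        ):
            best[node] = r
    g = nx.Graph()
    for node, r in best.items():
        g.add_node(
            node,
            direction=r.hypothesis.label,
            score=r.score,
            correctness_p=r.correctness_p,
            enrichment_p=r.enrichment_p,
        )
    for s in graph.statements:
        if s.source in best and s.target in best and s.source != s.target:
            rel = "increases" if s.relation == 1 else "decreases"
            if g.has_edge(s.source, s.target):
                # keep first relation label; connectivity is what matters
                continue
            g.add_edge(s.source, s.target, relation=rel)
    return DriverNetwork(g, _sorted_components(g))


def largest_connected_component(net: DriverNetwork) -> DriverNetwork:
    """Subnetwork induced by the largest component.

    Size ties are broken toward the component containing the
    lexicographically smallest node (components are pre-sorted that way).
    """
    if net.n_nodes == 0:
        return DriverNetwork(nx.Graph(), [])
    members = net.components[0]
    sub = net.graph.subgraph(members).copy()
    return DriverNetwork(sub, _sorted_components(sub))


def shared_downstream_targets(
    hypotheses: Sequence[Hypothesis],
    graph: CausalGraph,
    obs: ObservationSet | None = None,
    min_share: int = 2,
    depth: int = 1,
) -> pd.DataFrame:
    """Transcripts non-ambiguously predicted by at least ``min_share`` hypotheses.

    Returns one row per such transcript with the number of supporting
    hypotheses, each hypothesis's predicted sign (0 where it makes no
    prediction), and the observed call when observations are supplied.
    """
    if len(hypotheses) < 2:
        raise ContractViolation("need at least two hypotheses to share targets")
    if min_share > len(hypotheses):
        raise ContractViolation("min_share exceeds the number of hypotheses")
    universe = obs.universe if obs is not None else None
    profiles = [
        predict_downstream(h, graph, depth=depth, universe=universe)
        for h in hypotheses
    ]
    support: dict[str, dict[str, int]] = {}
    for h, p in zip(hypotheses, profiles):
        col = f"{h.node}_{h.label}"
        for t, v in p.predictions.items():
            if v == AMBIGUOUS:
                continue
            support.setdefault(t, {})[col] = v
    rows = []
    for t, preds in sorted(support.items()):
        if len(preds) < min_share:
            continue
        row = {"transcript": t, "share": len(preds)}
        for h in hypotheses:
            col = f"{h.node}_{h.label}"
            row[col] = preds.get(col, 0)
        if obs is not None:
            row["observed"] = obs.calls.get(t, 0)
        rows.append(row)
    cols = ["transcript", "share"] + [f"{h.node}_{h.label}" for h in hypotheses]
    if obs is not None:
        cols.append("observed")
    return pd.DataFrame(rows, columns=cols)


def explained_fraction(
    hypotheses: Sequence[Hypothesis],
    graph: CausalGraph,
    obs: ObservationSet,
    depth: int = 1,
) -> float:
    """Fraction of changed transcripts correctly explained by >= 1 hypothesis.

    Union semantics: a transcript counts once no matter how many hypotheses
    explain it, and a correct explanation is not cancelled by another
    hypothesis's incorrect one.
    """
    changed = obs.changed()
    if not changed:
        raise UndefinedFraction("no changed transcripts: explained fraction undefined")
    explained: set[str] = set()
    for h in hypotheses:
        profile = predict_downstream(h, graph, depth=depth, universe=obs.universe)
        for t, v in profile.predictions.items():
            if v != AMBIGUOUS and obs.calls[t] == v:
                explained.add(t)
    return len(explained) / len(changed)
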