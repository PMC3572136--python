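import numpy as np
import pandas as pd
import pytest

from cretools.causal_kb import CausalStatement, build_graph


def stmt(src, rel, tgt, layer="transcript"):
    return CausalStatement(src, rel, tgt, layer, "PMID:0")


@pytest.fixture
def chain_graph():
    """A increases B, A decreases C, B increases D."""
    return build_graph([stmt("A", 1, "B"), stmt("A", -1, "C"), stmt("B", 1, "D")])


@pytest.fixture
def conflict_graph():
    """A both increases and decreases D."""
    return build_graph([stmt("A", 1, "D"), stmt("A", -1, "D")])


def random_graph(rng, n_nodes=8, n_edges=16):
    """Small random signed multigraph for property tests."""
    names = [f"N{i}" for i in range(n_nodes)]
    statements = []
    for _ in range(n_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        statements.append(stmt(names[u], int(rng.choice([1, -1])), names[v]))
    return build_graph(statements)


@pytest.fixture
def toy_matrix():
    """6 features x (3 timepoints x 3 replicates), log2 scale, no signal."""
    rng = np.random.default_rng(7)
    cols = pd.MultiIndex.from_product(
        [["D0", "D8", "D11"], ["A", "B", "C"]], names=["timepoint", "replicate"]
    )
    vals = rng.normal(8, 0.3, size=(6, 9))
    from cretools.preprocess import TimecourseMatrix

    return TimecourseMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(6)], columns=cols)
    )
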