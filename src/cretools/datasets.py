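"""Small built-in example tables.

Currently one dataset: a published top-20 ranking of protein causal drivers
from a causal-reasoning analysis of pancreatic endocrine differentiation
(gene expression changes between day 8 and day 11 of an hESC-derived
differentiation), with per-driver correct / incorrect / ambiguous
explanation counts and a note marking drivers already associated with
beta-cell function. Used as a worked example of the ranking rule
(score = correct - incorrect, non-increasing down the table) and of
annotation-proportion summaries.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["example_driver_ranking"]

_DRIVER_RANKING_TSV = """\
node\tdirection\tcorrect\tincorrect\tambiguous\tnotes
IL6\tUp\t47\t9\t2\t
CDKN1A\tDown\t39\t7\t2\t-ve growth, +ve apoptosis
THAP1\tDown\t29\t0\t0\t
IL1B\tUp\t48\t20\t5\t-ve growth, +ve apoptosis
NEUROG3\tUp\t29\t3\t1\t+ve differentiation
EGF\tUp\t29\t9\t3\t+ve growth
NCOR1\tDown\t22\t2\t0\t
IL1A\tUp\t35\t16\t2\t
TP53\tDown\t36\t18\t2\t+ve apoptosis
HRAS\tUp\t25\t8\t2\t+ve apoptosis
SOCS3\tDown\t18\t2\t0\t-ve growth
TNFSF11\tUp\t18\t2\t0\t
E2F1\tUp\t18\t2\t1\t+ve differentiation
RET\tUp\t21\t6\t0\t
SMAD3\tUp\t17\t5\t0\t-ve differentiation
KDM5B\tDown\t16\t4\t0\t
CXCR7\tDown\t14\t2\t0\t
RB1\tDown\t12\t1\t0\t-ve growth
TCF3\tDown\t13\t2\t1\t-ve apoptosis
COL18A1\tDown\t12\t1\t0\t
"""


def example_driver_ranking() -> pd.DataFrame:
    """The example top-20 driver table, in ranked order, with a score column.

    Columns: node, direction (Up/Down), correct, incorrect, ambiguous,
    notes (empty when the driver had no prior beta-cell-function
    association), score (= correct - incorrect).
    """
    df = pd.read_csv(
        io.StringIO(_DRIVER_RANKING_TSV), sep="\t", keep_default_na=False
    )
    df["score"] = df["correct"] - df["incorrect"]
    return df
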