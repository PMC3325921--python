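"""Packaged reference panel: the published top-20 weighted-score table.

Twenty probe sets from the in vivo genotoxin study (mouse liver, 7 GTX + 3
NGTX), each with its eight raw parameter values, the corresponding 0-5
component scores, the weighted total and the gene symbol.  The highest
scorer is the murine endogenous retrovirus transcript BC005512 (probe set
1426936_at, total 32.0).  These rows serve two roles: a frozen oracle for
the weighted-total arithmetic, and the constraint set from which the default
score-bin tables are inferred.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

#: Parameter keys in table order.
PARAMETERS = (
    "specificity",
    "ave_ratio",
    "positive_condition",
    "positive_chemical",
    "p_value",
    "basal",
    "reverse_change",
    "cv_percent",
)

#: Weight of each component score in the total.
WEIGHTS = {
    "specificity": 2.0,
    "ave_ratio": 1.0,
    "positive_condition": 1.0,
    "positive_chemical": 1.0,
    "p_value": 1.0,
    "basal": 0.5,
    "reverse_change": 0.5,
    "cv_percent": 0.5,
}


@lru_cache(maxsize=1)
def reference_table() -> pd.DataFrame:
    """The 20-row reference panel, indexed by probe_id."""
    with resources.files("gtxscore.data").joinpath("reference_scores.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="probe_id")
    assert len(df) == 20
    return df


def reference_pairs() -> list[tuple[str, float, int]]:
    """All (parameter, value, score) constraints from the reference panel."""
    df = reference_table()
    pairs = []
    for param in PARAMETERS:
        for value, score in zip(df[param], df[f"{param}_score"]):
            pairs.append((param, float(value), int(score)))
    return pairs
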