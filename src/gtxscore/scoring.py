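"""Weighted multi-parameter scoring of candidate genotoxin-responsive genes.

Eight per-gene parameters are computed from the call matrix and the control
samples:

* specificity — up-calls in GTX cells over all up-calls;
* ave ratio — mean treated/control ratio over GTX up-calls;
* positive condition — replication-weighted count of GTX up-calls
  (a duplicated chemical's cells count 0.5 each);
* positive chemical — distinct GTX chemicals with at least one up-call;
* p value — two-sample t test of normalized treatment intensity, GTX vs
  NGTX conditions (Welch by default);
* basal — log10 intensity over control animals;
* reverse change — NGTX down-calls minus GTX down-calls;
* CV% — 100 x SD / mean of control-animal intensity.

Each parameter is mapped to an integer component score 0-5 through a
monotone piecewise-constant bin table, and the component scores combine as

    total = 2*S_spec + S_ratio + S_cond + S_chem + S_p
            + 0.5*(S_basal + S_rev + S_cv)

so the maximum attainable total is 37.5.  Genes with no up-call anywhere —
or none in GTX cells, which leaves the average ratio undefined — are
excluded from the ranking rather than scored zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .calls import DOWN, UP, CallCriteria, build_call_matrix, normalize
from .design import GTX, NGTX
from .exceptions import UndefinedParameterError, ValidationError
from .reference import PARAMETERS, WEIGHTS, reference_pairs, reference_table
from .simulate import ExpressionDataset

HIGHER = "higher-better"
LOWER = "lower-better"

#: Better direction of each raw parameter.
DIRECTIONS = {
    "specificity": HIGHER,
    "ave_ratio": HIGHER,
    "positive_condition": HIGHER,
    "positive_chemical": HIGHER,
    "p_value": LOWER,
    "basal": HIGHER,
    "reverse_change": HIGHER,
    "cv_percent": LOWER,
}

#: Natural domain of each parameter (inclusive bounds; inf = unbounded).
DOMAINS = {
    "specificity": (0.0, 1.0),
    "ave_ratio": (0.0, math.inf),
    "positive_condition": (0.0, math.inf),
    "positive_chemical": (0.0, math.inf),
    "p_value": (0.0, 1.0),
    "basal": (-math.inf, math.inf),
    "reverse_change": (-math.inf, math.inf),
    "cv_percent": (0.0, math.inf),
}


# ---------------------------------------------------------------------------
# Scalar parameter operations


def specificity(calls: Sequence[str], klass: Sequence[str]) -> float:
    """Fraction of a gene's up-calls that fall in GTX cells."""
    up = np.asarray(calls) == UP
    k = np.asarray(klass)
    total = int(up.sum())
    if total == 0:
        raise UndefinedParameterError("specificity undefined: no up-calls")
    return float(up[k == GTX].sum() / total)


def ave_ratio(calls: Sequence[str], klass: Sequence[str], ratios: Sequence[float]) -> float:
    """Unweighted mean treated/control ratio over GTX up-calls."""
    up = (np.asarray(calls) == UP) & (np.asarray(klass) == GTX)
    if not up.any():
        raise UndefinedParameterError("ave_ratio undefined: no GTX up-calls")
    return float(np.asarray(ratios, dtype=float)[up].mean())


def positive_condition(
    calls: Sequence[str], klass: Sequence[str], weights: Sequence[float]
) -> float:
    """Replication-weighted count of GTX up-calls."""
    up = (np.asarray(calls) == UP) & (np.asarray(klass) == GTX)
    return float(np.asarray(weights, dtype=float)[up].sum())


def positive_chemical(
    calls: Sequence[str], klass: Sequence[str], chemicals: Sequence[str]
) -> int:
    """Distinct GTX chemicals with at least one up-call (duplicates count once)."""
    up = (np.asarray(calls) == UP) & (np.asarray(klass) == GTX)
    return len(set(np.asarray(chemicals)[up]))


def reverse_change(calls: Sequence[str], klass: Sequence[str]) -> float:
    """NGTX down-calls minus GTX down-calls (negative = GTX-directional loss)."""
    down = np.asarray(calls) == DOWN
    k = np.asarray(klass)
    return float(down[k == NGTX].sum() - down[k == GTX].sum())


def group_p_value(
    gtx_values: Sequence[float],
    ngtx_values: Sequence[float],
    equal_var: bool = False,
) -> float:
    """Two-sided two-sample t test of intensity, GTX vs NGTX conditions.

    Degenerate inputs (both groups zero-variance) return 1.0 when the means
    agree and 0.0 otherwise, by convention.
    """
    a = np.asarray(gtx_values, dtype=float)
    b = np.asarray(ngtx_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("t test needs at least two values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p)


def basal_expression(control_intensities: Sequence[float], log_of_mean: bool = True) -> float:
    """log10 basal level over control animals.

    ``log_of_mean=True`` (default) takes log10 of the mean intensity; the
    alternative averages per-animal log10 values.
    """
    x = np.asarray(control_intensities, dtype=float)
    if log_of_mean:
        m = x.mean()
        if m <= 0:
            raise ValidationError("basal undefined: non-positive mean intensity")
        return float(np.log10(m))
    if (x <= 0).any():
        raise ValidationError("basal undefined: non-positive intensity")
    return float(np.log10(x).mean())


def cv_percent(control_intensities: Sequence[float]) -> float:
    """100 x sample SD / mean over control animals."""
    x = np.asarray(control_intensities, dtype=float)
    if x.size < 2:
        raise ValidationError("CV needs at least two control animals")
    m = x.mean()
    if m <= 0:
        raise ValidationError("CV undefined: non-positive mean")
    return float(100.0 * x.std(ddof=1) / m)


def total_score(scores: Mapping[str, float] | Sequence[float]) -> float:
    """Weighted total of the eight component scores (max 37.5)."""
    if isinstance(scores, Mapping):
        missing = [p for p in PARAMETERS if p not in scores]
        if missing:
            raise ValidationError(f"missing component scores: {missing}")
        vec = [scores[p] for p in PARAMETERS]
    else:
        vec = list(scores)
        if len(vec) != len(PARAMETERS):
            raise ValidationError(f"expected {len(PARAMETERS)} component scores, got {len(vec)}")
    for s in vec:
        if not 0 <= s <= 5:
            raise ValidationError(f"component scores must be in 0..5, got {s}")
    return float(sum(WEIGHTS[p] * s for p, s in zip(PARAMETERS, vec)))


# ---------------------------------------------------------------------------
# Score bin tables


@dataclass(frozen=True)
class ScoreBinTable:
    """Monotone piecewise-constant map from a parameter value to a 0-5 score.

    ``edges`` are ascending interval boundaries; value ``v`` falls in interval
    ``i = #{e in edges : e <= v}`` and receives ``scores[i]``.  The first and
    last intervals extend to the parameter's domain bounds.
    """

    parameter: str
    direction: str
    edges: tuple[float, ...]
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise ValidationError(f"bad direction {self.direction!r}")
        if len(self.scores) != len(self.edges) + 1:
            raise ValidationError("need exactly one score per interval")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValidationError("edges must be strictly increasing")
        if any(not 0 <= s <= 5 for s in self.scores):
            raise ValidationError("scores must lie in 0..5")
        seq = self.scores if self.direction == HIGHER else self.scores[::-1]
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValidationError("scores must be monotone in the better direction")

    def lookup(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        lo, hi = DOMAINS.get(self.parameter, (-math.inf, math.inf))
        if ((v < lo) | (v > hi)).any():
            raise ValidationError(f"value outside {self.parameter} domain [{lo}, {hi}]")
        idx = np.searchsorted(np.asarray(self.edges), v, side="right")
        return np.asarray(self.scores)[idx]


def bin_score(value: float, table: ScoreBinTable) -> int:
    """Score a single parameter value with a bin table."""
    return int(table.lookup([value])[0])


def infer_bin_tables(
    pairs: Iterable[tuple[str, float, int]]
) -> dict[str, ScoreBinTable]:
    """Infer per-parameter bin tables from observed (parameter, value, score)
    pairs, placing interval boundaries at midpoints between the closest
    observed values with different scores.

    Raises with an explicit infeasibility report if any two pairs contradict
    each other (same value, different score) or the value/score relation is
    not monotone.
    """
    by_param: dict[str, dict[float, int]] = {}
    for param, value, score in pairs:
        seen = by_param.setdefault(param, {})
        if value in seen and seen[value] != score:
            raise ValidationError(
                f"infeasible bin table for {param!r}: value {value} maps to "
                f"both score {seen[value]} and score {score}"
            )
        seen[value] = int(score)

    tables: dict[str, ScoreBinTable] = {}
    for param, mapping in by_param.items():
        values = sorted(mapping)
        scores = [mapping[v] for v in values]
        direction = DIRECTIONS.get(param)
        if direction is None:  # infer from the data for unknown parameters
            trend = next((b - a for a, b in zip(scores, scores[1:]) if b != a), 1)
            direction = HIGHER if trend > 0 else LOWER
        step = 1 if direction == HIGHER else -1
        for (va, sa), (vb, sb) in zip(zip(values, scores), zip(values[1:], scores[1:])):
            if (sb - sa) * step < 0:
                raise ValidationError(
                    f"infeasible bin table for {param!r}: ({va}, {sa}) and "
                    f"({vb}, {sb}) break monotonicity"
                )
        edges, interval_scores = [], [scores[0]]
        for va, vb, sa, sb in zip(values, values[1:], scores, scores[1:]):
            if sb != sa:
                edges.append((va + vb) / 2.0)
                interval_scores.append(sb)
        tables[param] = ScoreBinTable(param, direction, tuple(edges), tuple(interval_scores))
    return tables


@lru_cache(maxsize=1)
def default_bin_tables() -> dict[str, ScoreBinTable]:
    """Bin tables inferred from the packaged reference panel."""
    return infer_bin_tables(reference_pairs())


def bins_to_yaml(tables: Mapping[str, ScoreBinTable], path: str | Path) -> None:
    doc = {
        name: {
            "direction": t.direction,
            "edges": [float(e) for e in t.edges],
            "scores": [int(s) for s in t.scores],
        }
        for name, t in tables.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def bins_from_yaml(path: str | Path) -> dict[str, ScoreBinTable]:
    doc = yaml.safe_load(Path(path).read_text())
    return {
        name: ScoreBinTable(name, spec["direction"], tuple(spec["edges"]), tuple(spec["scores"]))
        for name, spec in doc.items()
    }


# ---------------------------------------------------------------------------
# Vectorized per-gene parameter table and ranking


def gene_parameters(
    calls: pd.DataFrame,
    dataset: ExpressionDataset,
    equal_var: bool = False,
    basal_log_of_mean: bool = True,
) -> pd.DataFrame:
    """Raw parameter table for every gene with >= 1 GTX up-call.

    ``calls`` is the long-form call matrix; ``dataset`` the raw dataset from
    which it was built (controls are re-normalized per-chip here for basal
    and CV%, and the fully normalized treatment intensities feed the t test).
    Genes excluded from scoring are reported in ``result.attrs['excluded']``
    with the reason (``no_up_call`` or ``no_gtx_up_call``).
    """
    wide = calls.pivot(index="gene_id", columns="condition", values="call")
    up, down = wide.eq(UP), wide.eq(DOWN)
    ratio = calls.pivot(index="gene_id", columns="condition", values="ratio")
    meta = (
        calls[["condition", "chemical", "klass", "weight"]]
        .drop_duplicates("condition")
        .set_index("condition")
        .loc[up.columns]
    )
    gtx_cols = list(meta.index[meta["klass"] == GTX])
    ngtx_cols = list(meta.index[meta["klass"] == NGTX])

    n_up_gtx = up[gtx_cols].sum(axis=1)
    n_up_all = up.sum(axis=1)
    excluded = {
        "no_up_call": list(n_up_all.index[n_up_all == 0]),
        "no_gtx_up_call": list(n_up_all.index[(n_up_all > 0) & (n_up_gtx == 0)]),
    }
    keep = n_up_gtx > 0
    up, down, ratio = up[keep], down[keep], ratio[keep]
    n_up_gtx, n_up_all = n_up_gtx[keep], n_up_all[keep]

    spec = n_up_gtx / n_up_all
    avg = (ratio[gtx_cols] * up[gtx_cols]).sum(axis=1) / n_up_gtx
    pos_cond = (up[gtx_cols] * meta.loc[gtx_cols, "weight"]).sum(axis=1)
    pos_chem = (
        up[gtx_cols]
        .T.groupby(meta.loc[gtx_cols, "chemical"])
        .any()
        .sum(axis=0)
    )
    rev = down[ngtx_cols].sum(axis=1) - down[gtx_cols].sum(axis=1)

    # Normalized treatment intensities (two-step normalization) for the t test.
    full = normalize(dataset, per_gene=True)
    treated = full.intensities.loc[up.index]
    if len(gtx_cols) < 2 or len(ngtx_cols) < 2:
        raise ValidationError("t test needs >= 2 GTX and >= 2 NGTX conditions")
    res = stats.ttest_ind(
        treated[gtx_cols].to_numpy(),
        treated[ngtx_cols].to_numpy(),
        axis=1,
        equal_var=equal_var,
    )
    pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        same_mean = np.isclose(
            treated[gtx_cols].mean(axis=1)[degenerate],
            treated[ngtx_cols].mean(axis=1)[degenerate],
        )
        pvals[degenerate] = np.where(same_mean, 1.0, 0.0)

    # Basal and CV% over all control animals, per-chip normalized scale.
    chip_controls = normalize(dataset, per_gene=False).intensities.loc[
        up.index, dataset.all_control_ids
    ]
    ctrl_mean = chip_controls.mean(axis=1)
    if basal_log_of_mean:
        basal = np.log10(ctrl_mean)
    else:
        basal = np.log10(chip_controls).mean(axis=1)
    cv = 100.0 * chip_controls.std(axis=1, ddof=1) / ctrl_mean

    out = pd.DataFrame(
        {
            "specificity": spec,
            "ave_ratio": avg,
            "positive_condition": pos_cond,
            "positive_chemical": pos_chem.reindex(up.index),
            "p_value": pvals,
            "basal": basal,
            "reverse_change": rev,
            "cv_percent": cv,
        }
    )
    out.attrs["excluded"] = excluded
    return out


def score_parameters(
    params: pd.DataFrame, bin_tables: Mapping[str, ScoreBinTable] | None = None
) -> pd.DataFrame:
    """Append the eight component scores, the weighted total and the rank."""
    tables = bin_tables or default_bin_tables()
    out = params.copy()
    total = np.zeros(len(out))
    for param in PARAMETERS:
        s = tables[param].lookup(out[param].to_numpy())
        out[f"{param}_score"] = s
        total += WEIGHTS[param] * s
    out["total_score"] = total
    idcol = out.index.name or "gene_id"
    out = (
        out.rename_axis(idcol)
        .reset_index()
        .sort_values(["total_score", idcol], ascending=[False, True])
        .set_index(idcol)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs = dict(params.attrs)
    return out


def rank_genes(
    dataset: ExpressionDataset,
    criteria: CallCriteria | None = None,
    bin_tables: Mapping[str, ScoreBinTable] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Full pipeline: normalize, call, parameterize, bin, total and rank.

    Returns the scored table sorted by total score (descending), ties broken
    by gene id; excluded genes are listed in ``.attrs['excluded']``.
    """
    calls = build_call_matrix(dataset, criteria)
    params = gene_parameters(calls, dataset, equal_var=equal_var)
    return score_parameters(params, bin_tables)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t")


def rescore_reference() -> pd.DataFrame:
    """Recompute totals and ranks from the reference panel's component scores."""
    df = reference_table().copy()
    df["recomputed_total"] = [
        total_score({p: row[f"{p}_score"] for p in PARAMETERS}) for _, row in df.iterrows()
    ]
    df = (
        df.reset_index()
        .sort_values(["recomputed_total", "probe_id"], ascending=[False, True])
        .set_index("probe_id")
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df
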