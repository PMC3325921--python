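"""Closed-form statistics for the bench assays that validate a biomarker.

qPCR relative quantification (2^-ddCt), the comet-assay olive tail moment,
ordinary least-squares dose-response regression between expression and DNA
damage, and micronucleus frequency per 1000 cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class CtRecord:
    """Target/reference threshold cycles for one treated and one control sample."""

    treated_target: float
    treated_reference: float
    control_target: float
    control_reference: float

    def __post_init__(self) -> None:
        for v in (self.treated_target, self.treated_reference,
                  self.control_target, self.control_reference):
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValidationError("all four Ct values must be finite and positive")


def ddct_fold_change(rec: CtRecord) -> float:
    """2^-ddCt relative expression of the target gene, treated vs control."""
    dct_treated = rec.treated_target - rec.treated_reference
    dct_control = rec.control_target - rec.control_reference
    return float(2.0 ** -(dct_treated - dct_control))


def fold_of_control(values: Sequence[float], control: float) -> np.ndarray:
    """Normalize raw expression values to the control mean (folds of control)."""
    if control <= 0:
        raise ValidationError("control value must be positive")
    return np.asarray(values, dtype=float) / control


@dataclass(frozen=True)
class CometRecord:
    """One comet: tail length (um) and fraction of DNA in the tail."""

    tail_length: float
    dna_fraction_in_tail: float

    def __post_init__(self) -> None:
        if self.tail_length < 0:
            raise ValidationError("tail length must be >= 0")
        if not 0.0 <= self.dna_fraction_in_tail <= 1.0:
            raise ValidationError("DNA fraction in tail must lie in [0, 1]")

    @classmethod
    def from_percent(cls, tail_length: float, percent_dna_in_tail: float) -> "CometRecord":
        """Accept percentage-of-DNA input (Komet-style) and store the fraction."""
        return cls(tail_length, percent_dna_in_tail / 100.0)


def olive_tail_moment(rec: CometRecord) -> float:
    """Olive tail moment = tail length x fraction of DNA in the tail (um)."""
    return rec.tail_length * rec.dna_fraction_in_tail


def mean_olive_tail_moment(records: Sequence[CometRecord]) -> float:
    """Per-slide mean OTM over scored cells (typically >= 100 per group)."""
    if not records:
        raise ValidationError("need at least one comet record")
    return float(np.mean([olive_tail_moment(r) for r in records]))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def dose_response_regression(
    x: Sequence[float], y: Sequence[float]
) -> RegressionResult:
    """OLS of per-dose mean DNA damage on per-dose mean expression.

    ``r_squared`` is the squared Pearson correlation; a constant ``x`` is
    rejected, a constant ``y`` gives slope 0 and r^2 = 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 2:
        raise ValidationError("need >= 2 paired points")
    if np.ptp(xa) == 0:
        raise ValidationError("x must not be constant")
    if np.ptp(ya) == 0:
        return RegressionResult(0.0, float(ya[0]), 0.0, int(xa.size))
    fit = stats.linregress(xa, ya)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(xa.size),
    )


def micronucleus_frequency(mn_cells: int, total_cells: int) -> tuple[float, float]:
    """(per-cell fraction, rate per 1000 cells) of micronucleated cells."""
    if total_cells < 1:
        raise ValidationError("total_cells must be >= 1")
    if not 0 <= mn_cells <= total_cells:
        raise ValidationError("mn_cells must lie in [0, total_cells]")
    fraction = mn_cells / total_cells
    return fraction, 1000.0 * fraction
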