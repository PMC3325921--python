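"""Normalization, treated/control ratios and the up/down regulation calls.

Normalization is the two-step median scheme used for single-channel arrays:
per-chip, every sample is scaled so its median intensity is 1; per-gene,
every value is divided by the median of its matched solvent-control samples
(same solvent, same timepoint).  Treated/control ratios are invariant to the
per-gene step because the matched-control divisor cancels, so ratio-based
calls can be computed on per-chip-normalized data directly.

Calls use a step-wise, intensity-dependent criterion: the intensity axis is
partitioned into bands, each with its own ratio cut-off, so that dim genes
need a stronger fold change to be called.  The band is selected by the
matched-control mean intensity on the per-chip scale — the control side, not
the treated side, so a gene's ratio never influences its own threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .simulate import ExpressionDataset

UP = "up"
DOWN = "down"
NONE = "none"

CALL_COLUMNS = [
    "gene_id", "condition", "chemical", "klass", "timepoint",
    "weight", "control_intensity", "ratio", "call",
]


@dataclass(frozen=True)
class CallCriteria:
    """Ordered intensity bands with per-band ratio cut-offs.

    Each rule is ``(intensity_floor, ratio_cutoff)``; a band spans from its
    floor to the next rule's floor.  ``up_rules`` cut-offs must exceed 1,
    ``down_rules`` cut-offs must be below 1.  Floors must start at 0 and be
    strictly increasing (overlapping bands are rejected).
    """

    up_rules: tuple[tuple[float, float], ...] = ((0.0, 3.0), (0.5, 2.0))
    down_rules: tuple[tuple[float, float], ...] = ((0.0, 1.0 / 3.0), (0.5, 0.5))

    def __post_init__(self) -> None:
        for rules, kind in ((self.up_rules, "up"), (self.down_rules, "down")):
            if not rules:
                raise ValidationError(f"{kind}_rules must not be empty")
            floors = [f for f, _ in rules]
            if floors[0] != 0.0:
                raise ValidationError(f"{kind}_rules must start at intensity 0")
            if any(b <= a for a, b in zip(floors, floors[1:])):
                raise ValidationError(f"{kind}_rules bands overlap or are unordered")
        if any(r <= 1.0 for _, r in self.up_rules):
            raise ValidationError("up-rule ratio cut-offs must be > 1")
        if any(r >= 1.0 for _, r in self.down_rules):
            raise ValidationError("down-rule ratio cut-offs must be < 1")

    def up_cutoff(self, intensity: np.ndarray) -> np.ndarray:
        return _band_lookup(self.up_rules, intensity)

    def down_cutoff(self, intensity: np.ndarray) -> np.ndarray:
        return _band_lookup(self.down_rules, intensity)


def _band_lookup(rules: tuple[tuple[float, float], ...], intensity) -> np.ndarray:
    floors = np.array([f for f, _ in rules])
    cuts = np.array([r for _, r in rules])
    idx = np.searchsorted(floors, np.asarray(intensity, dtype=float), side="right") - 1
    if (idx < 0).any():
        raise ValidationError("negative intensity outside the band domain")
    return cuts[idx]


def default_criteria() -> CallCriteria:
    """Conservative-at-low-intensity defaults: ratio >= 3 (<= 1/3) below a
    per-chip-normalized control intensity of 0.5, ratio >= 2 (<= 0.5) above."""
    return CallCriteria()


# ---------------------------------------------------------------------------
# Normalization

def normalize(ds: ExpressionDataset, per_gene: bool = True) -> ExpressionDataset:
    """Per-chip (median-1) and optionally per-gene (matched-control median)
    normalization; gene and sample order are preserved."""
    x = ds.intensities.copy()
    medians = x.median(axis=0)
    if (medians <= 0).any():
        bad = list(medians.index[medians <= 0])
        raise ValidationError(f"samples with non-positive median intensity: {bad}")
    x = x / medians

    if per_gene:
        groups = ds.samples.groupby(["solvent", "timepoint"], sort=False).groups
        for (solvent, tp), sample_ids in groups.items():
            ctrl = ds.control_ids(solvent, tp)
            if not ctrl:
                raise ValidationError(f"no controls for solvent={solvent}, timepoint={tp}")
            ref = x[ctrl].median(axis=1)
            if (ref <= 0).any():
                raise ValidationError(
                    f"zero control median for some gene in group ({solvent}, {tp})"
                )
            x[list(sample_ids)] = x[list(sample_ids)].div(ref, axis=0)
    return ExpressionDataset(x, ds.samples.copy())


# ---------------------------------------------------------------------------
# Ratios and calls

def compute_ratios(ds: ExpressionDataset) -> pd.DataFrame:
    """Long-form call matrix with ratios only (``call`` = none).

    ``ratio`` is treated intensity over the mean of matched controls;
    ``control_intensity`` is that matched-control mean on the input scale and
    is what the intensity bands are applied to.
    """
    frames = []
    for cond_id in ds.treatment_ids:
        row = ds.samples.loc[cond_id]
        ctrl = ds.control_ids(row["solvent"], row["timepoint"])
        ctrl_mean = ds.intensities[ctrl].mean(axis=1)
        if (ctrl_mean <= 0).any():
            raise ValidationError(f"zero control mean for condition {cond_id}")
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": ds.intensities.index,
                    "condition": cond_id,
                    "chemical": row["chemical"],
                    "klass": row["klass"],
                    "timepoint": row["timepoint"],
                    "weight": float(row["weight"]),
                    "control_intensity": ctrl_mean.to_numpy(),
                    "ratio": (ds.intensities[cond_id] / ctrl_mean).to_numpy(),
                    "call": NONE,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_regulation(matrix: pd.DataFrame, criteria: CallCriteria) -> pd.DataFrame:
    """Assign up/down/none per cell from its band's ratio cut-offs."""
    out = matrix.copy()
    intensity = out["control_intensity"].to_numpy(dtype=float)
    ratio = out["ratio"].to_numpy(dtype=float)
    up_cut = criteria.up_cutoff(intensity)
    down_cut = criteria.down_cutoff(intensity)
    call = np.where(ratio >= up_cut, UP, np.where(ratio <= down_cut, DOWN, NONE))
    out["call"] = call
    return out


def build_call_matrix(
    ds: ExpressionDataset, criteria: CallCriteria | None = None
) -> pd.DataFrame:
    """Raw dataset -> per-chip normalization -> ratios -> calls."""
    chip = normalize(ds, per_gene=False)
    return call_regulation(compute_ratios(chip), criteria or default_criteria())


def write_calls(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Criteria config round-trip

def criteria_to_yaml(criteria: CallCriteria, path: str | Path) -> None:
    doc = {
        "up_rules": [list(map(float, r)) for r in criteria.up_rules],
        "down_rules": [list(map(float, r)) for r in criteria.down_rules],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def criteria_from_yaml(path: str | Path) -> CallCriteria:
    doc = yaml.safe_load(Path(path).read_text())
    return CallCriteria(
        up_rules=tuple(tuple(r) for r in doc["up_rules"]),
        down_rules=tuple(tuple(r) for r in doc["down_rules"]),
    )
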