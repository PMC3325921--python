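"""Seedable synthetic expression data with the panel's statistical structure.

The generator emits one pooled treatment intensity vector per treatment cell
and ``n_control_animals`` individual control vectors per solvent x timepoint,
on a multiplicative (log-normal) intensity scale:

* per-gene baseline ``b_g = 10**Normal(mean, sd)``;
* control animal ``c = b_g * exp(Normal(0, sigma))`` with ``sigma`` chosen so
  the natural-scale CV among control animals matches ``control_cv_percent``
  (``sigma = sqrt(log(1 + cv^2))``);
* pooled treatment sample ``t = mean(matched controls) * F * exp(Normal(0,
  noise_sd))`` where the induction factor ``F = 2**Normal(*fold_change_log2)``
  applies only to responsive genes in GTX cells (and confounder genes in NGTX
  cells) and is 1 elsewhere.

Modelling the pooled sample around the matched-control mean reflects pooling
of several animals per group and makes the zero-effect case exact: with no
spiked effects and ``noise_sd = 0`` every treated/control ratio is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONTROL, GTX, NGTX, EffectSpec, StudyDesign, gene_ids
from .exceptions import ValidationError

SAMPLE_COLUMNS = ["chemical", "klass", "timepoint", "role", "solvent", "weight"]

TRUTH_RESPONSIVE = "responsive"
TRUTH_CONFOUNDER = "confounder"
TRUTH_NULL = "null"


@dataclass
class ExpressionDataset:
    """Gene x sample signal intensities plus per-sample metadata.

    ``intensities``: DataFrame indexed by gene_id with one column per sample.
    ``samples``: DataFrame indexed by sample_id with columns ``chemical``,
    ``klass`` (GTX/NGTX/control), ``timepoint``, ``role`` (treatment/control),
    ``solvent`` and ``weight`` (replication weight of the condition cell).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValidationError("intensity columns must match sample table order")
        if self.intensities.index.duplicated().any():
            raise ValidationError("gene ids must be unique")
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("intensities must be non-negative")
        ctrl = self.samples[self.samples["role"] == "control"]
        groups = set(zip(ctrl["solvent"], ctrl["timepoint"]))
        treat = self.samples[self.samples["role"] == "treatment"]
        missing = [
            sid
            for sid, row in treat.iterrows()
            if (row["solvent"], row["timepoint"]) not in groups
        ]
        if missing:
            raise ValidationError(f"treatment samples without matched controls: {missing}")

    @property
    def treatment_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "treatment"])

    def control_ids(self, solvent: str, timepoint: str) -> list[str]:
        s = self.samples
        mask = (s["role"] == "control") & (s["solvent"] == solvent) & (s["timepoint"] == timepoint)
        return list(s.index[mask])

    @property
    def all_control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "control"])


def cv_to_log_sd(cv_percent: float) -> float:
    """Natural-log sd of a log-normal with the given natural-scale CV%."""
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


def generate_dataset(
    design: StudyDesign,
    effects: EffectSpec,
    seed: int,
) -> tuple[ExpressionDataset, pd.Series]:
    """Simulate one dataset; returns (dataset, per-gene truth labels)."""
    if seed is None:  # reproducibility is mandatory, no implicit seeding
        raise ValidationError("an integer seed is required")
    genes = gene_ids(design.n_genes)
    gene_index = pd.Index(genes, name="gene_id")
    unknown = (effects.responsive_gene_ids | effects.ngtx_confounder_gene_ids) - set(genes)
    if unknown:
        raise ValidationError(f"effect gene ids not in design: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = design.n_genes
    baseline = 10.0 ** rng.normal(*effects.baseline_log10, size=n)
    sigma_ctrl = cv_to_log_sd(effects.control_cv_percent)

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple] = []

    # Individual solvent-control animals per solvent x timepoint.
    control_means: dict[tuple[str, str], np.ndarray] = {}
    solvents = design.solvents
    for solvent in solvents:
        for tp in design.timepoints:
            block = np.empty((n, design.n_control_animals))
            for a in range(design.n_control_animals):
                sid = f"ctrl-{solvent}_{tp}_a{a + 1}"
                vec = baseline * np.exp(rng.normal(0.0, sigma_ctrl, size=n))
                block[:, a] = vec
                columns[sid] = vec
                meta_rows.append((sid, solvent, CONTROL, tp, "control", solvent, 1.0))
            control_means[(solvent, tp)] = block.mean(axis=1)

    # One pooled treatment sample per condition cell.
    responsive = np.isin(genes, sorted(effects.responsive_gene_ids))
    confounder = np.isin(genes, sorted(effects.ngtx_confounder_gene_ids))
    for cond in design.conditions():
        fold = np.ones(n)
        if cond.klass == GTX and responsive.any():
            k = int(responsive.sum())
            fold[responsive] = 2.0 ** rng.normal(*effects.fold_change_log2, size=k)
        if cond.klass == NGTX and confounder.any():
            k = int(confounder.sum())
            fold[confounder] = 2.0 ** rng.normal(*effects.confounder_fold_change_log2, size=k)
        noise = (
            np.exp(rng.normal(0.0, effects.noise_sd, size=n))
            if effects.noise_sd > 0
            else np.ones(n)
        )
        vec = control_means[(cond.solvent, cond.timepoint)] * fold * noise
        columns[cond.condition_id] = vec
        meta_rows.append(
            (cond.condition_id, cond.chemical, cond.klass, cond.timepoint,
             "treatment", cond.solvent, cond.weight)
        )

    samples = pd.DataFrame(
        meta_rows, columns=["sample_id"] + SAMPLE_COLUMNS
    ).set_index("sample_id")
    intensities = pd.DataFrame(columns, index=gene_index)[samples.index]

    truth = pd.Series(TRUTH_NULL, index=gene_index, name="label")
    truth[responsive] = TRUTH_RESPONSIVE
    truth[confounder] = TRUTH_CONFOUNDER
    return ExpressionDataset(intensities, samples), truth


# ---------------------------------------------------------------------------
# Plain-text persistence (intensities.tsv / samples.tsv / truth.tsv)

def write_dataset(ds: ExpressionDataset, out_dir: str | Path, truth: pd.Series | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.intensities.to_csv(out / "intensities.tsv", sep="\t")
    ds.samples.to_csv(out / "samples.tsv", sep="\t")
    if truth is not None:
        truth.rename("label").to_csv(out / "truth.tsv", sep="\t")


def read_dataset(in_dir: str | Path) -> ExpressionDataset:
    src = Path(in_dir)
    intensities = pd.read_csv(src / "intensities.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(src / "samples.tsv", sep="\t", index_col=0)
    return ExpressionDataset(intensities, samples)


def read_truth(in_dir: str | Path) -> pd.Series:
    # keep_default_na=False: the literal label "null" must survive round-trip
    return pd.read_csv(
        Path(in_dir) / "truth.tsv", sep="\t", index_col=0, keep_default_na=False
    )["label"]
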