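"""Study design and effect specification for the in vivo genotoxin panel.

The default design mirrors a single-dose mouse liver study: seven genotoxins
(GTX) — DMN, DEN (run in duplicate), ENU, DPN, AAT, DBP, DMBA — and three
non-genotoxins (NGTX) — EtOH, PB, DEHP — sampled at 4 h, 20 h, 2 weeks and
4 weeks after administration.  Each treatment condition is one pooled RNA
sample per (chemical replicate, timepoint) cell; solvent controls (corn oil
or saline) are individual animals so that control-animal variability (CV%)
and basal expression are estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .exceptions import ValidationError

GTX = "GTX"
NGTX = "NGTX"
CONTROL = "control"

#: Default timepoint labels after single-dose administration.
DEFAULT_TIMEPOINTS = ("4h", "20h", "2wk", "4wk")


@dataclass(frozen=True)
class ChemicalSpec:
    """One model compound in the panel.

    ``replicates`` > 1 means the chemical was run as independent duplicate
    conditions; each of its cells then carries weight ``1/replicates`` in the
    weighted positive-condition count.
    """

    name: str
    klass: str  # GTX or NGTX
    solvent: str = "saline"
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.klass not in (GTX, NGTX):
            raise ValidationError(f"chemical class must be GTX or NGTX, got {self.klass!r}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @property
    def weight(self) -> float:
        """Per-cell replication weight (0.5 for a duplicated chemical)."""
        return float(Fraction(1, self.replicates))


@dataclass(frozen=True)
class Condition:
    """One treatment cell: a chemical replicate at one timepoint."""

    condition_id: str
    chemical: str
    klass: str
    timepoint: str
    solvent: str
    weight: float


@dataclass(frozen=True)
class StudyDesign:
    chemicals: tuple[ChemicalSpec, ...]
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_control_animals: int = 8
    n_genes: int = 10_000

    def __post_init__(self) -> None:
        classes = {c.klass for c in self.chemicals}
        if GTX not in classes or NGTX not in classes:
            raise ValidationError("design needs at least one GTX and one NGTX chemical")
        names = [c.name for c in self.chemicals]
        if len(names) != len(set(names)):
            raise ValidationError("chemical names must be unique")
        if not self.timepoints:
            raise ValidationError("at least one timepoint is required")
        if self.n_control_animals < 1 or self.n_genes < 1:
            raise ValidationError("counts must be positive")

    @property
    def solvents(self) -> tuple[str, ...]:
        return tuple(sorted({c.solvent for c in self.chemicals}))

    def conditions(self) -> list[Condition]:
        """All treatment cells, in panel order (chemical, replicate, timepoint)."""
        cells = []
        for chem in self.chemicals:
            for rep in range(1, chem.replicates + 1):
                stem = chem.name if chem.replicates == 1 else f"{chem.name}.{rep}"
                for tp in self.timepoints:
                    cells.append(
                        Condition(
                            condition_id=f"{stem}_{tp}",
                            chemical=chem.name,
                            klass=chem.klass,
                            timepoint=tp,
                            solvent=chem.solvent,
                            weight=chem.weight,
                        )
                    )
        return cells


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth perturbation applied by the simulator.

    responsive_gene_ids
        Genes induced in every GTX treatment cell with per-cell log2 fold
        change drawn from ``Normal(*fold_change_log2)``.
    ngtx_confounder_gene_ids
        Genes induced in NGTX cells instead (class-unspecific responders).
    baseline_log10
        (mean, sd) of per-gene baseline log10 intensity.
    control_cv_percent
        Target natural-scale coefficient of variation among control animals.
    noise_sd
        Multiplicative log-scale (natural log) noise sd on treatment samples.
    """

    responsive_gene_ids: frozenset[str] = frozenset()
    ngtx_confounder_gene_ids: frozenset[str] = frozenset()
    fold_change_log2: tuple[float, float] = (3.0, 0.25)
    confounder_fold_change_log2: tuple[float, float] = (3.0, 0.25)
    baseline_log10: tuple[float, float] = (2.0, 0.5)
    control_cv_percent: float = 30.0
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        overlap = self.responsive_gene_ids & self.ngtx_confounder_gene_ids
        if overlap:
            raise ValidationError(f"responsive and confounder gene sets overlap: {sorted(overlap)}")
        for sd in (self.fold_change_log2[1], self.confounder_fold_change_log2[1],
                   self.baseline_log10[1], self.noise_sd):
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        if self.control_cv_percent < 0:
            raise ValidationError("control_cv_percent must be >= 0")


def default_design(n_genes: int = 10_000, n_control_animals: int = 8) -> StudyDesign:
    """The ten-compound panel with duplicated DEN and four timepoints."""
    return StudyDesign(
        chemicals=(
            ChemicalSpec("DMN", GTX, "saline"),
            ChemicalSpec("DEN", GTX, "saline", replicates=2),
            ChemicalSpec("ENU", GTX, "saline"),
            ChemicalSpec("DPN", GTX, "saline"),
            ChemicalSpec("AAT", GTX, "corn-oil"),
            ChemicalSpec("DBP", GTX, "corn-oil"),
            ChemicalSpec("DMBA", GTX, "corn-oil"),
            ChemicalSpec("EtOH", NGTX, "saline"),
            ChemicalSpec("PB", NGTX, "saline"),
            ChemicalSpec("DEHP", NGTX, "corn-oil"),
        ),
        timepoints=DEFAULT_TIMEPOINTS,
        n_control_animals=n_control_animals,
        n_genes=n_genes,
    )


def gene_ids(n: int) -> list[str]:
    """Synthetic gene identifiers g00001, g00002, ..."""
    return [f"g{i:05d}" for i in range(1, n + 1)]


def default_effects(
    n_responsive: int = 5,
    fold_change_log2: tuple[float, float] = (3.0, 0.25),
    ngtx_confounders: Iterable[str] = (),
    **kwargs,
) -> EffectSpec:
    """Spike the first ``n_responsive`` genes as GTX-specific responders.

    The default — five responsive genes at a mean 8-fold induction — matches
    the spike-in configuration used throughout the test-bench simulations.
    """
    return EffectSpec(
        responsive_gene_ids=frozenset(gene_ids(n_responsive)),
        ngtx_confounder_gene_ids=frozenset(ngtx_confounders),
        fold_change_log2=fold_change_log2,
        **kwargs,
    )
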