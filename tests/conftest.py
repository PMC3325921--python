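import pytest

from gtxscore.design import ChemicalSpec, EffectSpec, StudyDesign, gene_ids


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """A scaled-down panel: 3 GTX (one duplicated) + 2 NGTX, 2 timepoints."""
    return StudyDesign(
        chemicals=(
            ChemicalSpec("DMN", "GTX", "saline"),
            ChemicalSpec("DEN", "GTX", "saline", replicates=2),
            ChemicalSpec("AAT", "GTX", "corn-oil"),
            ChemicalSpec("EtOH", "NGTX", "saline"),
            ChemicalSpec("DEHP", "NGTX", "corn-oil"),
        ),
        timepoints=("4h", "20h"),
        n_control_animals=3,
        n_genes=300,
    )


@pytest.fixture(scope="session")
def small_effects() -> EffectSpec:
    """Three spiked GTX-specific responders at a mean 8-fold induction."""
    return EffectSpec(responsive_gene_ids=frozenset(gene_ids(3)))
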