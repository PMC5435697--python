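import pytest

from strainkit.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_scenario():
    """The standard 4-strain synthetic scenario (seed 0), shared read-only."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced 3-strain scenario for fast end-to-end checks."""
    cfg = SimulationConfig(
        n_strains=3,
        genome_length=40_000,
        genes_per_category={"Y": 4, "M": 4, "Q": 4, "D": 4},
        per_category_divergence={"Y": 0.02, "M": 0.05, "Q": 0.10, "D": 0.25},
        n_hgt_genes=3,
        crispr_specs=[],
        seed=11,
    )
    return simulate(cfg)
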