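import numpy as np
import pytest

from poolfst.simulate import CollectionSpec, SimulationConfig, simulate_study


def two_pop_config(**overrides) -> SimulationConfig:
    """Two independent populations, dual 12-mosquito replicate pools each."""
    kwargs = dict(
        seed=11,
        n_genes=12,
        gene_length_bp=400,
        collections=(
            CollectionSpec("popA", 12, 2),
            CollectionSpec("popB", 12, 2),
        ),
        theta=0.2,
        coverage_mean=60.0,
        polymorphic_fraction=0.08,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """A small simulated two-population study shared across tests."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(two_pop_config(), outdir)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20161219)
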