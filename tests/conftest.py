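import pytest

from herbflux.fluxes import compute_fluxes
from herbflux.synthetic import SyntheticConfig, generate_network


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small but fully featured network: 8 sites, 1-2 plots each."""
    return SyntheticConfig(
        n_sites=8, plots_per_site=(1, 2), traps_per_plot=(9, 12),
        leaves_scored_per_scan=200, years=2, seed=123,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_network(small_config, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    return small_bundle[0]


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return small_bundle[1]


@pytest.fixture(scope="session")
def small_fluxes(small_dataset):
    return compute_fluxes(small_dataset)
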