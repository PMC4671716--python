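import numpy as np
import pytest

from ecotrade import (
    MRIOSystem,
    SyntheticConfig,
    footprint_series,
    generate_mrio_series,
    generate_panel,
    integration_series,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_countries=8, n_sectors=3, n_years=3, seed=1)


@pytest.fixture(scope="session")
def small_systems(small_config):
    return generate_mrio_series(small_config)


@pytest.fixture(scope="session")
def small_world(small_config, small_systems):
    """Footprints, integration and panel for the small synthetic world."""
    footprints = footprint_series(small_systems)
    integration = integration_series(small_systems)
    panel, truth = generate_panel(small_config, footprints, integration)
    return {
        "config": small_config,
        "systems": small_systems,
        "footprints": footprints,
        "integration": integration,
        "panel": panel,
        "truth": truth,
    }


@pytest.fixture()
def toy_two_country():
    """Hand-sized 2-country, 1-sector system with cross-border trade."""
    Z = np.array([[10.0, 8.0], [6.0, 12.0]])
    Y = np.array([[30.0, 12.0], [9.0, 33.0]])
    x = Z.sum(axis=1) + Y.sum(axis=1)
    va = x - Z.sum(axis=0)
    so2 = np.array([5.0, 3.0])
    return MRIOSystem(
        countries=["AA", "BB"],
        sectors=["s0"],
        Z=Z,
        Y=Y,
        value_added=va,
        so2=so2,
        year=2000,
    )
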