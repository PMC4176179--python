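import numpy as np
import pytest

from cismap import (
    MapBuildConfig,
    SimulationConfig,
    build_map,
    simulate_panel,
)
from cismap.map_builder import enumerate_candidates
from cismap.synthetic_data import TEST_TISSUE


@pytest.fixture(scope="session")
def small_panel():
    """A compact planted-signal panel shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_tissues=15,
        n_tss=20,
        n_crms=100,
        n_true_links=30,
        n_tfs=12,
        make_genome=True,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_map(small_panel):
    cfg = MapBuildConfig(theta=1e-3, test_tissue=TEST_TISSUE)
    return build_map(
        small_panel.tss_set,
        small_panel.crms,
        small_panel.histone,
        small_panel.expression,
        cfg,
    )


@pytest.fixture(scope="session")
def small_candidates(small_panel, small_map):
    return enumerate_candidates(
        small_panel.tss_set, small_panel.crms, small_map.config
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
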