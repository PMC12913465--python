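"""Shared fixtures: small synthetic tables and one coarse pipeline run."""

import numpy as np
import pytest

from heatspec import pipeline as pl
from heatspec import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def budding_table():
    """One default-sized budding-stage table (80 samples)."""
    cfg = synth.SimulationConfig(seed=11, stages=("budding",))
    return synth.simulate_experiment(cfg)[0]


@pytest.fixture(scope="session")
def coarse_config():
    """A coarse (strided) single-stage pipeline configuration."""
    return pl.RunConfig(
        simulation=synth.SimulationConfig(seed=5, stages=("branching",)),
        stride=10,
        spa_stride=2,
        spa_n_max=6,
    )


@pytest.fixture(scope="session")
def stage_report(coarse_config):
    """Full single-stage analysis at coarse resolution, reused read-only."""
    table = synth.simulate_experiment(coarse_config.simulation)[0]
    return pl.run_stage_analysis(table, coarse_config, "branching",
                                 seed=coarse_config.simulation.seed)
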