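import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import brulat as bl

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    return bl.WavelengthGrid(930.0 + 5.45 * np.arange(10))


@pytest.fixture(scope="session")
def small_cube(small_grid):
    """8 x 8 x 10 cube with reproducible random reflectance."""
    rng = np.random.default_rng(11)
    return bl.Hypercube(rng.uniform(0.1, 0.9, size=(8, 8, 10)), small_grid)


@pytest.fixture(scope="session")
def default_config():
    return bl.SimulationConfig()


@pytest.fixture(scope="session")
def l2_cube(default_config):
    """A latent-bruise scan (L2, 1 h) plus its ground truth."""
    return bl.generate_hypercube(default_config, "L2", 1, seed=42)


@pytest.fixture(scope="session")
def sound_cube(default_config):
    return bl.generate_hypercube(default_config, "sound", 1, seed=42)


@pytest.fixture(scope="session")
def tiny_experiment_table():
    """Small but complete simulated dataset shared by experiment tests."""
    cfg = bl.ExperimentConfig(n_per_batch=2, sound_total=60, seed=5)
    return cfg, bl.build_table(cfg)
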