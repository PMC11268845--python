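import numpy as np
import pandas as pd
import pytest

from phenopred.simulate import SimulationConfig, simulate_population


def tiny_config(**overrides) -> SimulationConfig:
    """A miniature population: 5 families x 8, 46 hybrids, 3 environments."""
    params = dict(
        n_markers=200,
        n_wavelengths=120,
        family_sizes=(8, 8, 8, 8, 8),
        n_both=15,
        n_t1_only=5,
        n_t2_only=5,
        environments=(("L1", "2020"), ("L2", "2020"), ("L1", "2021")),
        n_checks=2,
        check_reps=4,
        n_blocks=10,
        seed=11,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def tiny_population() -> dict:
    return simulate_population(tiny_config())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
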