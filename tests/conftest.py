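"""Shared fixtures: datasets are generated, never stored."""

import numpy as np
import pandas as pd
import pytest

from allocarbon import CompatibleSystemModel
from allocarbon.simulate import SimulationConfig, make_fixture_suite, simulate_dataset

ZERO_NOISE = dict(
    noise_scales=(0.0, 0.0, 0.0, 0.0),
    concentration_means=(0.48, 0.48, 0.48, 0.48),
    concentration_sds=(0.0, 0.0, 0.0, 0.0),
)


@pytest.fixture(scope="session")
def default_dataset() -> pd.DataFrame:
    """The 89-tree study emulation, seed 1."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_suite():
    return make_fixture_suite()


@pytest.fixture(scope="session")
def bm1_jackknife(default_dataset):
    return CompatibleSystemModel(default_dataset, "BM1").fit().jackknife()


@pytest.fixture(scope="session")
def cm3_jackknife(default_dataset):
    return CompatibleSystemModel(default_dataset, "CM3").fit().jackknife()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
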