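import numpy as np
import pytest

from palmconvert import SyntheticConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(grid_rows=120, grid_cols=120, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_landscape(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
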