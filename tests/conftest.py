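import numpy as np
import pytest

from fruitspec import (
    HyperspectralCube,
    SpectrumSet,
    WavelengthGrid,
    default_params,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return WavelengthGrid.uniform(400.0, 900.0, 20)


@pytest.fixture
def random_set(rng, small_grid):
    spectra = 0.2 + 0.6 * rng.random((12, small_grid.count))
    return SpectrumSet(spectra, small_grid,
                       [f"s{i}" for i in range(12)])


@pytest.fixture
def random_cube(rng):
    grid = WavelengthGrid.uniform(400.0, 900.0, 6)
    data = 0.1 + rng.random((8, 8, 6))
    return HyperspectralCube(data, grid, kind="reflectance")


@pytest.fixture(scope="session")
def tomato200():
    """Default-condition synthetic dataset at the 200-fruit field scale."""
    return generate_dataset(default_params(n_samples=200, seed=11))
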