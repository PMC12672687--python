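import numpy as np
import pytest
from hypothesis import settings

from mvcalib import (
    NoiseModel,
    build_wavelength_grid,
    default_pure_components,
    simulate_mixtures,
    split_design,
    table1_design,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return build_wavelength_grid(220.0, 400.0, 0.1)


@pytest.fixture(scope="session")
def design():
    return table1_design()


@pytest.fixture(scope="session")
def pure_models(grid):
    return default_pure_components(grid)


@pytest.fixture(scope="session")
def noiseless_run(grid, design, pure_models):
    """Exact Beer-Lambert mixtures of the packaged design (no noise)."""
    X = simulate_mixtures(pure_models, design.concentrations, grid, noise=None)
    Ycal, Yval = split_design(design)
    return (
        X.select_samples(design.calibration_ids),
        Ycal,
        X.select_samples(design.validation_ids),
        Yval,
    )


@pytest.fixture(scope="session")
def noisy_run(grid, design, pure_models):
    """The same design with 0.002 AU photometric noise (seed fixed)."""
    X = simulate_mixtures(
        pure_models, design.concentrations, grid, NoiseModel(0.002, 0.0, seed=20240917)
    )
    Ycal, Yval = split_design(design)
    return (
        X.select_samples(design.calibration_ids),
        Ycal,
        X.select_samples(design.validation_ids),
        Yval,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
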