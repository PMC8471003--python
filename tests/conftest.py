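import numpy as np
import pytest

from fibrospec import TissueOpticalModel, default_grid


@pytest.fixture(scope="session")
def small_grid():
    """Reduced 257-sample wavelength grid for desk-scale simulations."""
    return default_grid(257)


@pytest.fixture(scope="session")
def model_small(small_grid):
    """Default-noise forward model on the reduced grid."""
    return TissueOpticalModel(wavelengths=small_grid)


@pytest.fixture(scope="session")
def model_clean(small_grid):
    """Forward model with all noise and subject variability off."""
    return TissueOpticalModel(wavelengths=small_grid).noise_free()
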