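import numpy as np
import pytest

from anemovis import COMMON_GRID, GeneratorConfig, Spectrum


@pytest.fixture(scope="session")
def grid():
    return COMMON_GRID


@pytest.fixture(scope="session")
def cfg():
    """Default synthetic study conditions, root seed 0."""
    return GeneratorConfig(seed=0)


@pytest.fixture
def flat_spectrum(grid):
    def make(value: float, kind: str = "reflectance") -> Spectrum:
        return Spectrum(grid, np.full(len(grid), value), kind)

    return make
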