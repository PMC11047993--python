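import numpy as np
import pytest

from synthchip.addressing import ArrayGeometry


@pytest.fixture
def default_geometry() -> ArrayGeometry:
    return ArrayGeometry()


@pytest.fixture
def small_geometry() -> ArrayGeometry:
    """10x10 array addressed by 4 blocks of 3 columns (12-column decode
    space, 2 surplus outputs) — small enough for brute-force oracles."""
    return ArrayGeometry(n_rows=10, n_cols=10, n_blocks=4, pitch_um=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240406)
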