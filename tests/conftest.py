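import numpy as np
import pytest

from gistdock import (
    DEFAULT_BULK_EWW,
    GISTGrid,
    GridGeometry,
    derive_thermo,
    make_toy_complex,
)


def random_raw_grid(seed: int, dims=(6, 6, 6), spacing: float = 0.375) -> GISTGrid:
    """Random five-field GIST grid (no planted structure), bulk reference set."""
    rng = np.random.default_rng(seed)
    geo = GridGeometry((0.0, 0.0, 0.0), spacing, dims)
    return GISTGrid(
        geometry=geo,
        rho=np.abs(rng.normal(1.0, 1.5, dims)),
        e_sw=rng.normal(0.0, 1.0, dims),
        e_ww=rng.normal(DEFAULT_BULK_EWW, 1.0, dims),
        ts_orient=rng.normal(0.3, 0.3, dims),
        ts_trans=rng.normal(0.3, 0.3, dims),
        e_bulk_ww=DEFAULT_BULK_EWW,
    )


@pytest.fixture(scope="session")
def toy():
    return make_toy_complex(seed=7)


@pytest.fixture()
def derived_grid():
    return derive_thermo(random_raw_grid(11))
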