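import numpy as np
import pytest

from rootspec import SampleMeta, Spectrum, WavenumberGrid, default_grid


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    """The default working grid: 4000-400 cm^-1 at 2 cm^-1 (1801 points)."""
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid() -> WavenumberGrid:
    """A cheap 8 cm^-1 grid for tests where spectral detail is irrelevant."""
    return default_grid(spacing=8.0)


def make_spectrum(values, grid=None, sample_id="s1", species="maize", **meta):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = WavenumberGrid(1000.0 + 2.0 * np.arange(values.size))
    return Spectrum(grid, values, SampleMeta(sample_id=sample_id, species=species, **meta))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
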