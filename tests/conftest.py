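import numpy as np
import pytest

from oleonir.spectra_io import SpectraSet, Spectrum, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20241)


@pytest.fixture
def default_grid():
    return WavelengthGrid.regular()


@pytest.fixture
def make_spectra_set(default_grid):
    """Factory for random SpectraSet fixtures on the instrument grid."""

    def _make(n_samples=5, seed=0, grid=None, day=0):
        grid = grid or default_grid
        r = np.random.default_rng(seed)
        spectra = tuple(
            Spectrum(f"s{i:02d}", day, r.uniform(0.1, 1.5, len(grid)))
            for i in range(n_samples)
        )
        return SpectraSet(grid, spectra)

    return _make
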