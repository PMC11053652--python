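import numpy as np
import pandas as pd
import pytest

from sersid.io import Grid, SpectrumSet


@pytest.fixture(scope="session")
def grid():
    return Grid(400.0, 1800.0, 900)


@pytest.fixture(scope="session")
def small_grid():
    return Grid(400.0, 1800.0, 300)


def make_labeled_set(grid: Grid, n: int, analyte: str, concentration: float,
                     label: int, seed: int = 0) -> SpectrumSet:
    """Random-intensity spectra carrying the given labels (for bookkeeping tests)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 100.0, (n, grid.n))
    meta = pd.DataFrame({
        "analyte": [analyte] * n,
        "concentration_M": [concentration] * n,
        "label": [label] * n,
        "provenance": ["synthetic"] * n,
    })
    return SpectrumSet(grid.shifts, X, meta)


def planted_band_data(n_per_class: int, n_channels: int, band: slice,
                      amplitude: float = 5.0, noise: float = 1.0, seed: int = 0):
    """Two-class fixture: class 1 carries an extra bump inside `band`."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise, (2 * n_per_class, n_channels))
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X[y == 1, band] += amplitude
    return X, y
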