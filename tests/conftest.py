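import warnings

import numpy as np
import pytest

import specbase as sb


def build_basis_quietly(grid, L, **kw):
    """Build a Gaussian basis suppressing the narrow-width warning (small
    test grids legitimately sit below the spectroscopic width floor)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sb.OverfittingWarning)
        return sb.build_gaussian_basis(grid, L, **kw)


@pytest.fixture(scope="session")
def grid947():
    return sb.make_grid(375.0, 3500.0, 947)


@pytest.fixture(scope="session")
def small_grid():
    """0-100 cm^-1 with 101 channels: Gaussian centers land on grid points."""
    return sb.make_grid(0.0, 100.0, 101)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small full-rank model (p=60): 2 references, 2 background columns,
    L=4 Gaussian basis; used by exact-recovery and oracle tests."""
    grid = sb.make_grid(0.0, 590.0, 60)
    r = np.random.default_rng(7)
    nu = grid.nu
    s1 = np.exp(-(((nu - 150.0) / 18.0) ** 2))
    s2 = np.exp(-(((nu - 420.0) / 25.0) ** 2))
    refs = sb.ReferenceLibrary(grid, np.column_stack([s1, s2]), ("a", "b"))
    b1 = np.exp(-(((nu - 300.0) / 15.0) ** 2))
    b2 = np.exp(-(((nu - 520.0) / 20.0) ** 2))
    bg = sb.BackgroundBasis(grid, np.linalg.qr(np.column_stack([b1, b2]))[0])
    basis = build_basis_quietly(grid, 4)
    return grid, refs, bg, basis
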