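"""Broad Gaussian baseline basis.

A smooth fluorescence baseline is modelled as a linear combination of L
broad Gaussian vectors.  The design is fully determined by L and the grid:

* centers are equally spaced with the first and last pinned to the grid
  endpoints, ``m_l = nu_1 + (nu_p - nu_1) (l-1)/(L-1)``;
* the shared width is ``sigma = delta_m * sqrt(1 / (2 ln 2))`` where
  ``delta_m`` is the center interval, so each vector falls to exactly 1/2
  at its neighbours' centers (half-overlap).

On the 375-3500 cm^-1 grid with L = 11 this gives a center interval of
312.5 cm^-1 and a width of ~265 cm^-1.  Because Raman peaks are narrower
than ~350 cm^-1, widths below 350/(2 ln 2) ~ 252 cm^-1 start to absorb
peak energy into the baseline (overfitting); a warning is emitted there.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Spectrum, WavenumberGrid

__all__ = [
    "GaussianBasis",
    "OverfittingWarning",
    "gaussian_centers",
    "gaussian_width",
    "build_gaussian_basis",
    "DEFAULT_WIDTH_SCALE",
    "WIDTH_FLOOR_CM",
    "MAX_PEAK_WIDTH_CM",
]

#: sigma = DEFAULT_WIDTH_SCALE * delta_m reproduces the half-overlap design
DEFAULT_WIDTH_SCALE = float(np.sqrt(1.0 / (2.0 * np.log(2.0))))

#: Raman peaks are narrower than this, in general
MAX_PEAK_WIDTH_CM = 350.0

#: below this width the basis starts fitting Raman peaks, not baseline
WIDTH_FLOOR_CM = MAX_PEAK_WIDTH_CM / (2.0 * np.log(2.0))


class OverfittingWarning(UserWarning):
    """The Gaussian basis is narrow enough to fit Raman peaks."""


@dataclass(frozen=True)
class GaussianBasis:
    """Broad Gaussian matrix Kbl (p x L) with its design parameters."""

    grid: WavenumberGrid
    matrix: np.ndarray
    L: int
    centers: np.ndarray
    sigma: float
    delta_m: float

    def as_spectra(self) -> list[Spectrum]:
        return [
            Spectrum(self.grid, self.matrix[:, l], label=f"gauss_{l + 1:02d}")
            for l in range(self.L)
        ]


def _check_L(L: int) -> None:
    if L < 2:
        raise ValueError("L must be >= 2 (endpoint centers cannot both be pinned)")


def gaussian_centers(grid: WavenumberGrid, L: int) -> np.ndarray:
    """Equally spaced centers with m_1 = nu_1 and m_L = nu_p."""
    _check_L(L)
    return np.linspace(grid.nu_min, grid.nu_max, L)


def gaussian_width(
    grid: WavenumberGrid, L: int, width_scale: float = DEFAULT_WIDTH_SCALE
) -> float:
    """Shared width sigma (cm^-1) of the L-vector basis on the grid.

    Warns with :class:`OverfittingWarning` when the width falls below the
    ~252 cm^-1 floor implied by the 350 cm^-1 peak-width bound.
    """
    _check_L(L)
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")
    delta_m = grid.span / (L - 1)
    sigma = width_scale * delta_m
    if sigma < WIDTH_FLOOR_CM:
        warnings.warn(
            f"Gaussian width {sigma:.1f} cm^-1 is below the {WIDTH_FLOOR_CM:.0f} cm^-1 "
            "floor: the basis can fit Raman peaks (overfitting regime)",
            OverfittingWarning,
            stacklevel=2,
        )
    return float(sigma)


def build_gaussian_basis(
    grid: WavenumberGrid, L: int, width_scale: float = DEFAULT_WIDTH_SCALE
) -> GaussianBasis:
    """Evaluate the p x L broad Gaussian matrix on the grid."""
    _check_L(L)
    if L >= grid.p:
        raise ValueError("L must be smaller than the channel count")
    centers = gaussian_centers(grid, L)
    sigma = gaussian_width(grid, L, width_scale)
    delta_m = grid.span / (L - 1)
    nu = grid.nu[:, None]
    matrix = np.exp(-((nu - centers[None, :]) ** 2) / (2.0 * sigma**2))
    return GaussianBasis(grid, matrix, int(L), centers, sigma, delta_m)
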