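"""Wavenumber grids, spectrum containers, model matrices and tabular I/O.

Every container carries its :class:`WavenumberGrid` explicitly, and every
operation that combines containers verifies grid identity by the
``(nu_min, nu_max, p)`` triple before touching the numbers.  This fail-fast
contract is what keeps a corrected spectrum, a reference library and a
background basis from silently being combined on mismatched axes.

The canonical on-disk format is a CSV/TSV table whose first column is the
wavenumber axis in cm^-1 (header ``wavenumber_cm-1``) and whose remaining
columns are intensity traces, one spectrum per column.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "ReferenceLibrary",
    "BackgroundBasis",
    "NoiseModel",
    "BaselineResult",
    "SpectrumFormatError",
    "GridMismatchError",
    "DegenerateModelError",
    "SingularSystemError",
    "make_grid",
    "read_spectra",
    "write_spectra",
    "stack_values",
    "WAVENUMBER_COLUMN",
]

WAVENUMBER_COLUMN = "wavenumber_cm-1"

_UNIFORMITY_RTOL = 1e-9


class SpectrumFormatError(ValueError):
    """A spectrum table on disk violates the format contract."""


class GridMismatchError(ValueError):
    """Two containers that must share a wavenumber grid do not."""


class DegenerateModelError(ValueError):
    """A model matrix is rank deficient (or numerically close to it)."""


class SingularSystemError(ValueError):
    """A linear system that must be solvable is singular."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis: p channels from nu[0] to nu[-1], in cm^-1."""

    nu: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float)
        object.__setattr__(self, "nu", nu)
        if nu.ndim != 1 or nu.size < 3:
            raise ValueError("grid needs a 1-D axis with at least 3 channels")
        d = np.diff(nu)
        if np.any(d <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        span = nu[-1] - nu[0]
        mean_d = span / (nu.size - 1)
        if np.max(np.abs(d - mean_d)) > _UNIFORMITY_RTOL * max(abs(nu[-1]), abs(nu[0]), span):
            raise ValueError("wavenumber axis must be uniformly spaced")

    @property
    def p(self) -> int:
        return int(self.nu.size)

    @property
    def nu_min(self) -> float:
        return float(self.nu[0])

    @property
    def nu_max(self) -> float:
        return float(self.nu[-1])

    @property
    def spacing(self) -> float:
        """Channel spacing in cm^-1."""
        return (self.nu_max - self.nu_min) / (self.p - 1)

    @property
    def span(self) -> float:
        return self.nu_max - self.nu_min

    def matches(self, other: "WavenumberGrid") -> bool:
        return (
            self.p == other.p
            and self.nu_min == other.nu_min
            and self.nu_max == other.nu_max
        )

    def require_match(self, other: "WavenumberGrid", what: str = "operand") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what}: grid ({other.nu_min}, {other.nu_max}, {other.p}) does not "
                f"match expected ({self.nu_min}, {self.nu_max}, {self.p})"
            )

    def channels_from_cm(self, width_cm: float, minimum: int = 1) -> int:
        """Convert a width given in cm^-1 to a channel count (>= minimum)."""
        if width_cm <= 0:
            raise ValueError("width must be positive")
        return max(int(round(width_cm / self.spacing)), minimum)


def make_grid(nu_min: float, nu_max: float, n_channels: int) -> WavenumberGrid:
    """Build a uniform grid; e.g. ``make_grid(375, 3500, 947)`` is the
    375-3500 cm^-1 axis at ~3.3 cm^-1 resolution."""
    if nu_max <= nu_min:
        raise ValueError("nu_max must exceed nu_min")
    if n_channels < 3:
        raise ValueError("n_channels must be at least 3")
    return WavenumberGrid(np.linspace(nu_min, nu_max, int(n_channels)))


@dataclass(frozen=True)
class Spectrum:
    """Intensity trace (arbitrary counts) on a wavenumber grid."""

    grid: WavenumberGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size != self.grid.p:
            raise ValueError("values length must equal the grid channel count")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")

    def with_values(self, values: np.ndarray, label: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, self.label if label is None else label)


@dataclass(frozen=True)
class ReferenceLibrary:
    """Reference signature matrix S (p x C), one target analyte per column."""

    grid: WavenumberGrid
    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "names", tuple(self.names))
        if m.shape[0] != self.grid.p:
            raise ValueError("reference matrix rows must equal grid channels")
        if len(self.names) != m.shape[1]:
            raise ValueError("one name per reference column required")
        if not np.all(np.isfinite(m)):
            raise ValueError("reference matrix must be finite")
        if np.any(np.all(m == 0.0, axis=0)):
            raise ValueError("reference matrix contains an all-zero column")

    @property
    def n_references(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class BackgroundBasis:
    """Background basis matrix Kbg (p x M) spanning background signatures."""

    grid: WavenumberGrid
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        if m.shape[0] != self.grid.p:
            raise ValueError("background matrix rows must equal grid channels")
        if not np.all(np.isfinite(m)):
            raise ValueError("background matrix must be finite")

    @property
    def n_components(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class NoiseModel:
    """Heteroscedastic Gaussian channel noise n ~ N(0, gamma * diag(sigma_sq))."""

    sigma_sq: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma_sq, dtype=float)
        object.__setattr__(self, "sigma_sq", s)
        if s.ndim != 1 or np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("per-channel variances must be positive and finite")
        if not (self.gamma > 0):
            raise ValueError("gamma must be positive")

    @property
    def std(self) -> np.ndarray:
        """Per-channel noise standard deviation sqrt(gamma * sigma_i^2)."""
        return np.sqrt(self.gamma * self.sigma_sq)


@dataclass
class BaselineResult:
    """Outcome of a baseline correction: ``corrected + baseline == input``.

    The coefficient fields are populated only by the subspace-model
    corrector; iterative correctors report their iteration state in
    ``converged`` / ``n_iter`` / ``diagnostics`` instead.
    """

    baseline: Spectrum
    corrected: Spectrum
    method: str
    converged: bool = True
    n_iter: int = 1
    coefficients: np.ndarray | None = None
    signature_coeffs: np.ndarray | None = None
    background_coeffs: np.ndarray | None = None
    baseline_coeffs: np.ndarray | None = None
    residual_norm: float | None = None
    condition_number: float | None = None
    diagnostics: dict = field(default_factory=dict)


def stack_values(spectra: Sequence[Spectrum]) -> np.ndarray:
    """Stack spectra as columns of a p x N matrix (shared grid enforced)."""
    if not spectra:
        raise ValueError("no spectra given")
    grid = spectra[0].grid
    for s in spectra[1:]:
        grid.require_match(s.grid, "stack_values")
    return np.column_stack([s.values for s in spectra])


def _separator(path: str | os.PathLike, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ValueError("dialect must be 'csv' or 'tsv'")
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_spectra(path: str | os.PathLike, dialect: str | None = None) -> list[Spectrum]:
    """Read a spectrum table: wavenumber axis in column 1, one spectrum per
    further column, header row naming the spectra."""
    sep = _separator(path, dialect)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise SpectrumFormatError("table needs a wavenumber column plus >=1 intensity column")
    first = str(df.columns[0])
    try:
        float(first)
    except ValueError:
        pass
    else:
        raise SpectrumFormatError("missing header row (first column name is numeric)")
    if df.isna().any().any():
        raise SpectrumFormatError("table contains missing values")
    try:
        axis = df.iloc[:, 0].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SpectrumFormatError("wavenumber column is not numeric") from exc
    try:
        grid = WavenumberGrid(axis)
    except ValueError as exc:
        raise SpectrumFormatError(f"bad wavenumber axis: {exc}") from exc
    out = []
    for col in df.columns[1:]:
        try:
            vals = df[col].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise SpectrumFormatError(f"column {col!r} is not numeric") from exc
        out.append(Spectrum(grid, vals, label=str(col)))
    return out


def write_spectra(
    spectra: Sequence[Spectrum], path: str | os.PathLike, dialect: str | None = None
) -> None:
    """Write spectra to a table readable by :func:`read_spectra`.

    Values are printed with 17 significant digits so the round trip is
    bit-stable for doubles.
    """
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    data = {WAVENUMBER_COLUMN: grid.nu}
    for i, s in enumerate(spectra):
        grid.require_match(s.grid, "write_spectra")
        name = s.label or f"spectrum_{i + 1}"
        if name in data:
            name = f"{name}_{i + 1}"
        data[name] = s.values
    sep = _separator(path, dialect)
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, float_format="%.17g")
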