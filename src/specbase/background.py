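"""Background basis construction.

A background basis Kbg is learned from a corpus of background-only
spectra: each spectrum is baseline-corrected, the corrected spectra are
stacked as columns, and the left singular vectors belonging to the M
largest singular values become the basis columns.  The corpus is *not*
mean-centred (the basis must represent the background signal itself, not
deviations from a mean), and each singular vector is flipped so its
largest-magnitude element is positive, which fixes the SVD sign ambiguity
and makes the output deterministic.
"""
from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from . import classic
from .core import BackgroundBasis, BaselineResult, Spectrum, stack_values

__all__ = ["build_background_basis", "explained_fraction", "resolve_corrector"]

Corrector = Callable[[Spectrum], BaselineResult]

_NAMED_CORRECTORS: dict[str, Corrector] = {
    "als": classic.als_baseline,
    "airpls": classic.airpls_baseline,
    "arpls": classic.arpls_baseline,
    "imf": classic.imf_baseline,
    "rcf": classic.rcf_baseline,
}


def resolve_corrector(corrector: str | Corrector | None) -> Corrector | None:
    """Map a corrector name (or callable, or 'none'/None) to a callable."""
    if corrector is None or corrector == "none":
        return None
    if callable(corrector):
        return corrector
    try:
        return _NAMED_CORRECTORS[corrector]
    except KeyError:
        raise ValueError(
            f"unknown corrector {corrector!r}; choose from "
            f"{sorted(_NAMED_CORRECTORS)} or 'none'"
        ) from None


def build_background_basis(
    spectra: Sequence[Spectrum],
    M: int,
    corrector: str | Corrector | None = "arpls",
) -> BackgroundBasis:
    """Learn an M-column orthonormal background basis from a corpus.

    ``corrector`` names the baseline correction applied to each corpus
    spectrum before the SVD (default ArPLS); pass ``'none'`` for an
    already-corrected or noiseless corpus.
    """
    if not spectra:
        raise ValueError("empty background corpus")
    if M < 1:
        raise ValueError("M must be >= 1")
    if M > len(spectra):
        raise ValueError("M cannot exceed the number of corpus spectra")
    grid = spectra[0].grid
    if M >= grid.p:
        raise ValueError("M must be smaller than the channel count")
    corr = resolve_corrector(corrector)
    if corr is not None:
        spectra = [corr(s).corrected for s in spectra]
    X = stack_values(spectra)
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    cols = U[:, :M].copy()
    for j in range(M):
        k = int(np.argmax(np.abs(cols[:, j])))
        if cols[k, j] < 0:
            cols[:, j] = -cols[:, j]
    return BackgroundBasis(grid, cols)


def explained_fraction(
    spectra: Sequence[Spectrum], basis: BackgroundBasis
) -> float:
    """Fraction of corpus energy captured by the basis:
    ||P_basis X||_F^2 / ||X||_F^2."""
    if not spectra:
        raise ValueError("empty corpus")
    basis.grid.require_match(spectra[0].grid, "explained_fraction")
    X = stack_values(spectra)
    total = float(np.sum(X**2))
    if total == 0.0:
        raise ValueError("corpus has zero energy")
    proj = basis.matrix @ (basis.matrix.T @ X)
    return float(np.sum(proj**2) / total)
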