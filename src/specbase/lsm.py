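"""Joint baseline + signature estimation in an augmented linear subspace model.

The measured spectrum is modelled as

    x = S g + Kbg y_bg + Kbl y_bl + n  =  K' y' + n

with S the reference signature library, Kbg the background basis and Kbl
the broad Gaussian baseline basis.  The whole coefficient vector y' is
estimated by (ordinary or, given a noise model, generalized) least
squares, the baseline is reconstructed as ``b = Kbl y_bl`` and subtracted.
Because baseline and signatures are fitted simultaneously, removing the
baseline does not distort the part of the spectrum that the signature and
background subspaces explain.

The least-squares problem is solved by QR factorization of K' (never by
forming (K'^T K')^{-1} explicitly); full column rank is verified through a
condition-number threshold before solving.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .core import (
    BackgroundBasis,
    BaselineResult,
    DegenerateModelError,
    NoiseModel,
    ReferenceLibrary,
    Spectrum,
    WavenumberGrid,
)
from .gaussian import GaussianBasis

__all__ = ["AugmentedModel", "fit_lsm_baseline", "correct_batch"]

DEFAULT_COND_THRESHOLD = 1e10


@dataclass
class AugmentedModel:
    """The augmented design [S, Kbg, Kbl] with a cached QR factorization."""

    grid: WavenumberGrid
    S: np.ndarray
    Kbg: np.ndarray
    Kbl: np.ndarray
    condition_number: float
    _Q: np.ndarray = field(repr=False)
    _R: np.ndarray = field(repr=False)

    @property
    def K(self) -> np.ndarray:
        return np.hstack([self.S, self.Kbg])

    @property
    def Kprime(self) -> np.ndarray:
        return np.hstack([self.S, self.Kbg, self.Kbl])

    @property
    def n_columns(self) -> int:
        return self.S.shape[1] + self.Kbg.shape[1] + self.Kbl.shape[1]

    @classmethod
    def build(
        cls,
        refs: ReferenceLibrary,
        background: BackgroundBasis,
        basis: GaussianBasis,
        cond_threshold: float = DEFAULT_COND_THRESHOLD,
    ) -> "AugmentedModel":
        grid = refs.grid
        grid.require_match(background.grid, "background basis")
        grid.require_match(basis.grid, "Gaussian basis")
        Kprime = np.hstack([refs.matrix, background.matrix, basis.matrix])
        if Kprime.shape[1] >= grid.p:
            raise ValueError("C + M + L must be smaller than the channel count")
        sv = scipy.linalg.svdvals(Kprime)
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        if cond > cond_threshold:
            blocks = {
                "S": refs.matrix,
                "Kbg": background.matrix,
                "Kbl": basis.matrix,
                "[S,Kbg]": np.hstack([refs.matrix, background.matrix]),
            }
            detail = ", ".join(
                f"cond({name})={np.linalg.cond(m):.3g}" for name, m in blocks.items()
            )
            raise DegenerateModelError(
                f"augmented model is rank deficient: cond(K')={cond:.3g} "
                f"exceeds {cond_threshold:.3g} ({detail})"
            )
        Q, R = np.linalg.qr(Kprime)
        return cls(
            grid=grid,
            S=refs.matrix,
            Kbg=background.matrix,
            Kbl=basis.matrix,
            condition_number=cond,
            _Q=Q,
            _R=R,
        )

    def solve(self, values: np.ndarray) -> np.ndarray:
        """Least-squares coefficients of ``values`` on [S, Kbg, Kbl]."""
        return scipy.linalg.solve_triangular(self._R, self._Q.T @ values, lower=False)

    def correct(self, x: Spectrum) -> BaselineResult:
        self.grid.require_match(x.grid, f"spectrum {x.label!r}")
        y = self.solve(x.values)
        C = self.S.shape[1]
        M = self.Kbg.shape[1]
        g, ybg, ybl = y[:C], y[C : C + M], y[C + M :]
        baseline = self.Kbl @ ybl
        corrected = x.values - baseline
        residual = x.values - (self.S @ g + self.Kbg @ ybg + baseline)
        return BaselineResult(
            baseline=Spectrum(self.grid, baseline, label=f"{x.label}:lsm-baseline"),
            corrected=Spectrum(self.grid, corrected, label=f"{x.label}:lsm"),
            method="lsm",
            coefficients=y,
            signature_coeffs=g,
            background_coeffs=ybg,
            baseline_coeffs=ybl,
            residual_norm=float(np.linalg.norm(residual)),
            condition_number=self.condition_number,
        )


def _whitened_model(
    refs: ReferenceLibrary,
    background: BackgroundBasis,
    basis: GaussianBasis,
    noise: NoiseModel,
    cond_threshold: float,
) -> tuple[AugmentedModel, np.ndarray]:
    """Generalized least squares: pre-scale rows by 1/std before factoring."""
    std = noise.std
    if std.size != refs.grid.p:
        raise ValueError("noise model length must equal the channel count")
    w = 1.0 / std

    def scale(m: np.ndarray) -> np.ndarray:
        return m * w[:, None]

    scaled_refs = ReferenceLibrary(refs.grid, scale(refs.matrix), refs.names)
    scaled_bg = BackgroundBasis(refs.grid, scale(background.matrix))
    scaled_basis = GaussianBasis(
        basis.grid, scale(basis.matrix), basis.L, basis.centers, basis.sigma, basis.delta_m
    )
    return AugmentedModel.build(scaled_refs, scaled_bg, scaled_basis, cond_threshold), w


def fit_lsm_baseline(
    x: Spectrum,
    refs: ReferenceLibrary,
    background: BackgroundBasis,
    basis: GaussianBasis,
    noise: NoiseModel | None = None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> BaselineResult:
    """Correct one spectrum by the joint subspace fit.

    With ``noise`` given, estimation is generalized least squares (rows
    scaled by the reciprocal noise standard deviation); the returned
    baseline and corrected spectrum are always in raw counts.
    """
    return correct_batch([x], refs, background, basis, noise, cond_threshold)[0]


def correct_batch(
    spectra: Sequence[Spectrum],
    refs: ReferenceLibrary,
    background: BackgroundBasis,
    basis: GaussianBasis,
    noise: NoiseModel | None = None,
    cond_threshold: float = DEFAULT_COND_THRESHOLD,
) -> list[BaselineResult]:
    """Correct many spectra, factorizing the model matrices exactly once."""
    if not spectra:
        raise ValueError("no spectra to correct")
    if noise is None:
        model = AugmentedModel.build(refs, background, basis, cond_threshold)
        return [model.correct(x) for x in spectra]
    model, w = _whitened_model(refs, background, basis, noise, cond_threshold)
    out = []
    for x in spectra:
        refs.grid.require_match(x.grid, f"spectrum {x.label!r}")
        y = model.solve(w * x.values)
        C = refs.matrix.shape[1]
        M = background.matrix.shape[1]
        g, ybg, ybl = y[:C], y[C : C + M], y[C + M :]
        baseline = basis.matrix @ ybl  # raw-space baseline from whitened fit
        corrected = x.values - baseline
        residual = x.values - (refs.matrix @ g + background.matrix @ ybg + baseline)
        out.append(
            BaselineResult(
                baseline=Spectrum(refs.grid, baseline, label=f"{x.label}:lsm-baseline"),
                corrected=Spectrum(refs.grid, corrected, label=f"{x.label}:lsm"),
                method="lsm",
                coefficients=y,
                signature_coeffs=g,
                background_coeffs=ybg,
                baseline_coeffs=ybl,
                residual_norm=float(np.linalg.norm(residual)),
                condition_number=model.condition_number,
            )
        )
    return out
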