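"""Model-error metric, adaptive subspace detector and ROC evaluation.

RMSME (root mean square modeling error) scores how well a corrected
spectrum x' is explained by the known subspace K = [S, Kbg]: the
least-squares residual n = x' - K yhat is summarized as
sqrt(mean(n_i^2)).  A corrector that removes the baseline without
distorting the Raman signature leaves only noise in n.

The adaptive subspace detector (ASD) is the GLRT for the two-hypothesis
linear subspace model (background only vs background + agent):

    T(x') = (x'^T P_Kbg_perp x'  -  x'^T P_K_perp x') / (x'^T P_K_perp x')

i.e. the extra energy explained by adding the agent signatures, relative
to the energy neither subspace explains.  Because span(Kbg) is nested in
span(K), T >= 0 always, and T is invariant to rescaling x'.  The agent is
declared present when T exceeds the threshold.

ROC curves sweep the threshold over the pooled statistic values with a
strict-inequality convention and are anchored at (0,0) and (1,1); AUC is
the trapezoid-rule area.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    BackgroundBasis,
    DegenerateModelError,
    ReferenceLibrary,
    Spectrum,
)

__all__ = [
    "MetricResult",
    "DetectionResult",
    "ROCCurve",
    "rmsme",
    "asd_statistic",
    "asd_statistics",
    "roc_curve",
]

_COND_THRESHOLD = 1e10


@dataclass
class MetricResult:
    """RMSME value with the residual and fitted coefficients behind it."""

    rmsme: float
    modeling_error: np.ndarray
    fitted_coeffs: np.ndarray


@dataclass
class DetectionResult:
    """ASD statistic, optional thresholded decision, and degeneracy flag."""

    statistic: float
    threshold: float | None = None
    decision: str | None = None
    in_span: bool = False


@dataclass
class ROCCurve:
    """Detection curve: P_fa vs P_d over the swept threshold, plus AUC."""

    pfa: np.ndarray
    pd: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.pfa.tolist(), self.pd.tolist()))


def _orthonormal_basis(matrix: np.ndarray, name: str) -> np.ndarray:
    sv = np.linalg.svd(matrix, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > _COND_THRESHOLD:
        raise DegenerateModelError(f"{name} is rank deficient")
    Q, _ = np.linalg.qr(matrix)
    return Q


def _check_inputs(
    x: Spectrum, refs: ReferenceLibrary, background: BackgroundBasis
) -> np.ndarray:
    refs.grid.require_match(x.grid, "spectrum")
    refs.grid.require_match(background.grid, "background basis")
    return np.hstack([refs.matrix, background.matrix])


def rmsme(
    x_corrected: Spectrum,
    refs: ReferenceLibrary,
    background: BackgroundBasis,
) -> MetricResult:
    """Root mean square modeling error of x' against K = [S, Kbg]."""
    K = _check_inputs(x_corrected, refs, background)
    sv = np.linalg.svd(K, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > _COND_THRESHOLD:
        raise DegenerateModelError("K = [S, Kbg] is rank deficient")
    yhat, *_ = np.linalg.lstsq(K, x_corrected.values, rcond=None)
    n = x_corrected.values - K @ yhat
    return MetricResult(
        rmsme=float(np.sqrt(np.mean(n**2))),
        modeling_error=n,
        fitted_coeffs=yhat,
    )


def _asd_from_bases(
    values: np.ndarray, Qk: np.ndarray, Qbg: np.ndarray
) -> tuple[float, bool]:
    total = float(values @ values)
    e_k = total - float(np.sum((Qk.T @ values) ** 2))
    e_bg = total - float(np.sum((Qbg.T @ values) ** 2))
    num = max(e_bg - e_k, 0.0)  # nested subspaces: clamp roundoff
    if e_k <= 1e-12 * total:
        return float("inf"), True
    return num / e_k, False


def asd_statistic(
    x_corrected: Spectrum,
    refs: ReferenceLibrary,
    background: BackgroundBasis,
    threshold: float | None = None,
) -> DetectionResult:
    """ASD statistic for one corrected spectrum; agent declared present
    when the statistic exceeds ``threshold`` (if given)."""
    K = _check_inputs(x_corrected, refs, background)
    if not np.any(x_corrected.values):
        raise ValueError("spectrum is identically zero")
    Qk = _orthonormal_basis(K, "K = [S, Kbg]")
    Qbg = _orthonormal_basis(background.matrix, "Kbg")
    t, in_span = _asd_from_bases(x_corrected.values, Qk, Qbg)
    decision = None
    if threshold is not None:
        decision = "agent_present" if t > threshold else "agent_absent"
    return DetectionResult(statistic=t, threshold=threshold, decision=decision, in_span=in_span)


def asd_statistics(
    spectra: Sequence[Spectrum],
    refs: ReferenceLibrary,
    background: BackgroundBasis,
) -> np.ndarray:
    """ASD statistics for a batch, factorizing the subspaces once."""
    if not spectra:
        raise ValueError("no spectra given")
    K = _check_inputs(spectra[0], refs, background)
    Qk = _orthonormal_basis(K, "K = [S, Kbg]")
    Qbg = _orthonormal_basis(background.matrix, "Kbg")
    out = np.empty(len(spectra))
    for i, s in enumerate(spectra):
        refs.grid.require_match(s.grid, f"spectrum {s.label!r}")
        out[i], _ = _asd_from_bases(s.values, Qk, Qbg)
    return out


def roc_curve(
    stats_h1: Sequence[float], stats_h0: Sequence[float]
) -> ROCCurve:
    """ROC of the detector: threshold swept over pooled statistic values,
    strict inequality at the threshold, anchored at (0,0) and (1,1)."""
    h1 = np.asarray(stats_h1, dtype=float)
    h0 = np.asarray(stats_h0, dtype=float)
    if h1.size == 0 or h0.size == 0:
        raise ValueError("both statistic lists must be non-empty")
    thresholds = np.unique(np.concatenate([h1, h0]))[::-1]
    h0s = np.sort(h0)
    h1s = np.sort(h1)
    pfa = (h0.size - np.searchsorted(h0s, thresholds, side="right")) / h0.size
    pd = (h1.size - np.searchsorted(h1s, thresholds, side="right")) / h1.size
    pfa = np.concatenate([[0.0], pfa, [1.0]])
    pd = np.concatenate([[0.0], pd, [1.0]])
    auc = float(np.trapezoid(pd, pfa))
    return ROCCurve(pfa=pfa, pd=pd, auc=auc)
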