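"""Classic baseline correctors: IMF, RCF and the penalized-least-squares family.

The penalized-least-squares (Whittaker) correctors all solve the same
weighted smoothing system

    (W + lambda * D'D) b = W x

with D the (p-2) x p second-difference operator, and differ only in how
the per-channel weights w_i in [0, 1] are updated from the residual
d = x - b:

* ALS    : w_i = alpha where x_i >= b_i, 1 - alpha where x_i < b_i.
* AirPLS : w_i = 0 where x_i >= b_i, exp(j (x_i - b_i) / |d-|_1) below,
           stopping when |d-|_1 < 0.001 |x|_1.
* ArPLS  : logistic weights from the mean/std of the negative residuals,
           w_i = 1 below the baseline.

IMF smooths by iterating a sliding-window median; RCF takes the lower
rolling-circle envelope (grayscale opening with a circular structuring
element).  Window/radius parameters are given in cm^-1 and converted to
channels on the spectrum's own grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.linalg
import scipy.ndimage
import scipy.sparse
from numpy.lib.stride_tricks import sliding_window_view

from .core import BaselineResult, SingularSystemError, Spectrum

__all__ = [
    "PLSState",
    "second_difference_matrix",
    "pls_solve",
    "als_baseline",
    "airpls_baseline",
    "arpls_baseline",
    "imf_baseline",
    "rcf_baseline",
]


@dataclass
class PLSState:
    """Final iteration state of a penalized-least-squares corrector."""

    weights: np.ndarray
    baseline: np.ndarray
    lam: float
    iteration: int
    residual: np.ndarray
    converged: bool


def second_difference_matrix(p: int) -> scipy.sparse.csr_matrix:
    """The (p-2) x p operator with stencil [1, -2, 1]; annihilates affine vectors."""
    if p < 3:
        raise ValueError("p must be >= 3")
    return scipy.sparse.diags(
        [np.ones(p - 2), -2.0 * np.ones(p - 2), np.ones(p - 2)],
        offsets=[0, 1, 2],
        shape=(p - 2, p),
        format="csr",
    )


@lru_cache(maxsize=32)
def _penalty_bands(p: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals (main, +1, +2) of D'D for the banded Cholesky solve."""
    D = second_difference_matrix(p)
    A = (D.T @ D).todia()
    # offsets of a dia_matrix are sorted ascending; pick what we need
    off = {o: A.data[i] for i, o in enumerate(A.offsets)}
    d0 = off[0].copy()
    d1 = off[1].copy()  # stored with leading padding per dia convention
    d2 = off[2].copy()
    return d0, d1, d2


def pls_solve(x: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    """Solve (W + lam D'D) b = W x by a symmetric banded factorization."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.ndim != 1 or w.shape != x.shape:
        raise ValueError("x and weights must be 1-D vectors of equal length")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if not np.any(w > 0):
        raise SingularSystemError("all-zero weights: smoothing system is singular")
    p = x.size
    d0, d1, d2 = _penalty_bands(p)
    ab = np.zeros((3, p))
    ab[0] = lam * d2  # second superdiagonal (dia padding already in place)
    ab[1] = lam * d1
    ab[2] = lam * d0 + w
    rhs = w * x
    try:
        b = scipy.linalg.solveh_banded(ab, rhs, lower=False)
        # one step of iterative refinement with an extended-precision
        # residual: the system's condition number grows with lambda and a
        # plain banded solve loses accuracy for very stiff penalties
        for _ in range(1 if lam <= 1e6 else 2):
            r = rhs.astype(np.longdouble) - _apply_system(b, w, lam)
            b = b + scipy.linalg.solveh_banded(ab, r.astype(float), lower=False)
        return b
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate weights
        raise SingularSystemError(f"smoothing system not positive definite: {exc}") from exc


def _apply_system(b: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """(W + lam D'D) b in extended precision, using the banded structure."""
    bl = b.astype(np.longdouble)
    u = bl[:-2] - 2.0 * bl[1:-1] + bl[2:]  # D b
    out = w.astype(np.longdouble) * bl
    out[:-2] += np.longdouble(lam) * u
    out[1:-1] += np.longdouble(lam) * (-2.0 * u)
    out[2:] += np.longdouble(lam) * u
    return out


def _pls_result(
    x: Spectrum, state: PLSState, method: str
) -> BaselineResult:
    base = Spectrum(x.grid, state.baseline, label=f"{x.label}:{method}-baseline")
    corr = Spectrum(x.grid, x.values - state.baseline, label=f"{x.label}:{method}")
    return BaselineResult(
        baseline=base,
        corrected=corr,
        method=method,
        converged=state.converged,
        n_iter=state.iteration,
        diagnostics={"weights": state.weights, "lambda": state.lam},
    )


def als_baseline(
    x: Spectrum,
    lam: float = 1000.0,
    alpha: float = 0.01,
    max_iter: int = 50,
) -> BaselineResult:
    """Asymmetric least squares: constant weight alpha above the baseline,
    1 - alpha below.  Stops when the above/below pattern repeats (the weight
    update admits 2-cycles, so the last two patterns are checked)."""
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must lie in (0, 0.5)")
    if not (1e-3 <= alpha <= 1e-1):
        warnings.warn(
            f"alpha={alpha:g} is outside the recommended [1e-3, 1e-1] range",
            UserWarning,
            stacklevel=2,
        )
    v = x.values
    w = np.ones_like(v)
    history: list[bytes] = []
    converged = False
    b = v.copy()
    it = 0
    for it in range(1, max_iter + 1):
        b = pls_solve(v, w, lam)
        above = v >= b
        key = np.packbits(above).tobytes()
        if key in history:
            converged = True
            break
        history.append(key)
        if len(history) > 2:
            history.pop(0)
        w = np.where(above, alpha, 1.0 - alpha)
    state = PLSState(w, b, lam, it, v - b, converged)
    return _pls_result(x, state, "als")


def airpls_baseline(
    x: Spectrum, lam: float = 50.0, max_iter: int = 50
) -> BaselineResult:
    """Adaptive iteratively reweighted PLS.

    Channels at or above the baseline get zero weight; channels below get
    ``exp(j d_i / |d-|_1)`` with j the iteration number, so deep dips are
    reweighted progressively.  Terminates when the total negative residual
    drops below 0.1% of the total signal.
    """
    v = x.values
    norm_x = np.abs(v).sum()
    w = np.ones_like(v)
    converged = False
    b = v.copy()
    it = 0
    for it in range(1, max_iter + 1):
        b = pls_solve(v, w, lam)
        d = v - b
        neg = d < 0
        dneg_norm = float(-d[neg].sum())
        if dneg_norm < 0.001 * norm_x or not np.any(neg):
            converged = True
            break
        w = np.zeros_like(v)
        w[neg] = np.exp(it * d[neg] / dneg_norm)
    state = PLSState(w, b, lam, it, v - b, converged)
    return _pls_result(x, state, "airpls")


def arpls_baseline(
    x: Spectrum, lam: float = 200.0, tol: float = 1e-6, max_iter: int = 100
) -> BaselineResult:
    """Asymmetrically reweighted PLS with logistic weights.

    Above the baseline the weight decays logistically with the residual,
    centred 2 standard deviations of the negative-residual (noise) part
    above its mean; below the baseline the weight is 1.  Stops when the
    relative change of the weight vector falls below ``tol``.
    """
    v = x.values
    w = np.ones_like(v)
    converged = False
    degenerate = False
    b = v.copy()
    it = 0
    scale = float(np.max(np.abs(v))) or 1.0
    for it in range(1, max_iter + 1):
        b = pls_solve(v, w, lam)
        d = v - b
        dneg = d[d < 0]
        if dneg.size == 0 or float(np.std(dneg)) <= 1e-5 * scale:
            # noiseless residuals: the logistic argument is undefined; the
            # hard threshold 1{x < b} is the limiting weight pattern and the
            # current baseline is already its fixed point, so stop here
            w = (d < 0).astype(float)
            degenerate = True
            converged = True
            break
        m = float(np.mean(dneg))
        s = float(np.std(dneg))
        arg = np.clip(2.0 * (d + m - 2.0 * s) / s, -500.0, 500.0)
        new_w = np.where(d < 0, 1.0, 1.0 / (1.0 + np.exp(arg)))
        change = np.linalg.norm(new_w - w) / max(np.linalg.norm(w), 1e-300)
        w = new_w
        if change < tol:
            converged = True
            break
    state = PLSState(w, b, lam, it, v - b, converged)
    res = _pls_result(x, state, "arpls")
    res.diagnostics["degenerate_weights"] = degenerate
    return res


def imf_baseline(
    x: Spectrum, window_cm: float = 300.0, n_iter: int = 5
) -> BaselineResult:
    """Iterative median filter; window in cm^-1, converted to an odd channel
    count, edges reflected."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    size = x.grid.channels_from_cm(window_cm, minimum=3)
    if size % 2 == 0:
        size += 1
    if size > x.grid.p:
        raise ValueError("median window is wider than the spectrum")
    b = x.values.copy()
    for _ in range(n_iter):
        b = scipy.ndimage.median_filter(b, size=size, mode="reflect")
    return BaselineResult(
        baseline=Spectrum(x.grid, b, label=f"{x.label}:imf-baseline"),
        corrected=Spectrum(x.grid, x.values - b, label=f"{x.label}:imf"),
        method="imf",
        n_iter=n_iter,
        diagnostics={"window_channels": size},
    )


def rcf_baseline(
    x: Spectrum, radius_cm: float = 100.0, intensity_scale: float = 1.0
) -> BaselineResult:
    """Rolling circle filter: lower envelope by grayscale opening with a
    circular structuring element.

    The circle radius is ``radius_cm`` along the wavenumber axis (converted
    to channels); ``intensity_scale`` sets how many intensity counts one
    channel of circle height corresponds to.  Edges are continued by odd
    reflection so an affine ramp is reproduced exactly.
    """
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    r = x.grid.channels_from_cm(radius_cm, minimum=1)
    if radius_cm > x.grid.span / 2:
        raise ValueError("circle radius exceeds half the axis span")
    t = np.arange(-r, r + 1, dtype=float)
    ball = intensity_scale * np.sqrt(r**2 - t**2)
    v = x.values
    # erosion: min over the window of (x - ball)
    vp = np.pad(v, r, mode="reflect", reflect_type="odd")
    ero = np.min(sliding_window_view(vp, 2 * r + 1) - ball, axis=1)
    # dilation of the erosion: max over the window of (ero + ball)
    ep = np.pad(ero, r, mode="reflect", reflect_type="odd")
    b = np.max(sliding_window_view(ep, 2 * r + 1) + ball, axis=1)
    b = np.minimum(b, v)  # opening is a lower envelope; guard edge padding
    return BaselineResult(
        baseline=Spectrum(x.grid, b, label=f"{x.label}:rcf-baseline"),
        corrected=Spectrum(x.grid, v - b, label=f"{x.label}:rcf"),
        method="rcf",
        diagnostics={"radius_channels": r},
    )
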