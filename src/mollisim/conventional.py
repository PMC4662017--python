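"""Conventional MOLLI post-processing.

The baseline against which dictionary matching is compared: per pixel, the
magnitude inversion-recovery curve is fitted with the 3-parameter model

    S(TI) = A - B * exp(-TI / T1*)

after restoring signal polarity by exhaustive sign-flip search over the
sorted-TI prefix, and the apparent T1* is converted to T1 with the
FLASH-derived Look-Locker correction T1 = T1* (B/A - 1).  The readout
train shortens the apparent recovery, so T1* < T1 always, and because the
correction factor was derived for FLASH rather than the bSSFP readout
MOLLI actually uses, the corrected T1 systematically underestimates the
true value -- increasingly so for long T1 and for schemes with little
recovery time between inversions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .maps import MolliSeries, ParameterMap

__all__ = ["IRFitResult", "FitFailure", "fit_ir3", "ll_correct",
           "conventional_map", "LookLockerT1"]

DEFAULT_T1_STARTS = (200.0, 600.0, 1000.0, 1600.0)


class FitFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class IRFitResult:
    """3-parameter magnitude IR fit: S(TI) = A - B exp(-TI/T1*)."""

    a: float
    b: float
    t1_star_ms: float
    t1_ms: float
    inversion_index: int
    residual: float


def _model(theta, tis):
    a, b, t1s = theta
    return a - b * np.exp(-tis / t1s)


def fit_ir3(tis_ms: np.ndarray, s: np.ndarray,
            t1_starts_ms=DEFAULT_T1_STARTS,
            apply_ll_correction: bool = True) -> IRFitResult:
    """Polarity-restored 3-parameter fit of a magnitude IR series.

    ``tis_ms`` must be sorted ascending with ``s`` ordered accordingly.
    For every candidate inversion index k the first k samples are negated
    and the model is fitted by trust-region least squares from each T1*
    start; the global residual minimum over k and starts wins.  Raises
    :class:`FitFailure` if no start converges (callers mark the pixel
    invalid rather than aborting a whole map).
    """
    tis = np.asarray(tis_ms, float)
    s = np.asarray(s, float)
    if tis.size != s.size:
        raise ValueError("TIs and samples must have equal length")
    if tis.size < 4:
        raise ValueError("need at least 4 samples for a 3-parameter fit")
    if np.any(np.diff(tis) <= 0):
        raise ValueError("TIs must be sorted strictly ascending")

    best = None
    for k in range(tis.size + 1):
        sk = s.copy()
        sk[:k] = -sk[:k]
        a0 = max(sk[-1], 1e-6)
        b0 = max(a0 + abs(sk[0]), 1e-6)
        for t1s0 in t1_starts_ms:
            try:
                sol = least_squares(
                    lambda th: _model(th, tis) - sk,
                    x0=[a0, b0, t1s0],
                    bounds=([-np.inf, 0.0, 1.0], [np.inf, np.inf, 1e6]),
                    method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                    max_nfev=500)
            except Exception:
                continue
            if not sol.success:
                continue
            resid = float(2.0 * sol.cost)
            if best is None or resid < best[0] - 1e-15:
                best = (resid, k, sol.x)
    if best is None:
        raise FitFailure("3-parameter IR fit did not converge at any "
                         "polarity/start combination")
    resid, k, (a, b, t1s) = best
    if apply_ll_correction and a > 0:
        t1 = ll_correct(a, b, t1s)
    else:
        t1 = float("nan")
    return IRFitResult(a=float(a), b=float(b), t1_star_ms=float(t1s),
                       t1_ms=float(t1), inversion_index=int(k),
                       residual=resid)


def ll_correct(a: float, b: float, t1_star_ms: float) -> float:
    """Look-Locker correction T1 = T1* (B/A - 1).

    Exact for an ideal continuous FLASH readout; applied to MOLLI by
    convention.  A <= 0 marks an unphysical fit (invalid pixel).
    """
    if a <= 0:
        raise ValueError("Look-Locker correction undefined for A <= 0")
    return t1_star_ms * (b / a - 1.0)


class LookLockerT1(BaseEstimator):
    """Stateless sklearn-style estimator wrapping the conventional fit.

    ``predict(X)`` maps rows of magnitude samples (taken at ``tis_ms``,
    already sorted ascending) to Look-Locker-corrected T1 values; pixels
    whose fit fails or yields A <= 0 come back NaN.
    """

    def __init__(self, tis_ms=None, t1_starts_ms=DEFAULT_T1_STARTS):
        self.tis_ms = tis_ms
        self.t1_starts_ms = t1_starts_ms

    def fit(self, X=None, y=None):
        if self.tis_ms is None:
            raise ValueError("tis_ms must be set")
        return self

    def predict(self, X):
        self.fit()
        X = np.atleast_2d(np.asarray(X, float))
        out = np.full(X.shape[0], np.nan)
        for i, row in enumerate(X):
            try:
                r = fit_ir3(self.tis_ms, row, self.t1_starts_ms)
                out[i] = r.t1_ms
            except (FitFailure, ValueError):
                pass
        return out


def conventional_map(series: MolliSeries,
                     mask: np.ndarray | None = None,
                     t1_starts_ms=DEFAULT_T1_STARTS) -> ParameterMap:
    """Per-pixel 3-parameter fit + Look-Locker correction over the mask.

    Samples are sorted by effective TI before fitting (groups merged, the
    usual MOLLI convention).  Identical pixel vectors (common in
    noise-free synthetic data) are fitted once and cached.  Invalid pixels
    (failed fit or A <= 0) are excluded from the returned mask.
    """
    order = np.argsort(series.tis_ms)
    tis = series.tis_ms[order]
    ny, nx = series.shape
    if mask is None:
        mask = np.ones((ny, nx), bool)
    mask = np.asarray(mask, bool)
    if mask.shape != (ny, nx):
        raise ValueError("mask shape does not match the series")
    t1 = np.full((ny, nx), np.nan)
    resid = np.full((ny, nx), np.nan)
    amp = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), bool)
    if not mask.any():
        warnings.warn("empty mask: no pixels fitted", stacklevel=2)
    cache: dict[bytes, tuple[float, float, float, bool]] = {}
    for iy, ix in zip(*np.nonzero(mask)):
        sig = series.images[order, iy, ix]
        key = sig.tobytes()
        if key not in cache:
            try:
                r = fit_ir3(tis, sig, t1_starts_ms)
                ok = np.isfinite(r.t1_ms)
                cache[key] = (r.t1_ms, r.residual, r.a, ok)
            except (FitFailure, ValueError):
                cache[key] = (np.nan, np.nan, np.nan, False)
        t1v, rv, av, ok = cache[key]
        if ok:
            t1[iy, ix] = t1v
            resid[iy, ix] = rv
            amp[iy, ix] = av
            valid[iy, ix] = True
    return ParameterMap(
        t1_ms=t1, residual=resid, amplitude=amp, mask=valid,
        provenance={
            "method": "conventional-molli",
            "model": "S(TI) = A - B exp(-TI/T1*), LL correction",
            "t1_starts_ms": list(t1_starts_ms),
        })
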