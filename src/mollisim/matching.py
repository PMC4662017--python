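"""Dictionary matching: least-squared-difference search with a free
non-negative amplitude per entry.

For a measured magnitude vector s and dictionary entry d_k, the optimal
scale is a_k = max(0, <s, d_k> / <d_k, d_k>) and the residual is
r_k = ||s - a_k d_k||^2; the entry minimizing r_k wins, with ties broken
toward smaller (T1, T2).  The free amplitude absorbs the unknown per-pixel
equilibrium magnetization, which makes the match invariant to the overall
signal scale while still returning a physical amplitude estimate.  The
search is a full linear scan of the dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dictionary import SignalDictionary
from .maps import MolliSeries, ParameterMap

__all__ = ["MatchResult", "DictionaryMatcher", "match_signal",
           "match_series", "TiMismatchError"]


class TiMismatchError(ValueError):
    """Series TIs differ from the dictionary's; rebuild required."""

    def __init__(self, series_tis, dict_tis):
        self.series_tis = np.asarray(series_tis, float)
        self.dict_tis = np.asarray(dict_tis, float)
        super().__init__(
            "effective TIs of the series do not match the dictionary "
            f"(series: {np.round(self.series_tis, 2).tolist()}, "
            f"dictionary: {np.round(self.dict_tis, 2).tolist()}); the "
            "dictionary must be rebuilt for this session's actual timing")


@dataclass(frozen=True)
class MatchResult:
    t1_ms: float
    t2_ms: float
    amplitude: float
    residual: float
    entry_index: int


class DictionaryMatcher(BaseEstimator, RegressorMixin):
    """Nearest-simulated-signal regressor over a (T1, T2) dictionary.

    fit(X, y) stores the dictionary: X is the (n_entries, n_images) array
    of simulated magnitude vectors and y the (n_entries, 2) array of
    (T1, T2) pairs (milliseconds).  predict(X) maps measured magnitude
    vectors to the (T1, T2) of the amplitude-scaled least-squares nearest
    entry.  Entries must be sorted by (T1, T2); argmin then realizes the
    smaller-(T1, T2) tie-break for free.
    """

    def __init__(self, tis_ms=None):
        self.tis_ms = tis_ms

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or y.shape != (X.shape[0], 2):
            raise ValueError("X must be (n_entries, n_images) and y "
                             "(n_entries, 2)")
        order = np.lexsort((y[:, 1], y[:, 0]))
        self.signals_ = X[order]
        self.params_ = y[order]
        self.norms_ = np.einsum("ij,ij->i", self.signals_, self.signals_)
        if np.any(self.norms_ == 0):
            raise ValueError("dictionary contains an all-zero entry")
        self.n_images_ = X.shape[1]
        return self

    @classmethod
    def from_dictionary(cls, dictionary: SignalDictionary
                        ) -> "DictionaryMatcher":
        est = cls(tis_ms=np.asarray(dictionary.tis_ms, float))
        est.fit(dictionary.signals,
                np.column_stack([dictionary.t1_ms, dictionary.t2_ms]))
        est.digest_ = dictionary.meta.get("digest")
        return est

    def _match(self, S: np.ndarray):
        """Vectorized match of (n_pixels, n_images) magnitude rows."""
        dots = S @ self.signals_.T                    # (n_pix, n_entries)
        amps = np.maximum(dots / self.norms_, 0.0)
        resid = np.einsum("ij,ij->i", S, S)[:, None] \
            - 2.0 * amps * dots + amps ** 2 * self.norms_
        best = np.argmin(resid, axis=1)               # first = smallest T1,T2
        rows = np.arange(S.shape[0])
        return best, amps[rows, best], np.maximum(resid[rows, best], 0.0)

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_images_:
            raise ValueError(
                f"signal length {X.shape[1]} does not match dictionary "
                f"image count {self.n_images_}")
        best, _, _ = self._match(X)
        return self.params_[best]

    def match(self, s: np.ndarray) -> MatchResult:
        s = np.asarray(s, float)
        if s.ndim != 1:
            raise ValueError("match() takes a single signal vector")
        if s.size != self.n_images_:
            raise ValueError(
                f"signal length {s.size} does not match dictionary image "
                f"count {self.n_images_}")
        if np.any(s < 0):
            raise ValueError("magnitude signals must be non-negative")
        if not np.any(s > 0):
            raise ValueError("all-zero signal: masked/empty pixel")
        best, amp, resid = self._match(s[None, :])
        k = int(best[0])
        return MatchResult(t1_ms=float(self.params_[k, 0]),
                           t2_ms=float(self.params_[k, 1]),
                           amplitude=float(amp[0]),
                           residual=float(resid[0]), entry_index=k)


def match_signal(s: np.ndarray,
                 dictionary: SignalDictionary) -> MatchResult:
    """Best amplitude-scaled least-squares dictionary entry for one pixel."""
    return DictionaryMatcher.from_dictionary(dictionary).match(s)


def match_series(series: MolliSeries, dictionary: SignalDictionary,
                 mask: np.ndarray | None = None,
                 ti_tolerance_ms: float = 1.0) -> ParameterMap:
    """Pixel-by-pixel dictionary matching of a MOLLI magnitude series.

    The series' effective TIs must equal the dictionary's within
    ``ti_tolerance_ms`` per image; otherwise the dictionary was simulated
    for different timing and a rebuild is demanded.  Unmasked and all-zero
    pixels are flagged NaN.  The result does not depend on pixel order.
    """
    tis = np.asarray(series.tis_ms, float)
    dtis = np.asarray(dictionary.tis_ms, float)
    if tis.size != dtis.size or \
            np.any(np.abs(tis - dtis) > ti_tolerance_ms):
        raise TiMismatchError(tis, dtis)
    ny, nx = series.shape
    if mask is None:
        mask = np.ones((ny, nx), bool)
    mask = np.asarray(mask, bool)
    if mask.shape != (ny, nx):
        raise ValueError("mask shape does not match the series")

    est = DictionaryMatcher.from_dictionary(dictionary)
    shape = (ny, nx)
    t1 = np.full(shape, np.nan)
    t2 = np.full(shape, np.nan)
    amp = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    valid = mask.copy()
    if not mask.any():
        import warnings
        warnings.warn("empty mask: no pixels matched", stacklevel=2)
    else:
        S = series.images[:, mask].T                  # (n_pix, n_images)
        nonzero = np.any(S > 0, axis=1)
        valid[mask] = nonzero
        if nonzero.any():
            best, a, r = est._match(S[nonzero])
            idx = np.nonzero(mask.ravel())[0][nonzero]
            t1.ravel()[idx] = est.params_[best, 0]
            t2.ravel()[idx] = est.params_[best, 1]
            amp.ravel()[idx] = a
            resid.ravel()[idx] = r
    return ParameterMap(
        t1_ms=t1, t2_ms=t2, amplitude=amp, residual=resid, mask=valid,
        provenance={
            "method": "dictionary-match",
            "dictionary_digest": dictionary.meta.get("digest"),
            "n_entries": dictionary.n_entries,
            "ti_tolerance_ms": ti_tolerance_ms,
        })
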