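"""Signal-dictionary construction over a (T1, T2) grid.

Every grid pair is simulated once through the exact expanded timeline with
a slice-profile ensemble of spins, and the magnitude of the complex
ensemble sum at each k-space-center instant becomes that entry's signal
vector.  Matching scanner magnitude images against these vectors is what
turns the simulation into a relaxometry method, so the dictionary records
enough provenance (acquisition-config digest, grid, step, spin count) to
refuse silent mismatches at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

import h5py
from numba import get_num_threads, set_num_threads

from ._kernel import propagate_grid
from .bloch import BlochNumericalError, Timeline
from .sequence import (AcquisitionParams, CardiacTiming, MolliScheme,
                       build_timeline, parse_scheme)
from .io import config_digest

__all__ = [
    "GridSpec", "SignalDictionary", "DigestMismatchError",
    "enumerate_grid", "slice_spin_positions", "simulate_entry",
    "build_dictionary", "save_dictionary", "load_dictionary",
]


class DigestMismatchError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridSpec:
    """Rectangular (T1, T2) grid in ms, with the physical T2 <= T1 cut.

    Values are generated as ``start + k*step`` exactly (no accumulated
    floating-point drift over long axes).  ``stop_inclusive`` controls, per
    axis, whether a stop landing on the lattice is kept.
    """

    t1_start_ms: float = 200.0
    t1_stop_ms: float = 1900.0
    t1_step_ms: float = 1.0
    t2_start_ms: float = 20.0
    t2_stop_ms: float = 400.0
    t2_step_ms: float = 1.0
    exclude_t2_gt_t1: bool = True
    t1_stop_inclusive: bool = True
    t2_stop_inclusive: bool = True

    def __post_init__(self):
        if self.t1_step_ms <= 0 or self.t2_step_ms <= 0:
            raise ValueError("grid steps must be positive")
        if self.t1_stop_ms < self.t1_start_ms or \
                self.t2_stop_ms < self.t2_start_ms:
            raise ValueError("grid stop must be >= start")

    def t1_values(self) -> np.ndarray:
        return _axis(self.t1_start_ms, self.t1_stop_ms, self.t1_step_ms,
                     self.t1_stop_inclusive)

    def t2_values(self) -> np.ndarray:
        return _axis(self.t2_start_ms, self.t2_stop_ms, self.t2_step_ms,
                     self.t2_stop_inclusive)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "t1_start_ms", "t1_stop_ms", "t1_step_ms", "t2_start_ms",
            "t2_stop_ms", "t2_step_ms", "exclude_t2_gt_t1",
            "t1_stop_inclusive", "t2_stop_inclusive")}


def _axis(start: float, stop: float, step: float,
          inclusive: bool) -> np.ndarray:
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    vals = start + step * np.arange(n)
    eps = 1e-9 * max(1.0, abs(stop))
    if not inclusive and vals.size and vals[-1] >= stop - eps:
        vals = vals[:-1]
    return vals


def enumerate_grid(spec: GridSpec) -> np.ndarray:
    """All (T1, T2) pairs as an (N, 2) array, sorted by (T1, T2).

    With ``exclude_t2_gt_t1`` the unphysical T2 > T1 corner is dropped.
    """
    t1 = spec.t1_values()
    t2 = spec.t2_values()
    if t1.size == 0 or t2.size == 0:
        raise ValueError("grid is empty")
    t1g = np.repeat(t1, t2.size)
    t2g = np.tile(t2, t1.size)
    if spec.exclude_t2_gt_t1:
        keep = t2g <= t1g + 1e-9
        t1g, t2g = t1g[keep], t2g[keep]
    if t1g.size == 0:
        raise ValueError("grid is empty after the T2 <= T1 cut")
    return np.column_stack([t1g, t2g])


def slice_spin_positions(n_spins: int, slice_thickness_mm: float,
                         slice_fov_factor: float = 2.0) -> np.ndarray:
    """Uniform spin positions (meters) across the slice profile.

    Spans ``slice_fov_factor`` times the slice thickness symmetrically
    about 0, so out-of-slice behavior of the excitation is represented.
    Requires an odd count so one spin sits exactly at slice center.
    """
    if n_spins < 3:
        raise ValueError("need at least 3 slice spins")
    if n_spins % 2 == 0:
        raise ValueError(
            f"n_spins must be odd so a spin sits at z=0, got {n_spins}")
    half = slice_fov_factor * slice_thickness_mm * 1e-3 / 2.0
    return np.linspace(-half, half, n_spins)


def _grid_signals(pairs_ms: np.ndarray, timeline: Timeline,
                  positions_m: np.ndarray, n_workers: int = 1) -> np.ndarray:
    from numba import config as numba_config
    old = get_num_threads()
    set_num_threads(min(max(int(n_workers), 1),
                        numba_config.NUMBA_NUM_THREADS))
    try:
        out, status = propagate_grid(
            timeline.duration_s, timeline.rf_amplitude_uT,
            timeline.rf_phase_rad, timeline.gradient_mT_m,
            timeline.is_crusher, timeline.adc_index,
            np.asarray(positions_m, float),
            np.asarray(pairs_ms[:, 0], float) * 1e-3,
            np.asarray(pairs_ms[:, 1], float) * 1e-3,
            timeline.n_images)
    finally:
        set_num_threads(old)
    bad = np.nonzero(status >= 0)[0]
    if bad.size:
        e = bad[0]
        raise BlochNumericalError(int(status[e])) from None
    return out


def simulate_entry(t1_ms: float, t2_ms: float, timeline: Timeline,
                   positions_m: np.ndarray,
                   magnitude: bool = True) -> np.ndarray:
    """Noise-free slice-ensemble signal for one (T1, T2) pair.

    Returns the per-image magnitude of the complex ensemble sum (or the
    complex sum itself with ``magnitude=False``).  Deterministic.
    """
    from .bloch import Isochromat, ensemble_signal
    if t1_ms <= 0 or t2_ms <= 0:
        raise ValueError(f"invalid relaxation pair T1={t1_ms}, T2={t2_ms}")
    try:
        sig = ensemble_signal(
            [Isochromat(z_position=float(z), t1_ms=t1_ms, t2_ms=t2_ms)
             for z in np.asarray(positions_m, float)], timeline)
    except BlochNumericalError as err:
        raise BlochNumericalError(err.event_index) from RuntimeError(
            f"simulation failed for T1={t1_ms} ms, T2={t2_ms} ms")
    return np.abs(sig) if magnitude else sig


@dataclass
class SignalDictionary:
    """Simulated signal vectors indexed by their (T1, T2) pair."""

    t1_ms: np.ndarray                 # (N,)
    t2_ms: np.ndarray                 # (N,)
    signals: np.ndarray               # (N, n_images), magnitudes
    tis_ms: np.ndarray                # (n_images,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t1_ms = np.asarray(self.t1_ms, float)
        self.t2_ms = np.asarray(self.t2_ms, float)
        self.signals = np.asarray(self.signals, float)
        self.tis_ms = np.asarray(self.tis_ms, float)
        if self.signals.shape != (self.t1_ms.size, self.tis_ms.size):
            raise ValueError("signals shape must be (entries, images)")

    @property
    def n_entries(self) -> int:
        return int(self.t1_ms.size)

    def entry_index(self, t1_ms: float, t2_ms: float) -> int:
        hit = np.nonzero((np.abs(self.t1_ms - t1_ms) < 1e-9)
                         & (np.abs(self.t2_ms - t2_ms) < 1e-9))[0]
        if hit.size != 1:
            raise KeyError(f"({t1_ms}, {t2_ms}) not in dictionary")
        return int(hit[0])


def build_dictionary(spec: GridSpec, params: AcquisitionParams,
                     scheme: MolliScheme | str, timing: CardiacTiming,
                     n_workers: int = 1) -> SignalDictionary:
    """Simulate the whole grid on the exact timeline.

    Entries are mutually independent, so the result is byte-identical for
    any ``n_workers``; they are stored sorted by (T1, T2).
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    pairs = enumerate_grid(spec)
    timeline = build_timeline(params, scheme, timing)
    positions = slice_spin_positions(params.n_slice_spins,
                                     params.slice_thickness_mm,
                                     params.slice_fov_factor)
    signals = _grid_signals(pairs, timeline, positions, n_workers)
    meta = {
        "digest": config_digest(params, scheme, timing),
        "grid": spec.to_dict(),
        "scheme": scheme.text,
        "n_slice_spins": int(params.n_slice_spins),
        "dt_us": float(params.dt_us),
        "n_entries": int(pairs.shape[0]),
    }
    return SignalDictionary(pairs[:, 0], pairs[:, 1], signals,
                            timeline.effective_tis_ms, meta)


def save_dictionary(path, dictionary: SignalDictionary) -> None:
    """HDF5 container: /t1_ms /t2_ms /signals /tis_ms + meta attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t1_ms", data=dictionary.t1_ms)
        f.create_dataset("t2_ms", data=dictionary.t2_ms)
        f.create_dataset("signals", data=dictionary.signals)
        f.create_dataset("tis_ms", data=dictionary.tis_ms)
        f.attrs["meta_json"] = json.dumps(dictionary.meta)
        f.attrs["format_version"] = 1


def load_dictionary(path, expected_digest: str | None = None,
                    allow_mismatch: bool = False) -> SignalDictionary:
    """Load and, when a digest is supplied, verify provenance.

    A dictionary simulated under one acquisition configuration is
    meaningless for another session, so a digest mismatch is refused
    unless explicitly overridden.
    """
    try:
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta_json"])
            d = SignalDictionary(
                t1_ms=f["t1_ms"][()], t2_ms=f["t2_ms"][()],
                signals=f["signals"][()], tis_ms=f["tis_ms"][()],
                meta=meta)
    except (OSError, KeyError) as err:
        raise OSError(f"corrupt or unreadable dictionary file {path}: "
                      f"{err}") from err
    if expected_digest is not None and \
            meta.get("digest") != expected_digest:
        if not allow_mismatch:
            raise DigestMismatchError(
                f"dictionary digest {meta.get('digest')} does not match "
                f"the session configuration digest {expected_digest}; "
                f"rebuild the dictionary or pass allow_mismatch=True")
    return d
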