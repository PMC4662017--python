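"""Digital phantoms and synthetic MOLLI acquisition.

Everything downstream of the scanner is testable without scanner data:
ground-truth T1/T2/M0 maps are laid out as disks (or a rectangular grid),
the full MOLLI timeline is Bloch-simulated once per distinct tissue, and
per-pixel complex Gaussian noise turns the noise-free complex signals into
Rician-distributed magnitudes, matching the statistics of scanner
magnitude images.

The default tissue table is the six-vial myocardial phantom: T1/T2 pairs
for pre-contrast normal myocardium (1048/50), blood (1570/196), edema
(1249/62), infarct (1361/64) and normal myocardium at 2-3 min (344/52)
and 13-15 min (413/50) post contrast.  A second fixture emulates a
Eurospin-style plate: T2 held near 52 ms with T1 spanning 212-1522 ms
(the intermediate T1 values are synthetic, chosen evenly spaced).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionary import simulate_entry, slice_spin_positions
from .maps import MolliSeries
from .sequence import (AcquisitionParams, CardiacTiming, MolliScheme,
                       build_timeline, parse_scheme)
from .io import config_digest

__all__ = [
    "Tissue", "PhantomMaps", "MYOCARDIAL_TISSUES", "EUROSPIN_TISSUES",
    "make_phantom", "make_rr_series", "simulate_acquisition",
]


@dataclass(frozen=True)
class Tissue:
    name: str
    t1_ms: float
    t2_ms: float


MYOCARDIAL_TISSUES: tuple[Tissue, ...] = (
    Tissue("normal_myocardium_pre", 1048.0, 50.0),
    Tissue("blood_pre", 1570.0, 196.0),
    Tissue("edema_pre", 1249.0, 62.0),
    Tissue("infarct_pre", 1361.0, 64.0),
    Tissue("normal_myocardium_post_2_3min", 344.0, 52.0),
    Tissue("normal_myocardium_post_13_15min", 413.0, 50.0),
)

# Synthetic Eurospin-style fixture: T1 endpoints 212 and 1522 ms with
# evenly spaced intermediates (the real plate's intermediate values are
# not reproduced here), T2 fixed near normal myocardium.
EUROSPIN_TISSUES: tuple[Tissue, ...] = tuple(
    Tissue(f"eurospin_{i + 1}", float(t1), 52.0)
    for i, t1 in enumerate(np.linspace(212.0, 1522.0, 6).round(0)))


@dataclass
class PhantomMaps:
    """Ground-truth per-pixel maps plus the region table."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    labels: np.ndarray                  # int, 0 = background
    tissues: tuple[Tissue, ...] = field(default_factory=tuple)

    def __post_init__(self):
        inside = self.labels > 0
        if np.any(self.t2_ms[inside] > self.t1_ms[inside]):
            raise ValueError("phantom contains T2 > T1 pixels")
        if np.any(self.t1_ms[inside] <= 0) or np.any(self.t2_ms[inside] <= 0):
            raise ValueError("labeled pixels need T1 >= T2 > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1_ms.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def make_phantom(layout: str = "disks",
                 tissue_table: tuple[Tissue, ...] | None = None,
                 shape: tuple[int, int] = (96, 96),
                 m0: float = 1.0) -> PhantomMaps:
    """Non-overlapping tissue regions on a square canvas.

    ``"disks"`` arranges one disk per tissue on a 2 x ceil(n/2) lattice;
    ``"grid"`` tiles rectangles.  Background pixels carry M0 = 0.
    """
    tissues = tuple(tissue_table) if tissue_table is not None \
        else MYOCARDIAL_TISSUES
    for t in tissues:
        if not (t.t1_ms >= t.t2_ms > 0):
            raise ValueError(f"tissue {t.name}: need T1 >= T2 > 0")
    ny, nx = shape
    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    m0map = np.zeros(shape)
    labels = np.zeros(shape, int)
    n = len(tissues)
    if layout == "disks":
        rows = 2 if n > 3 else 1
        cols = int(np.ceil(n / rows))
        radius = min(ny / (2.0 * rows), nx / (2.0 * cols)) * 0.7
        yy, xx = np.mgrid[0:ny, 0:nx]
        for i, tissue in enumerate(tissues):
            r, c = divmod(i, cols)
            cy = (r + 0.5) * ny / rows
            cx = (c + 0.5) * nx / cols
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
            if np.any(labels[disk] != 0):
                raise ValueError("phantom layout produced overlapping "
                                 "regions")
            labels[disk] = i + 1
            t1[disk] = tissue.t1_ms
            t2[disk] = tissue.t2_ms
            m0map[disk] = m0
    elif layout == "grid":
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        for i, tissue in enumerate(tissues):
            r, c = divmod(i, cols)
            ys = slice(int(r * ny / rows) + 1, int((r + 1) * ny / rows) - 1)
            xs = slice(int(c * nx / cols) + 1, int((c + 1) * nx / cols) - 1)
            if np.any(labels[ys, xs] != 0):
                raise ValueError("phantom layout produced overlapping "
                                 "regions")
            labels[ys, xs] = i + 1
            t1[ys, xs] = tissue.t1_ms
            t2[ys, xs] = tissue.t2_ms
            m0map[ys, xs] = m0
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return PhantomMaps(t1_ms=t1, t2_ms=t2, m0=m0map, labels=labels,
                       tissues=tissues)


def make_rr_series(mean_bpm: float, sd_ms: float, n_beats: int,
                   seed: int | None = 0,
                   trigger_delay_ms: float = 0.0) -> CardiacTiming:
    """Simulated ECG: RR = 60000/bpm + Gaussian jitter clipped at 3 sd."""
    if mean_bpm <= 0:
        raise ValueError("mean_bpm must be positive")
    if sd_ms < 0:
        raise ValueError("sd_ms must be non-negative")
    mean_rr = 60000.0 / mean_bpm
    if sd_ms == 0:
        rr = np.full(n_beats, mean_rr)
    else:
        rng = np.random.default_rng(seed)
        jitter = np.clip(rng.normal(0.0, sd_ms, n_beats),
                         -3.0 * sd_ms, 3.0 * sd_ms)
        rr = mean_rr + jitter
    return CardiacTiming(tuple(float(x) for x in rr), trigger_delay_ms)


def simulate_acquisition(phantom: PhantomMaps, params: AcquisitionParams,
                         scheme: MolliScheme | str, timing: CardiacTiming,
                         noise_sigma: float = 0.0,
                         seed: int | None = 0) -> MolliSeries:
    """Bloch-simulate the MOLLI series a scanner would produce.

    Each distinct (T1, T2) in the phantom is simulated once through the
    full timeline (slice-profile ensemble) and broadcast to its pixels
    scaled by M0; complex Gaussian noise of sd ``noise_sigma`` per channel
    is added before the magnitude, giving Rician statistics.
    ``noise_sigma = 0`` returns the exact noise-free magnitudes.  The
    whole series is reproducible from the seed.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    timeline = build_timeline(params, scheme, timing)
    positions = slice_spin_positions(params.n_slice_spins,
                                     params.slice_thickness_mm,
                                     params.slice_fov_factor)
    n_images = timeline.n_images
    ny, nx = phantom.shape
    complex_imgs = np.zeros((n_images, ny, nx), complex)

    inside = phantom.labels > 0
    pairs = np.unique(np.column_stack([phantom.t1_ms[inside],
                                       phantom.t2_ms[inside]]), axis=0)
    for t1v, t2v in pairs:
        sig = simulate_entry(float(t1v), float(t2v), timeline, positions,
                             magnitude=False)
        sel = inside & (phantom.t1_ms == t1v) & (phantom.t2_ms == t2v)
        complex_imgs[:, sel] = sig[:, None] * phantom.m0[sel][None, :]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sigma, complex_imgs.shape) \
            + 1j * rng.normal(0.0, noise_sigma, complex_imgs.shape)
        complex_imgs = complex_imgs + noise
    images = np.abs(complex_imgs)
    return MolliSeries(
        images=images, tis_ms=timeline.effective_tis_ms,
        meta={
            "digest": config_digest(params, scheme, timing),
            "scheme": scheme.text,
            "rr_intervals_ms": list(timing.rr_intervals_ms),
            "noise_sigma": float(noise_sigma),
            "seed": seed,
        })
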