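"""In-memory containers shared by the acquisition and estimation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MolliSeries", "ParameterMap"]


@dataclass
class MolliSeries:
    """Magnitude image stack with per-image effective inversion times.

    ``images`` has shape (n_images, ny, nx) in acquisition order;
    ``tis_ms`` carries one effective TI per image.  ``meta`` holds the
    acquisition provenance (scheme string, RR series, config digest,
    noise level, seed).
    """

    images: np.ndarray
    tis_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, float)
        self.tis_ms = np.asarray(self.tis_ms, float)
        if self.images.ndim != 3:
            raise ValueError("images must be (n_images, ny, nx)")
        if self.images.shape[0] != self.tis_ms.size:
            raise ValueError(
                f"{self.images.shape[0]} images but {self.tis_ms.size} "
                "effective TIs")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1], self.images.shape[2]

    def pixel(self, iy: int, ix: int) -> np.ndarray:
        return self.images[:, iy, ix]


@dataclass
class ParameterMap:
    """Per-pixel relaxometry result with a validity mask.

    ``t1_ms`` (and the optional channels) are NaN outside the mask;
    ``provenance`` records how the map was made (method name, dictionary
    digest or fit settings), so any output can be traced from file
    metadata alone.
    """

    t1_ms: np.ndarray
    mask: np.ndarray
    t2_ms: np.ndarray | None = None
    residual: np.ndarray | None = None
    amplitude: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t1_ms = np.asarray(self.t1_ms, float)
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != self.t1_ms.shape:
            raise ValueError("mask and t1 map shapes differ")
        for name in ("t2_ms", "residual", "amplitude"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != self.t1_ms.shape:
                    raise ValueError(f"{name} shape differs from t1 map")
                setattr(self, name, arr)

    def channels(self) -> dict[str, np.ndarray]:
        out = {"t1_ms": self.t1_ms}
        for name in ("t2_ms", "residual", "amplitude"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = arr
        return out
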