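"""File formats, configuration and provenance.

Image series and parameter maps travel as NIfTI volumes with a JSON
sidecar carrying the acquisition metadata (effective TIs, scheme string,
RR series, noise level, seed).  Session configuration is YAML or JSON
mirroring :class:`~mollisim.sequence.AcquisitionParams`; every run logs
the configuration digest so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .maps import MolliSeries, ParameterMap
from .sequence import (AcquisitionParams, CardiacTiming, MolliScheme,
                       SechPulse, SincPulse, parse_scheme)

__all__ = [
    "config_digest", "write_series", "read_series", "write_map", "read_map",
    "load_config", "save_config", "SessionConfig", "get_logger",
]

log = logging.getLogger("mollisim")


def get_logger() -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    return log


def _canonical(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _canonical(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_digest(params: AcquisitionParams, scheme: MolliScheme | str,
                  timing: CardiacTiming) -> str:
    """Stable hash of everything that shapes the simulated sequence."""
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    payload = {
        "params": _canonical(params),
        "scheme": scheme.text or list(scheme.groups),
        "timing": _canonical(timing),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# NIfTI series / maps with JSON sidecars


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_series(path, series: MolliSeries) -> None:
    """NIfTI (nx, ny, n_images) plus a JSON sidecar with the TIs."""
    path = Path(path)
    data = np.moveaxis(series.images, 0, -1).transpose(1, 0, 2)
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)), path)
    sidecar = dict(series.meta)
    sidecar["tis_ms"] = [float(t) for t in series.tis_ms]
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    get_logger().info("wrote series %s (%d images, digest %s)", path,
                      series.n_images, sidecar.get("digest"))


def read_series(path) -> MolliSeries:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_file}; effective TIs are mandatory "
            "metadata for a MOLLI series")
    sidecar = json.loads(sidecar_file.read_text())
    if "tis_ms" not in sidecar:
        raise ValueError(f"sidecar {sidecar_file} lacks 'tis_ms'")
    data = np.asarray(nib.load(path).dataobj, float)
    if data.ndim != 3:
        raise ValueError("series NIfTI must be 3-D (nx, ny, n_images)")
    images = np.moveaxis(data.transpose(1, 0, 2), -1, 0)
    tis = np.asarray(sidecar.pop("tis_ms"), float)
    if images.shape[0] != tis.size:
        raise ValueError(
            f"sidecar lists {tis.size} TIs but the volume holds "
            f"{images.shape[0]} images")
    return MolliSeries(images=images, tis_ms=tis, meta=sidecar)


def write_map(out_dir, pmap: ParameterMap, stem: str = "map") -> None:
    """One NIfTI per channel plus ``<stem>_provenance.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in pmap.channels().items():
        img = nib.Nifti1Image(arr.T.astype(np.float32), np.eye(4))
        nib.save(img, out_dir / f"{stem}_{name}.nii.gz")
    nib.save(nib.Nifti1Image(pmap.mask.T.astype(np.uint8), np.eye(4)),
             out_dir / f"{stem}_mask.nii.gz")
    (out_dir / f"{stem}_provenance.json").write_text(
        json.dumps(pmap.provenance, indent=2, default=str))
    get_logger().info("wrote maps to %s (provenance: %s)", out_dir,
                      pmap.provenance.get("method"))


def read_map(out_dir, stem: str = "map") -> ParameterMap:
    out_dir = Path(out_dir)
    t1 = np.asarray(
        nib.load(out_dir / f"{stem}_t1_ms.nii.gz").dataobj, float).T
    mask = np.asarray(
        nib.load(out_dir / f"{stem}_mask.nii.gz").dataobj, bool).T
    extra = {}
    for name in ("t2_ms", "residual", "amplitude"):
        p = out_dir / f"{stem}_{name}.nii.gz"
        if p.exists():
            extra[name] = np.asarray(nib.load(p).dataobj, float).T
    prov_file = out_dir / f"{stem}_provenance.json"
    prov = json.loads(prov_file.read_text()) if prov_file.exists() else {}
    return ParameterMap(t1_ms=t1, mask=mask, provenance=prov, **extra)


# ---------------------------------------------------------------------------
# Session configuration


@dataclasses.dataclass
class SessionConfig:
    """Acquisition + scheme + timing, as read from a YAML/JSON file."""

    params: AcquisitionParams
    scheme: MolliScheme
    timing: CardiacTiming
    noise_sigma: float = 0.0
    seed: int = 0

    @property
    def digest(self) -> str:
        return config_digest(self.params, self.scheme, self.timing)


def load_config(path) -> SessionConfig:
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    pd = dict(raw.get("acquisition", {}))
    if "ir_pulse" in pd:
        pd["ir_pulse"] = SechPulse(**pd["ir_pulse"])
    if "excitation_pulse" in pd:
        pd["excitation_pulse"] = SincPulse(**pd["excitation_pulse"])
    if "initial_tis_ms" in pd:
        pd["initial_tis_ms"] = tuple(pd["initial_tis_ms"])
    params = AcquisitionParams(**pd)
    scheme = parse_scheme(raw["scheme"])
    t = raw.get("timing", {})
    if "rr_intervals_ms" in t:
        timing = CardiacTiming(tuple(t["rr_intervals_ms"]),
                               t.get("trigger_delay_ms", 0.0))
    else:
        rr = float(t.get("rr_ms", 1000.0))
        timing = CardiacTiming.fixed(rr, scheme.n_beats + 1,
                                     t.get("trigger_delay_ms", 0.0))
    return SessionConfig(params=params, scheme=scheme, timing=timing,
                         noise_sigma=float(raw.get("noise_sigma", 0.0)),
                         seed=int(raw.get("seed", 0)))


def save_config(path, cfg: SessionConfig) -> None:
    path = Path(path)
    raw = {
        "acquisition": _canonical(cfg.params),
        "scheme": cfg.scheme.text,
        "timing": _canonical(cfg.timing),
        "noise_sigma": cfg.noise_sigma,
        "seed": cfg.seed,
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
    else:
        path.write_text(json.dumps(raw, indent=2))
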