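"""ROI statistics and method-agreement plots for phantom analysis.

Accuracy is summarized per region of interest as bias = ROI mean minus the
reference value, with the study-level summary being the mean +/- sd of the
per-ROI biases.  Agreement with a reference standard uses the modified
Bland-Altman convention: the difference between methods is plotted against
the *reference* value (not the pair mean), with 95 % limits at
mean +/- 1.96 sd.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .maps import ParameterMap

__all__ = ["RoiStats", "BiasSummary", "BlandAltman", "evaluate_bias",
           "bland_altman", "write_roi_stats"]


@dataclass(frozen=True)
class RoiStats:
    name: str
    n: int
    mean: float
    sd: float
    reference: float

    @property
    def bias(self) -> float:
        return self.mean - self.reference


@dataclass(frozen=True)
class BiasSummary:
    rois: tuple[RoiStats, ...]
    mean_bias: float
    sd_bias: float


def evaluate_bias(pmap: ParameterMap, reference: dict[str, float],
                  rois: dict[str, np.ndarray],
                  channel: str = "t1_ms") -> BiasSummary:
    """Per-ROI mean/sd/bias against reference values, plus the summary.

    ``rois`` maps names to boolean pixel masks; every ROI must contain at
    least one valid (masked-in, finite) pixel.
    """
    values = getattr(pmap, channel)
    stats = []
    for name, roi in rois.items():
        if name not in reference:
            raise KeyError(f"no reference value for ROI {name!r}")
        roi = np.asarray(roi, bool)
        sel = roi & pmap.mask & np.isfinite(values)
        if not sel.any():
            raise ValueError(f"ROI {name!r} contains no valid pixels")
        v = values[sel]
        stats.append(RoiStats(name=name, n=int(v.size),
                              mean=float(v.mean()),
                              sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                              reference=float(reference[name])))
    biases = np.array([s.bias for s in stats])
    return BiasSummary(
        rois=tuple(stats), mean_bias=float(biases.mean()),
        sd_bias=float(biases.std(ddof=1)) if biases.size > 1 else 0.0)


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd: float
    limits: tuple[float, float]         # mean +/- 1.96 sd


def bland_altman(estimates: np.ndarray, references: np.ndarray,
                 plot_path: str | Path | None = None,
                 label: str = "T1 [ms]") -> BlandAltman:
    """Modified Bland-Altman agreement of estimates with a reference.

    Differences (estimate - reference) are summarized and, when
    ``plot_path`` is given, plotted against the reference value.
    """
    est = np.asarray(estimates, float)
    ref = np.asarray(references, float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length "
                         "1-D vectors")
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = est - ref
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    limits = (mean - 1.96 * sd, mean + 1.96 * sd)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(ref, diff, c="k", s=25)
        ax.axhline(mean, color="k")
        for lim in limits:
            ax.axhline(lim, color="k", linestyle="--")
        ax.set_xlabel(f"reference {label}")
        ax.set_ylabel(f"difference (estimate - reference) {label}")
        ax.set_title("modified Bland-Altman (x-axis = reference)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return BlandAltman(mean_difference=mean, sd=sd, limits=limits)


def write_roi_stats(path: str | Path, summary: BiasSummary) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["roi", "n", "mean", "sd", "reference", "bias"])
        for s in summary.rois:
            w.writerow([s.name, s.n, f"{s.mean:.3f}", f"{s.sd:.3f}",
                        f"{s.reference:.3f}", f"{s.bias:.3f}"])
        w.writerow(["summary", len(summary.rois), "", "", "",
                    f"{summary.mean_bias:.3f} +/- {summary.sd_bias:.3f}"])
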