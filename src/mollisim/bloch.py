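"""Discrete-event Bloch-equation engine.

An MR experiment is expanded into a flat :class:`Timeline` of constant-field
events (RF amplitude/phase, slice gradient, crusher and ADC markers).  Each
isochromat -- a spin packet with one T1, T2, slice position and off-resonance
-- is propagated through the events with operator splitting: rotation about
the instantaneous effective field first, relaxation second.  For events
without RF the splitting is exact (z-rotation and transverse decay commute),
so arbitrarily long free-precession intervals are represented by single
events with no discretization error; only shaped RF pulses need to be
sampled at the simulation step.

Units follow quantitative-MR convention: T1/T2 in milliseconds at the API,
seconds internally; RF amplitude in microtesla; gradients in mT/m; slice
positions in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._kernel import GAMMA, propagate_ensemble, propagate_spin

__all__ = [
    "GAMMA",
    "Magnetization",
    "Isochromat",
    "TimelineEvent",
    "Timeline",
    "step",
    "simulate_isochromat",
    "ensemble_signal",
    "BlochNumericalError",
]


class BlochNumericalError(RuntimeError):
    """Raised when propagation produces a non-finite magnetization."""

    def __init__(self, event_index: int):
        self.event_index = event_index
        super().__init__(
            f"non-finite magnetization at timeline event {event_index}")


@dataclass
class Magnetization:
    """Magnetization 3-vector in units of the equilibrium magnetization."""

    mx: float = 0.0
    my: float = 0.0
    mz: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.mx, self.my, self.mz], dtype=float)

    @property
    def transverse(self) -> complex:
        return self.mx + 1j * self.my


@dataclass
class Isochromat:
    """Spin packet: slice position (m), T1/T2 (ms), off-resonance (Hz)."""

    z_position: float = 0.0
    t1_ms: float = 1000.0
    t2_ms: float = 100.0
    off_resonance_hz: float = 0.0
    equilibrium: float = 1.0

    def __post_init__(self):
        if not (self.t1_ms > 0 and self.t2_ms > 0):
            raise ValueError(
                f"T1 and T2 must be positive, got T1={self.t1_ms} "
                f"T2={self.t2_ms}")


@dataclass
class TimelineEvent:
    """One constant-field interval of the expanded pulse sequence.

    Crusher events are instantaneous ideal spoilers: they zero the
    transverse magnetization, carry no RF and advance no time
    (``duration_s`` is 0 for them and positive for every other event).
    """

    duration_s: float
    rf_amplitude_uT: float = 0.0
    rf_phase_rad: float = 0.0
    gradient_mT_m: float = 0.0
    is_crusher: bool = False
    adc_image_index: int | None = None

    def __post_init__(self):
        if self.is_crusher:
            if self.rf_amplitude_uT != 0.0:
                raise ValueError("crusher events carry zero RF")
        elif not self.duration_s > 0:
            raise ValueError("non-crusher events need duration > 0")


@dataclass
class Timeline:
    """Struct-of-arrays form of an event sequence, plus image metadata."""

    duration_s: np.ndarray
    rf_amplitude_uT: np.ndarray
    rf_phase_rad: np.ndarray
    gradient_mT_m: np.ndarray
    is_crusher: np.ndarray
    adc_index: np.ndarray          # int32, -1 where no sample
    effective_tis_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    image_group: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_events(self) -> int:
        return int(self.duration_s.shape[0])

    @property
    def n_images(self) -> int:
        marked = self.adc_index[self.adc_index >= 0]
        return int(marked.max()) + 1 if marked.size else 0

    @property
    def total_duration_s(self) -> float:
        return float(self.duration_s.sum())

    @classmethod
    def from_events(cls, events: Iterable[TimelineEvent],
                    effective_tis_ms: Sequence[float] = (),
                    image_group: Sequence[int] = ()) -> "Timeline":
        events = list(events)
        if not events:
            raise ValueError("timeline needs at least one event")
        tl = cls(
            duration_s=np.array([e.duration_s for e in events], float),
            rf_amplitude_uT=np.array([e.rf_amplitude_uT for e in events],
                                     float),
            rf_phase_rad=np.array([e.rf_phase_rad for e in events], float),
            gradient_mT_m=np.array([e.gradient_mT_m for e in events], float),
            is_crusher=np.array([e.is_crusher for e in events], bool),
            adc_index=np.array(
                [-1 if e.adc_image_index is None else e.adc_image_index
                 for e in events], np.int32),
            effective_tis_ms=np.asarray(effective_tis_ms, float),
            image_group=np.asarray(image_group, int),
        )
        tl.validate()
        return tl

    def validate(self) -> None:
        if np.any(self.duration_s < 0):
            raise ValueError("event durations must be non-negative")
        if np.any((self.duration_s == 0) & ~self.is_crusher):
            raise ValueError("only crusher events may have zero duration")
        if np.any(self.is_crusher & (self.rf_amplitude_uT != 0)):
            raise ValueError("crusher events carry zero RF")
        marked = self.adc_index[self.adc_index >= 0]
        if marked.size:
            uniq, counts = np.unique(marked, return_counts=True)
            if np.any(counts > 1):
                raise ValueError("each image index may be sampled only once")
            if uniq.min() != 0 or uniq.max() != uniq.size - 1:
                raise ValueError("ADC image indices must be 0..n_images-1")

    def events(self) -> list[TimelineEvent]:
        return [
            TimelineEvent(
                duration_s=float(self.duration_s[i]),
                rf_amplitude_uT=float(self.rf_amplitude_uT[i]),
                rf_phase_rad=float(self.rf_phase_rad[i]),
                gradient_mT_m=float(self.gradient_mT_m[i]),
                is_crusher=bool(self.is_crusher[i]),
                adc_image_index=(int(self.adc_index[i])
                                 if self.adc_index[i] >= 0 else None),
            )
            for i in range(self.n_events)
        ]


def step(mag: Magnetization, iso: Isochromat,
         ev: TimelineEvent) -> Magnetization:
    """Advance one magnetization vector through one event.

    Rotation about the effective field through ``-|omega| * dt`` (the
    left-handed precession of dM/dt = gamma M x B), then T2 decay of the
    transverse components and T1 recovery of the longitudinal one.  Crusher
    events project the transverse plane to zero and do nothing else, which
    makes them exactly idempotent.
    """
    if ev.is_crusher:
        return Magnetization(0.0, 0.0, mag.mz)

    dt = ev.duration_s
    m = mag.as_array()

    b1_T = ev.rf_amplitude_uT * 1e-6
    w = np.array([
        GAMMA * b1_T * np.cos(ev.rf_phase_rad),
        GAMMA * b1_T * np.sin(ev.rf_phase_rad),
        GAMMA * ev.gradient_mT_m * 1e-3 * iso.z_position
        + 2.0 * np.pi * iso.off_resonance_hz,
    ])
    wnorm = np.linalg.norm(w)
    if wnorm > 0:
        u = w / wnorm
        phi = -wnorm * dt
        c, s = np.cos(phi), np.sin(phi)
        m = m * c + np.cross(u, m) * s + u * np.dot(u, m) * (1.0 - c)

    e1 = np.exp(-dt / (iso.t1_ms * 1e-3))
    e2 = np.exp(-dt / (iso.t2_ms * 1e-3))
    m0 = iso.equilibrium
    out = Magnetization(m[0] * e2, m[1] * e2, m0 + (m[2] - m0) * e1)
    if not np.all(np.isfinite(out.as_array())):
        raise BlochNumericalError(-1)
    return out


def _timeline_arrays(timeline: Timeline):
    return (timeline.duration_s, timeline.rf_amplitude_uT,
            timeline.rf_phase_rad, timeline.gradient_mT_m,
            timeline.is_crusher, timeline.adc_index)


def simulate_isochromat(iso: Isochromat, timeline: Timeline) -> np.ndarray:
    """Complex transverse sample (mx + i my) at every ADC marker.

    The spin starts at equilibrium (0, 0, M0).  Returns an empty array if
    the timeline carries no ADC markers.
    """
    n_images = timeline.n_images
    out_re = np.zeros(n_images)
    out_im = np.zeros(n_images)
    status = propagate_spin(*_timeline_arrays(timeline),
                            float(iso.z_position), iso.t1_ms * 1e-3,
                            iso.t2_ms * 1e-3, float(iso.off_resonance_hz),
                            float(iso.equilibrium), out_re, out_im)
    if status >= 0:
        raise BlochNumericalError(status)
    return out_re + 1j * out_im


def ensemble_signal(isochromats: Sequence[Isochromat],
                    timeline: Timeline) -> np.ndarray:
    """Complex sum over the ensemble of per-spin ADC samples.

    Linear in the ensemble by construction: the signal of a union of
    ensembles is the sum of their signals.
    """
    isochromats = list(isochromats)
    if not isochromats:
        raise ValueError("ensemble must contain at least one isochromat")
    z = np.array([i.z_position for i in isochromats], float)
    t1 = np.array([i.t1_ms for i in isochromats], float) * 1e-3
    t2 = np.array([i.t2_ms for i in isochromats], float) * 1e-3
    off = np.array([i.off_resonance_hz for i in isochromats], float)
    m0 = np.array([i.equilibrium for i in isochromats], float)
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")
    out_re, out_im, status = propagate_ensemble(
        *_timeline_arrays(timeline), z, t1, t2, off, m0, timeline.n_images)
    if status >= 0:
        raise BlochNumericalError(status)
    return out_re + 1j * out_im
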