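"""MOLLI pulse-sequence expansion.

Turns an acquisition-parameter set, a MOLLI scheme string such as
``"5(3p)3"`` and a cardiac-timing record into a concrete event
:class:`~mollisim.bloch.Timeline`, with the per-image effective inversion
times computed from the scheme's initial TIs and the RR intervals.

The layout of one ECG-triggered single-shot follows the clinical sequence:
a linear flip-angle ramp of ``ramp_pulses`` phase-alternated excitations
(flip k * alpha / N, no ADC) followed by ``n_phase_encodes`` full-flip
balanced-SSFP repetitions, with a single ADC marker at the echo of the
k-space-center line.  RF phase alternates 0, pi, 0, pi continuously over
the whole timeline, so the bSSFP condition is retained across ramp,
acquisition and successive shots.  Each inversion block is an ideal
crusher, a hyperbolic-secant adiabatic pulse, and a second crusher; the
block is placed so that the pulse *ends* exactly ``initial_ti`` before the
k-space-center echo of the group's first readout.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernel import GAMMA
from .bloch import Isochromat, Magnetization, Timeline, TimelineEvent, step

__all__ = [
    "SechPulse", "SincPulse", "AcquisitionParams", "MolliScheme",
    "CardiacTiming", "SchemeParseError", "InfeasibleTimingError",
    "parse_scheme", "make_sech_pulse", "make_sinc_pulse",
    "validate_inversion", "min_feasible_ti", "build_timeline",
    "default_acquisition_params",
]

GAMMA_BAR = GAMMA / (2.0 * np.pi)  # Hz / T


class SchemeParseError(ValueError):
    pass


class InfeasibleTimingError(ValueError):
    """Requested initial TI is shorter than the sequence can realize."""

    def __init__(self, requested_ti_ms: float, min_ti_ms: float):
        self.requested_ti_ms = requested_ti_ms
        self.min_ti_ms = min_ti_ms
        super().__init__(
            f"initial TI {requested_ti_ms:.3f} ms is infeasible; the "
            f"k-space center cannot occur earlier than {min_ti_ms:.3f} ms "
            f"after the end of the inversion pulse")


@dataclass(frozen=True)
class SechPulse:
    """Hyperbolic-secant adiabatic inversion: B1(t) = b1max sech(beta t),
    phase(t) = mu ln sech(beta t), t centered on the pulse."""

    duration_ms: float = 4.74
    mu: float = 5.0
    beta_per_s: float = 2235.0      # sech(beta*T/2) ~ 0.01 at 4.74 ms
    b1max_uT: float = 54.0


@dataclass(frozen=True)
class SincPulse:
    """Apodized sinc excitation; ``lobes`` zero-crossings per side."""

    duration_us: float = 490.0
    lobes: int = 3
    apodization: str = "hann"       # "hann" | "hamming" | "none"


@dataclass(frozen=True)
class AcquisitionParams:
    """Everything the simulator needs to expand one MOLLI acquisition.

    Defaults reproduce the phantom protocol: TR 2.54 ms, TE 1.27 ms, 35 deg
    excitation, 490 us sinc, 6 mm slice, 65 phase-encode lines (linear
    order, center line 33), 10-pulse linear ramp, sech inversion of 4.74 ms,
    initial TIs 114 and 350 ms.
    """

    tr_ms: float = 2.54
    te_ms: float = 1.27
    flip_deg: float = 35.0
    ramp_pulses: int = 10
    n_phase_encodes: int = 65
    center_line_index: int | None = None   # default ceil(n/2)
    slice_thickness_mm: float = 6.0
    ir_pulse: SechPulse = field(default_factory=SechPulse)
    excitation_pulse: SincPulse = field(default_factory=SincPulse)
    dt_us: float = 10.0
    initial_tis_ms: tuple[float, ...] = (114.0, 350.0)
    n_slice_spins: int = 21
    slice_fov_factor: float = 2.0

    def __post_init__(self):
        if self.center_line_index is None:
            object.__setattr__(self, "center_line_index",
                               int(np.ceil(self.n_phase_encodes / 2)))
        if not 1 <= self.center_line_index <= self.n_phase_encodes:
            raise ValueError("center_line_index out of range")
        if self.ramp_pulses < 0:
            raise ValueError("ramp_pulses must be >= 0")
        if self.dt_us <= 0:
            raise ValueError("dt_us must be positive")
        if abs(self.te_ms - self.tr_ms / 2) > 0.05 * self.tr_ms:
            warnings.warn(
                f"TE={self.te_ms} ms is not ~TR/2={self.tr_ms / 2} ms; "
                "the balanced-SSFP echo condition is violated",
                stacklevel=2)

    def replace(self, **kw) -> "AcquisitionParams":
        return replace(self, **kw)


def default_acquisition_params(**overrides) -> AcquisitionParams:
    """Phantom-protocol defaults; keyword overrides applied on top."""
    return AcquisitionParams(**overrides)


@dataclass(frozen=True)
class MolliScheme:
    """Ordered readout groups; pause is heartbeats after each group."""

    groups: tuple[tuple[int, int], ...]   # (n_readouts, pause_beats)
    text: str = ""

    @property
    def n_images(self) -> int:
        return sum(n for n, _ in self.groups)

    @property
    def n_beats(self) -> int:
        beats = 0
        for i, (n, pause) in enumerate(self.groups):
            beats += n
            if i < len(self.groups) - 1:
                beats += pause
        return beats


@dataclass(frozen=True)
class CardiacTiming:
    """RR-interval series (ms, one per heartbeat) and trigger delay."""

    rr_intervals_ms: tuple[float, ...]
    trigger_delay_ms: float = 0.0

    def __post_init__(self):
        if any(rr <= 0 for rr in self.rr_intervals_ms):
            raise ValueError("all RR intervals must be positive")

    @classmethod
    def fixed(cls, rr_ms: float, n_beats: int,
              trigger_delay_ms: float = 0.0) -> "CardiacTiming":
        return cls(tuple([float(rr_ms)] * n_beats), trigger_delay_ms)


_SCHEME_RE = re.compile(r"(\d+)|\((\d+)p\)")


def parse_scheme(text: str) -> MolliScheme:
    """Parse ``"5(3p)3"``-style MOLLI scheme notation.

    Numbers outside parentheses are readouts per modified-Look-Locker
    experiment; ``(Np)`` is the pause, in heartbeats, after the preceding
    group.  The trailing group carries no pause.
    """
    s = text.strip()
    pos = 0
    counts: list[int] = []
    pauses: list[int] = []
    expect_group = True
    while pos < len(s):
        m = _SCHEME_RE.match(s, pos)
        if m is None:
            raise SchemeParseError(
                f"malformed scheme {text!r}: unexpected character at "
                f"position {pos}")
        if m.group(1) is not None:
            if not expect_group:
                raise SchemeParseError(
                    f"malformed scheme {text!r}: expected '(Np)' pause at "
                    f"position {pos}")
            counts.append(int(m.group(1)))
            expect_group = False
        else:
            if expect_group:
                raise SchemeParseError(
                    f"malformed scheme {text!r}: pause without preceding "
                    f"group at position {pos}")
            pauses.append(int(m.group(2)))
            expect_group = True
        pos = m.end()
    if not counts or expect_group:
        raise SchemeParseError(
            f"malformed scheme {text!r}: must end with a readout group")
    if len(pauses) != len(counts) - 1:
        raise SchemeParseError(f"malformed scheme {text!r}")
    if any(c < 1 for c in counts):
        raise SchemeParseError(
            f"malformed scheme {text!r}: groups need >= 1 readout")
    groups = tuple(
        (counts[i], pauses[i] if i < len(pauses) else 0)
        for i in range(len(counts)))
    return MolliScheme(groups=groups, text=s)


# ---------------------------------------------------------------------------
# RF waveform factories


def _sample_times(duration_s: float, dt_s: float):
    n = max(int(np.ceil(duration_s / dt_s)), 1)
    sub = duration_s / n
    t = (np.arange(n) + 0.5) * sub - duration_s / 2.0
    return t, sub


def _sech_samples(pulse: SechPulse, dt_us: float):
    dur_s = pulse.duration_ms * 1e-3
    t, sub = _sample_times(dur_s, dt_us * 1e-6)
    if t.size < 10:
        raise ValueError("sech pulse must cover at least 10 samples; "
                         "reduce dt_us")
    sech = 1.0 / np.cosh(pulse.beta_per_s * t)
    amp = pulse.b1max_uT * sech
    phase = pulse.mu * np.log(sech)
    return sub, amp, phase


def make_sech_pulse(duration_ms: float = 4.74, mu: float = 5.0,
                    beta_per_s: float = 2235.0, b1max_uT: float = 54.0,
                    dt_us: float = 10.0) -> list[TimelineEvent]:
    """Phase-modulated hyperbolic-secant inversion as timeline events.

    Non-selective: zero gradient.  The frequency sweep -mu*beta*tanh(beta t)
    is represented purely as the time-varying phase mu*ln(sech(beta t)).
    """
    sub, amp, phase = _sech_samples(
        SechPulse(duration_ms, mu, beta_per_s, b1max_uT), dt_us)
    return [TimelineEvent(duration_s=sub, rf_amplitude_uT=float(a),
                          rf_phase_rad=float(p))
            for a, p in zip(amp, phase)]


def validate_inversion(events: list[TimelineEvent],
                       t1_ms: float = 1e9, t2_ms: float = 1e9) -> float:
    """Mz after the pulse for an equilibrium spin (relaxation off by
    default).  Direct Bloch integration of the sweep; the adiabatic
    contract is Mz <= -0.98."""
    iso = Isochromat(z_position=0.0, t1_ms=t1_ms, t2_ms=t2_ms)
    m = Magnetization()
    for ev in events:
        m = step(m, iso, ev)
    return m.mz


def _sinc_samples(pulse: SincPulse, flip_deg: float,
                  slice_thickness_mm: float, dt_us: float):
    """Amplitude samples (uT), sub-step (s) and slice gradient (mT/m)."""
    dur_s = pulse.duration_us * 1e-6
    dt_s = dt_us * 1e-6
    if dur_s < 4 * dt_s:
        raise ValueError(
            f"excitation duration {pulse.duration_us} us too short to "
            f"resolve at dt={dt_us} us")
    t, sub = _sample_times(dur_s, dt_s)
    lobes = max(int(pulse.lobes), 1)
    x = 2.0 * lobes * t / dur_s
    shape = np.sinc(x)
    if pulse.apodization == "hann":
        shape = shape * (0.5 + 0.5 * np.cos(2 * np.pi * t / dur_s))
    elif pulse.apodization == "hamming":
        shape = shape * (0.54 + 0.46 * np.cos(2 * np.pi * t / dur_s))
    elif pulse.apodization != "none":
        raise ValueError(f"unknown apodization {pulse.apodization!r}")
    # calibrate: on-resonance flip at slice center is gamma * integral(B1)
    flip_rad = np.deg2rad(flip_deg)
    area = shape.sum() * sub              # dimensionless-amp * s
    amp_uT = shape * (flip_rad / (GAMMA * area)) * 1e6
    bandwidth_hz = 2.0 * lobes / dur_s
    grad_T_m = bandwidth_hz / (GAMMA_BAR * slice_thickness_mm * 1e-3)
    return sub, amp_uT, grad_T_m * 1e3


def make_sinc_pulse(duration_us: float = 490.0, flip_deg: float = 35.0,
                    lobes: int = 3, slice_thickness_mm: float = 6.0,
                    dt_us: float = 10.0, apodization: str = "hann",
                    rephase_ms: float = 0.2) -> list[TimelineEvent]:
    """Slice-selective sinc excitation plus slice-rephasing lobe.

    The amplitude is calibrated so the on-resonance flip at slice center is
    ``flip_deg`` exactly (the flip is gamma * B1 area, the gradient
    contributes nothing at z = 0); a rephasing gradient of minus half the
    slice-lobe area follows the pulse.  ``flip_deg = 0`` yields pure
    gradient events (identity for on-center spins).
    """
    if not 0 <= flip_deg < 180:
        raise ValueError("flip must be in [0, 180) degrees")
    sub, amp, grad = _sinc_samples(
        SincPulse(duration_us, lobes, apodization), flip_deg,
        slice_thickness_mm, dt_us)
    events = [TimelineEvent(duration_s=sub, rf_amplitude_uT=float(a),
                            gradient_mT_m=grad) for a in amp]
    area = grad * duration_us * 1e-6
    events.append(TimelineEvent(duration_s=rephase_ms * 1e-3,
                                gradient_mT_m=-area / (2 * rephase_ms * 1e-3)))
    return events


# ---------------------------------------------------------------------------
# Timeline assembly


class _Assembler:
    """Append-only event buffer with an absolute-time cursor (ms)."""

    def __init__(self):
        self.dur: list[float] = []      # ms
        self.amp: list[float] = []
        self.phase: list[float] = []
        self.grad: list[float] = []
        self.crush: list[bool] = []
        self.adc: list[int] = []
        self.t = 0.0

    def add(self, dur_ms, amp=0.0, phase=0.0, grad=0.0, crush=False, adc=-1):
        self.dur.append(dur_ms)
        self.amp.append(amp)
        self.phase.append(phase)
        self.grad.append(grad)
        self.crush.append(crush)
        self.adc.append(adc)
        self.t += dur_ms

    def advance_to(self, t_ms, adc=-1):
        gap = t_ms - self.t
        if gap < -1e-6:
            raise RuntimeError(
                f"timeline overlap: cursor {self.t:.4f} ms past {t_ms:.4f}")
        if gap > 1e-9 or adc >= 0:
            self.add(max(gap, 1e-9), adc=adc)
        self.t = t_ms

    def build(self, effective_tis_ms, image_group) -> Timeline:
        tl = Timeline(
            duration_s=np.asarray(self.dur, float) * 1e-3,
            rf_amplitude_uT=np.asarray(self.amp, float),
            rf_phase_rad=np.asarray(self.phase, float),
            gradient_mT_m=np.asarray(self.grad, float),
            is_crusher=np.asarray(self.crush, bool),
            adc_index=np.asarray(self.adc, np.int32),
            effective_tis_ms=np.asarray(effective_tis_ms, float),
            image_group=np.asarray(image_group, int),
        )
        tl.validate()
        return tl


def min_feasible_ti(params: AcquisitionParams) -> float:
    """Shortest realizable initial TI (ms), by k-space arithmetic:
    ramp_pulses*TR + (center_line_index - 1)*TR + TE.  The physical bound
    adds half the excitation-pulse duration (TE is counted from the RF
    center); :func:`build_timeline` enforces the physical bound."""
    return (params.ramp_pulses * params.tr_ms
            + (params.center_line_index - 1) * params.tr_ms + params.te_ms)


def build_timeline(params: AcquisitionParams, scheme: MolliScheme,
                   timing: CardiacTiming) -> Timeline:
    """Expand a full MOLLI experiment into one continuous event timeline.

    Per group: crusher -> sech inversion -> crusher, placed so the pulse
    ends ``initial_ti`` before the first readout's k-space-center echo;
    then one single-shot per consecutive heartbeat; pause beats are free
    relaxation.  ``effective_tis_ms`` records, per image in acquisition
    order, the time from the end of the group's inversion pulse to its ADC
    marker.
    """
    if isinstance(scheme, str):
        scheme = parse_scheme(scheme)
    if len(params.initial_tis_ms) != len(scheme.groups):
        raise ValueError(
            f"scheme {scheme.text!r} has {len(scheme.groups)} groups but "
            f"{len(params.initial_tis_ms)} initial TIs were given")
    if len(timing.rr_intervals_ms) < scheme.n_beats:
        raise ValueError(
            f"scheme occupies {scheme.n_beats} heartbeats but only "
            f"{len(timing.rr_intervals_ms)} RR intervals were supplied")

    tr = params.tr_ms
    te = params.te_ms
    exc = params.excitation_pulse
    exc_ms = exc.duration_us * 1e-3
    half_rf = exc_ms / 2.0
    tau = min(0.2, (tr - exc_ms) / 4.0)   # gradient-lobe duration, ms
    if tau <= 0:
        raise ValueError("TR too short for the excitation pulse")
    echo_in_block = half_rf + te
    if not exc_ms + tau <= echo_in_block <= tr - tau:
        raise ValueError(
            "TE places the echo outside the free window of the TR block")

    sinc_sub, sinc_amp, grad = _sinc_samples(
        exc, params.flip_deg, params.slice_thickness_mm, params.dt_us)
    sinc_sub_ms = sinc_sub * 1e3
    slice_area = grad * exc_ms            # mT/m * ms
    lobe_grad = -slice_area / (2.0 * tau)
    sech_sub, sech_amp, sech_phase = _sech_samples(params.ir_pulse,
                                                   params.dt_us)
    sech_sub_ms = sech_sub * 1e3
    ir_ms = params.ir_pulse.duration_ms

    adc_offset = min_feasible_ti(params) + half_rf   # shot start -> echo
    shot_ms = (params.ramp_pulses + params.n_phase_encodes) * tr
    min_ti = adc_offset

    r_wave = np.concatenate([[0.0], np.cumsum(timing.rr_intervals_ms)])

    # ---- plan segments in absolute time (ms) -----------------------------
    inversions: list[tuple[float, int]] = []     # (start, group)
    shots: list[tuple[float, int, int]] = []     # (start, group, image)
    adc_times: list[float] = []
    inv_end_by_group: list[float] = []
    image_group: list[int] = []
    beat = 0
    image = 0
    for gi, (n_read, pause) in enumerate(scheme.groups):
        ti0 = float(params.initial_tis_ms[gi])
        if ti0 < min_ti - 1e-9:
            raise InfeasibleTimingError(ti0, min_ti)
        first_adc = r_wave[beat] + timing.trigger_delay_ms + adc_offset
        inv_end = first_adc - ti0
        inversions.append((inv_end - ir_ms, gi))
        inv_end_by_group.append(inv_end)
        for _ in range(n_read):
            start = r_wave[beat] + timing.trigger_delay_ms
            shots.append((start, gi, image))
            adc_times.append(start + adc_offset)
            image_group.append(gi)
            image += 1
            beat += 1
        if gi < len(scheme.groups) - 1:
            beat += pause

    # global shift so the timeline starts at t = 0
    t_min = min(s for s, _ in inversions)
    shift = -t_min if t_min < 0 else 0.0
    inversions = [(s + shift, g) for s, g in inversions]
    shots = [(s + shift, g, i) for s, g, i in shots]
    adc_times = [t + shift for t in adc_times]
    inv_end_by_group = [t + shift for t in inv_end_by_group]

    segments = sorted(
        [(s, 0, "inv", g) for s, g in inversions]
        + [(s, 1, "shot", (g, i)) for s, g, i in shots])

    asm = _Assembler()
    pulse_count = 0
    for start, _, kind, payload in segments:
        asm.advance_to(start)
        if kind == "inv":
            asm.add(0.0, crush=True)
            for a, p in zip(sech_amp, sech_phase):
                asm.add(sech_sub_ms, amp=float(a), phase=float(p))
            asm.add(0.0, crush=True)
            # guard against float accumulation across many sub-steps
            asm.t = start + ir_ms
        else:
            _, img = payload
            adc_line = params.ramp_pulses + params.center_line_index - 1
            n_pulses = params.ramp_pulses + params.n_phase_encodes
            for p in range(n_pulses):
                block = start + p * tr
                asm.advance_to(block)
                if p < params.ramp_pulses:
                    scale = (p + 1) / params.ramp_pulses
                else:
                    scale = 1.0
                phase = np.pi * (pulse_count % 2)
                pulse_count += 1
                for a in sinc_amp:
                    asm.add(sinc_sub_ms, amp=float(a) * scale, phase=phase,
                            grad=grad)
                asm.t = block + exc_ms
                asm.add(tau, grad=lobe_grad)
                if p == adc_line:
                    asm.advance_to(block + echo_in_block, adc=img)
                asm.advance_to(block + tr - tau)
                asm.add(tau, grad=lobe_grad)
            asm.t = start + shot_ms

    effective_tis = np.array(adc_times) - np.array(
        [inv_end_by_group[g] for g in image_group])
    return asm.build(effective_tis, image_group)
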