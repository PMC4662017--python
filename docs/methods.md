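# Methods

## The problem

MOLLI (Modified Look-Locker Inversion recovery) is the workhorse cardiac
T1-mapping sequence: several inversion-recovery experiments, each read out
with ECG-triggered single-shot balanced-SSFP acquisitions on consecutive
heartbeats, merged into one 8-point recovery curve per pixel.  The readout
train perturbs the recovery, so the fitted apparent constant T1* is always
shorter than T1, and the standard correction T1 = T1*(B/A − 1) — derived
for a FLASH readout, not bSSFP — leaves a systematic, T1-dependent
underestimation.  `mollisim` removes the closed-form model entirely: it
simulates the *identical* pulse sequence with a discrete-event Bloch
engine for every physiological (T1, T2) pair, collects the simulated
signals into a dictionary, and assigns each measured pixel the (T1, T2)
of the entry with the least squared difference (MR-fingerprinting-style
matching, but on an unmodified clinical sequence).  The conventional
3-parameter + Look-Locker pipeline is included as the baseline.

## Bloch engine

State is the magnetization 3-vector of an isochromat (one T1, T2, slice
position z, off-resonance).  A pulse sequence is a flat list of
constant-field events (RF amplitude in µT, RF phase, slice gradient in
mT/m, crusher and ADC flags).  Per event the engine applies operator
splitting: rotation about the effective field ω = (γB1 cosφ, γB1 sinφ,
γG z + 2πΔf) through −|ω|·dt (Rodrigues form), then exact relaxation
(transverse ×e^(−dt/T2), longitudinal → M0 + (Mz − M0)e^(−dt/T1)).

Numerical consequences of this design:

- For events without RF the z-rotation commutes with relaxation, so the
  splitting is *exact*; free-precession intervals of any length are
  single events with zero discretization error.  Only shaped RF pulses
  are sampled at the simulation step Δt.
- Splitting error during RF is O(dt²·ω/T2); against a per-event
  matrix-exponential oracle (exponentiation of the full 4×4 affine Bloch
  generator) the stepper agrees to <1e−7 at 1 µs steps.
- Crushers are ideal software spoilers: instantaneous projection of the
  transverse plane to zero, no time advance, no relaxation — hence
  exactly idempotent.  They carry duration 0; all other events require
  duration > 0.
- Halving Δt from 10 µs to 5 µs (the two steps used for the protocol
  fixtures) changes MOLLI sample magnitudes by <0.5 %.  At 50 µs the
  absolute signal carries a ~5 % discretization offset (edge spins
  precess ~4 rad per step under the ~48 mT/m slice gradient).  This
  offset is common mode between dictionary and simulated series as long
  as both use the same Δt — which the configuration digest enforces — so
  matching results are unaffected; 50 µs is therefore the default for
  desk-scale runs and tests, 10 µs for high-accuracy work.

The inner loops (single spin, slice ensemble, full grid) are
numba-compiled; the grid kernel parallelizes over entries with an ordered
output array, so results are bit-identical for any worker count.

## Sequence model

`build_timeline` expands acquisition parameters + a scheme string
("5(3p)3", "4(1p)3(1p)2", "5(0p)3"; the parenthesized number is the pause
in heartbeats) + an RR-interval record into one continuous event list:

- Single-shot block per readout beat: `ramp_pulses` linearly increasing
  flips (k·α/N, default N = 10), then `n_phase_encodes` full-α bSSFP TRs.
  RF phase alternates 0, π continuously across ramp, acquisition and
  successive shots.  One ADC marker per image, at the echo of the
  k-space-center line (default line ⌈65/2⌉ = 33 for the 65-line linear
  trajectory).
- TR block layout: RF (490 µs sinc with slice gradient) from the block
  start, rephasing lobe of −½ the slice-lobe area, echo at TE after the
  RF *center*, prewinding lobe of −½ area at the block end — net gradient
  area per TR is zero (balanced).
- Inversion block per group: crusher → hyperbolic-secant adiabatic pulse
  → crusher, placed so the pulse *ends* exactly `initial_ti` before the
  first readout's echo (for the first group this puts the inversion
  slightly before the first R wave; the timeline origin shifts
  accordingly).  Effective TIs are recorded per image as echo time minus
  inversion end; within a group consecutive TIs differ by exactly the
  intervening RR intervals.
- `min_feasible_ti` = ramp·TR + (center−1)·TR + TE is the k-space
  arithmetic bound (107.95 ms at the phantom protocol); the physical
  bound adds half the excitation pulse (+0.245 ms).  Infeasible initial
  TIs raise an error that reports the bound.

RF defaults, chosen once where the protocol leaves them open:

- sech inversion: duration 4.74 ms; µ = 5; β = 2235 s⁻¹ (so
  sech(β·T/2) ≈ 0.01); B1max = 54 µT = 2× the numerically measured
  adiabatic threshold.  Contract: Mz ≤ −0.98 after the pulse from
  equilibrium (measured −0.9997), insensitive (<0.01) to 1.5× B1 scaling.
  The sweep is represented purely as the phase modulation
  µ·ln sech(βt) in a single rotating frame.
- sinc excitation: 490 µs, 3 zero-crossings per side, Hann apodized;
  amplitude calibrated analytically so the slice-center flip is exact
  (flip = γ∫B1 dt at z = 0); slice gradient from the pulse bandwidth
  2·lobes/T and the 6 mm slice.  A spin one slice-thickness off-center
  responds at <1 % of the center spin.

## Dictionary and matching

The grid is integer milliseconds (defaults 200–1900 × 20–400 ms, step
1 ms, unphysical T2 > T1 excluded: 627 981 pairs; the two performance
fixtures use T1 600 ≤ T1 < 2000, giving exactly 533 400 and 21 560
entries at 1 and 5 ms steps).  Each entry is the magnitude of the complex
sum over a slice-profile ensemble — default 21 spins spanning 2× the
slice thickness (101 spins reproduces the high-accuracy configuration;
the per-spin profile sum converges: 5 % residual at 21 spins, 0.8 % at
101, against a 201-spin reference).  Entries are stored sorted by
(T1, T2) in HDF5 with the acquisition-config digest; loading against a
different session configuration is refused unless overridden.

Matching gives every entry a free non-negative amplitude
a_k = max(0, ⟨s,d_k⟩/⟨d_k,d_k⟩) — the per-pixel M0 is unknown — and
minimizes ‖s − a_k d_k‖² by full linear search; ties break toward smaller
(T1, T2) (entries are sorted, so first-minimum suffices).  The match is
exactly scale invariant.  Noiseless on-grid signals are recovered
exactly.  Off-grid truths land within one grid step in T1 for ~97 % of
uniformly drawn physiological pairs on a 20 ms grid; the remaining ~3 %
land two steps away by trading T1 against a T2 near the short-T2 edge —
the intrinsic T1–T2 ridge of the magnitude MOLLI signal, which carries
little T2 information except at long T1 / short T2.  T2 estimates are
therefore reported but only trustworthy in that corner, mirroring the
sequence's known T2 insensitivity.

## Conventional baseline

Per pixel, samples are sorted by effective TI (groups merged), polarity
is restored by exhaustive sign-flip search over the sorted prefix (n + 1
candidate inversion indices at n = 8 samples), and S(TI) = A − B·e^(−TI/T1*)
is fitted by bounded trust-region least squares with multi-start T1* ∈
{200, 600, 1000, 1600} ms (tolerances 1e−14, ≤500 evaluations); the
global residual minimum over polarity × starts wins, followed by
T1 = T1*(B/A − 1).  A ≤ 0 or non-convergence flags the pixel invalid
rather than aborting the map.  Identical pixel vectors are fitted once
(noise-free synthetic maps collapse to one fit per tissue).

On Bloch-simulated data this baseline reproduces the known failure
modes: T1* < T1 for every tissue; corrected T1 still underestimates, by
>100 ms for the long-T1 tissues (blood 1570/196, infarct 1361/64, edema
1249/62) on the no-pause 5(0p)3 scheme (mean 168 ms); and at fixed T2 the
error grows strictly with T1.  Across tissues with *varying* T2 the
growth is not monotone — blood's long T2 partially offsets the bias — so
the monotonicity property is asserted on the fixed-T2 fixture.

## Synthetic data generator

`make_phantom` lays out non-overlapping disks (or rectangles) with the
six-vial myocardial tissue table (normal myocardium 1048/50, blood
1570/196, edema 1249/62, infarct 1361/64, post-contrast 344/52 and
413/50 ms) or a Eurospin-style plate (T2 52 ms, T1 212–1522 ms; the
intermediate T1 values are synthetic, evenly spaced, since only the
endpoints are standard).  `make_rr_series` emulates the trigger: RR =
60000/bpm plus Gaussian jitter truncated at ±3 sd, seeded.
`simulate_acquisition` Bloch-simulates each distinct tissue once
(caching makes a 6-tissue image 6 simulations, not 10⁴), broadcasts by
M0, adds complex Gaussian noise per channel before the magnitude —
Rician statistics, so M0 = 0 background has Rayleigh mean σ√(π/2) — and
attaches the effective TIs.  Everything is bit-reproducible from the
seed.

What the generator does *not* emulate — and what passing tests therefore
do not show about scanner data: magnetization transfer, blood flow and
motion (stationary spins), B0/B1 inhomogeneity (off-resonance defaults
to 0), coil sensitivities and SENSE reconstruction noise correlation,
and trigger jitter within a beat (the trigger delay is absorbed into the
RR bookkeeping).  The paper-level claim this package *can* check is the
internal one: given MOLLI physics, dictionary matching recovers the
simulated truth where the conventional fit is biased.

## Problem sizes

Default test/analysis scale, chosen for single-core desk runs: Δt 50 µs,
21 slice spins, 20 ms or 5 ms grids (1 665 / 25 000 entries), 96×96
phantoms.  A full-protocol 5(3p)3 simulation of one (T1, T2) pair is
~8 ms; the 533 400-entry fixture is enumerated (counting is exact and
instant) but not simulated by the tests.

## Known limitations

- Only the slice axis is simulated; phase/readout gradients enter via
  timing only (no k-space encoding, no partial-volume within a shot).
- Phase-sensitive matching and inter-grid interpolation are not
  implemented (magnitude dictionary, full linear search).
- T2 from MOLLI is intrinsically ill-posed outside long-T1/short-T2; the
  matcher reports it with that caveat rather than suppressing it.
- The sech and sinc pulse parameters are contracts (inversion
  efficiency, flip calibration), not reproductions of any vendor's
  waveforms.
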