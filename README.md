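# mollisim

Simulation-based MOLLI relaxometry: accurate T1 (and, where the signal
allows, T2) from clinical cardiac T1-mapping series by Bloch-simulating
the identical pulse sequence and matching measured signals against a
dictionary of simulated outcomes.

## The problem

MOLLI (Modified Look-Locker Inversion recovery) merges several
ECG-triggered inversion-recovery experiments, each read out with
single-shot balanced-SSFP acquisitions, into one 8-point magnitude
recovery curve per pixel.  Conventional post-processing fits the
3-parameter model

    S(TI) = A − B·exp(−TI / T1*)

and corrects the apparent constant with the Look-Locker factor
T1 = T1*·(B/A − 1).  That correction is derived for a FLASH readout, not
the bSSFP readout MOLLI actually uses, so the corrected T1
systematically underestimates the truth — increasingly for long T1 and
for schemes with little recovery time between inversions.

`mollisim` sidesteps the closed form: it expands the acquisition
parameters, scheme (e.g. `5(3p)3`) and recorded RR intervals into the
exact pulse-sequence timeline, propagates a slice-profile ensemble of
spins through it with a discrete-event Bloch engine for every
physiological (T1, T2) pair (default grid 200–1900 × 20–400 ms), and
estimates per-pixel relaxation constants as the dictionary entry with
the least squared difference to the measured magnitudes (with a free
non-negative amplitude absorbing the unknown M0):

    (T1, T2) = argmin_k  min_{a ≥ 0} ‖ s − a·d_k ‖²

A digital-phantom generator (tissue T1/T2 tables, simulated ECG, Rician
noise) makes the whole pipeline testable without a scanner.  The
conventional fit is included as the baseline it improves upon.

Intended users: quantitative-MR researchers studying T1-mapping accuracy
and sequence effects on relaxometry, without access to scanner time.

## Worked example

```python
import numpy as np
import mollisim as ms
from mollisim.dictionary import GridSpec, build_dictionary
from mollisim.matching import match_series
from mollisim.conventional import conventional_map
from mollisim.evaluate import evaluate_bias
from mollisim.phantom import make_phantom

params = ms.default_acquisition_params(dt_us=50.0)   # phantom protocol
timing = ms.CardiacTiming.fixed(1000.0, 12)          # 60 bpm simulated ECG

phantom = make_phantom(shape=(48, 48))               # six-tissue disks
series = ms.simulate_acquisition(phantom, params, "5(3p)3", timing,
                                 noise_sigma=0.0, seed=1)
print("effective TIs [ms]:", np.round(np.sort(series.tis_ms), 1))

dictionary = build_dictionary(GridSpec(t1_step_ms=10.0, t2_step_ms=10.0),
                              params, "5(3p)3", timing)
print(f"dictionary: {dictionary.n_entries} entries")

rois = {t.name: phantom.region_mask(i + 1)
        for i, t in enumerate(phantom.tissues)}
reference = {t.name: t.t1_ms for t in phantom.tissues}

matched = match_series(series, dictionary, mask=phantom.labels > 0)
s = evaluate_bias(matched, reference, rois)
print(f"dictionary matching: T1 bias {s.mean_bias:+.1f} +/- {s.sd_bias:.1f} ms")

baseline = conventional_map(series, mask=phantom.labels > 0)
s2 = evaluate_bias(baseline, reference, rois)
print(f"conventional fit:    T1 bias {s2.mean_bias:+.1f} +/- {s2.sd_bias:.1f} ms")
```

prints (about 50 s on one core):

```
effective TIs [ms]: [ 114.  350. 1114. 1350. 2114. 2350. 3114. 4114.]
dictionary: 6459 entries
dictionary matching: T1 bias +0.8 +/- 4.6 ms
conventional fit:    T1 bias -47.8 +/- 28.1 ms
```

Reading this: the effective inversion times are the scheme's two initial
TIs (114 and 350 ms) plus whole heartbeats; dictionary matching recovers
the six ground-truth T1 values to within a grid step (+0.8 ms mean ROI
bias), while the conventional 3-parameter + Look-Locker pipeline on the
*same simulated data* is biased low by ~48 ms on average — the
FLASH-based correction under-corrects the bSSFP-perturbed recovery.

The same workflow is available from the shell
(`mollisim simulate-phantom / build-dict / match / fit-molli /
evaluate`; see `examples/phantom_protocol.yaml` for a config mirroring
the phantom protocol), and the two estimation stages are exposed as
sklearn-style estimators (`DictionaryMatcher`, `LookLockerT1`) for use
in pipelines.

See `docs/methods.md` for the model, numerical choices, and what the
synthetic phantoms do and do not emulate.

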