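"""Shared fixtures: phantom-protocol timelines and a coarse dictionary.

Heavy objects are session-scoped; the simulation step is 50 us everywhere
in the suite (RF pulses remain well resolved and full-protocol Bloch runs
stay sub-second) except where a test is explicitly about discretization.
"""

import numpy as np
import pytest

import mollisim as ms
from mollisim.dictionary import (GridSpec, build_dictionary,
                                 slice_spin_positions)

RELAX_OFF_MS = 1e9   # explicit "relaxation disabled" sentinel for tests


@pytest.fixture(scope="session")
def params50():
    return ms.default_acquisition_params(dt_us=50.0)


@pytest.fixture(scope="session")
def timing_rr1000():
    return ms.CardiacTiming.fixed(1000.0, 12)


@pytest.fixture(scope="session")
def timeline_533(params50, timing_rr1000):
    return ms.build_timeline(params50, "5(3p)3", timing_rr1000)


@pytest.fixture(scope="session")
def timeline_503(timing_rr1000):
    params = ms.default_acquisition_params(dt_us=50.0)
    return ms.build_timeline(params, "5(0p)3", timing_rr1000)


@pytest.fixture(scope="session")
def positions21(params50):
    return slice_spin_positions(params50.n_slice_spins,
                                params50.slice_thickness_mm,
                                params50.slice_fov_factor)


@pytest.fixture(scope="session")
def coarse_dict(params50, timing_rr1000):
    """20 ms / 20 ms dictionary over the physiological range, 5(3p)3."""
    spec = GridSpec(t1_step_ms=20.0, t2_step_ms=20.0)
    return build_dictionary(spec, params50, "5(3p)3", timing_rr1000)


def sorted_by_ti(timeline, signal):
    order = np.argsort(timeline.effective_tis_ms)
    return timeline.effective_tis_ms[order], np.asarray(signal)[order]
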