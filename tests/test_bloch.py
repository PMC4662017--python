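"""Bloch-engine physics: closed forms, oracle equivalence, ensemble laws."""

import numpy as np
import pytest
from scipy.linalg import expm

import mollisim as ms
from mollisim.bloch import (GAMMA, BlochNumericalError, Isochromat,
                            Magnetization, Timeline, TimelineEvent,
                            ensemble_signal, simulate_isochromat, step)

from conftest import RELAX_OFF_MS


def oracle_step(m, iso, ev):
    """Exact per-event propagation: exponentiate the 4x4 affine Bloch
    generator (rotation and relaxation simultaneously)."""
    b1 = ev.rf_amplitude_uT * 1e-6
    wx = GAMMA * b1 * np.cos(ev.rf_phase_rad)
    wy = GAMMA * b1 * np.sin(ev.rf_phase_rad)
    wz = GAMMA * ev.gradient_mT_m * 1e-3 * iso.z_position \
        + 2 * np.pi * iso.off_resonance_hz
    t1, t2 = iso.t1_ms * 1e-3, iso.t2_ms * 1e-3
    gen = np.array([
        [-1 / t2, wz, -wy, 0.0],
        [-wz, -1 / t2, wx, 0.0],
        [wy, -wx, -1 / t1, iso.equilibrium / t1],
        [0.0, 0.0, 0.0, 0.0]])
    out = expm(gen * ev.duration_s) @ np.array([m.mx, m.my, m.mz, 1.0])
    return Magnetization(*out[:3])


def hard_pulse(flip_deg, duration_s=1e-4, phase=0.0, n=10):
    b1_uT = np.deg2rad(flip_deg) / (GAMMA * duration_s) * 1e6
    return [TimelineEvent(duration_s=duration_s / n, rf_amplitude_uT=b1_uT,
                          rf_phase_rad=phase) for _ in range(n)]


class TestStep:
    def test_inversion_recovery_closed_form(self):
        iso = Isochromat(t1_ms=1000.0, t2_ms=100.0)
        ev = TimelineEvent(duration_s=1e-4)
        m = Magnetization(0.0, 0.0, -1.0)
        for _ in range(10_000):
            m = step(m, iso, ev)
        assert m.mz == pytest.approx(1.0 - 2.0 * np.exp(-1.0), rel=1e-6)

    def test_transverse_decay_closed_form(self):
        iso = Isochromat(t1_ms=500.0, t2_ms=80.0)
        ev = TimelineEvent(duration_s=80e-3 / 8000)   # dt = T2/8000
        m = Magnetization(0.6, 0.3, 0.5)
        for _ in range(8000):
            m = step(m, iso, ev)
        assert abs(m.transverse) == pytest.approx(
            abs(0.6 + 0.3j) * np.exp(-1.0), rel=1e-6)

    def test_90_degree_hard_pulse(self):
        iso = Isochromat(t1_ms=RELAX_OFF_MS, t2_ms=RELAX_OFF_MS)
        m = Magnetization()
        for ev in hard_pulse(90.0, n=100):
            m = step(m, iso, ev)
        assert abs(m.mz) < 1e-6
        assert abs(m.transverse) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_preserves_norm(self):
        iso = Isochromat(z_position=2e-3, t1_ms=RELAX_OFF_MS,
                         t2_ms=RELAX_OFF_MS, off_resonance_hz=70.0)
        rng = np.random.default_rng(7)
        m = Magnetization(0.3, -0.4, 0.6)
        norm0 = np.linalg.norm(m.as_array())
        for _ in range(200):
            ev = TimelineEvent(duration_s=1e-5,
                               rf_amplitude_uT=rng.uniform(0, 10),
                               rf_phase_rad=rng.uniform(0, 2 * np.pi),
                               gradient_mT_m=rng.uniform(-30, 30))
            m = step(m, iso, ev)
            assert np.linalg.norm(m.as_array()) == pytest.approx(
                norm0, abs=1e-9)

    def test_crusher_zeroes_transverse_and_is_idempotent(self):
        iso = Isochromat()
        crush = TimelineEvent(duration_s=0.0, is_crusher=True)
        m = Magnetization(0.5, -0.2, 0.4)
        once = step(m, iso, crush)
        twice = step(once, iso, crush)
        assert once.mx == once.my == 0.0
        assert once.mz == m.mz
        assert (twice.mx, twice.my, twice.mz) == (once.mx, once.my, once.mz)

    def test_invalid_relaxation_rejected(self):
        with pytest.raises(ValueError):
            Isochromat(t1_ms=-5.0, t2_ms=50.0)
        with pytest.raises(ValueError):
            Isochromat(t1_ms=500.0, t2_ms=0.0)

    def test_matches_matrix_exponential_oracle(self):
        """Stepwise propagation vs exact per-event exponential on random
        20-event timelines (dt small enough that the splitting error is
        far below the 1e-6 contract)."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            iso = Isochromat(z_position=rng.uniform(-3e-3, 3e-3),
                             t1_ms=300.0, t2_ms=40.0,
                             off_resonance_hz=rng.uniform(-100, 100))
            m_step = Magnetization()
            m_oracle = Magnetization()
            for _ in range(20):
                ev = TimelineEvent(
                    duration_s=1e-6,
                    rf_amplitude_uT=rng.uniform(0, 5),
                    rf_phase_rad=rng.uniform(0, 2 * np.pi),
                    gradient_mT_m=rng.uniform(-30, 30))
                m_step = step(m_step, iso, ev)
                m_oracle = oracle_step(m_oracle, iso, ev)
            np.testing.assert_allclose(m_step.as_array(),
                                       m_oracle.as_array(), atol=1e-6)


class TestSimulateIsochromat:
    def test_single_adc_after_90(self):
        events = hard_pulse(90.0, duration_s=1e-5) + [
            TimelineEvent(duration_s=1e-9, adc_image_index=0)]
        tl = Timeline.from_events(events)
        iso = Isochromat(t1_ms=RELAX_OFF_MS, t2_ms=RELAX_OFF_MS)
        s = simulate_isochromat(iso, tl)
        assert np.abs(s[0]) == pytest.approx(1.0, abs=1e-9)

    def test_free_decay_to_exp_minus_one(self):
        events = hard_pulse(90.0, duration_s=1e-6) + [
            TimelineEvent(duration_s=0.1, adc_image_index=0)]
        tl = Timeline.from_events(events)
        s = simulate_isochromat(Isochromat(t1_ms=1000.0, t2_ms=100.0), tl)
        assert np.abs(s[0]) == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_no_adc_markers_gives_empty_result(self):
        tl = Timeline.from_events([TimelineEvent(duration_s=1e-3)])
        s = simulate_isochromat(Isochromat(), tl)
        assert s.size == 0

    def test_kernel_agrees_with_python_stepper(self):
        rng = np.random.default_rng(3)
        events = []
        for _ in range(50):
            events.append(TimelineEvent(
                duration_s=rng.uniform(1e-6, 1e-4),
                rf_amplitude_uT=rng.uniform(0, 8),
                rf_phase_rad=rng.uniform(0, 2 * np.pi),
                gradient_mT_m=rng.uniform(-20, 20)))
        events.append(TimelineEvent(duration_s=1e-6, adc_image_index=0))
        tl = Timeline.from_events(events)
        iso = Isochromat(z_position=1e-3, t1_ms=300.0, t2_ms=40.0,
                         off_resonance_hz=25.0)
        m = Magnetization()
        for ev in events:
            m = step(m, iso, ev)
        s = simulate_isochromat(iso, tl)
        assert s[0] == pytest.approx(m.transverse, abs=1e-12)


class TestEnsemble:
    def test_single_spin_identity(self, timeline_533):
        iso = Isochromat(t1_ms=1048.0, t2_ms=50.0)
        np.testing.assert_array_equal(
            ensemble_signal([iso], timeline_533),
            simulate_isochromat(iso, timeline_533))

    def test_linearity(self, timeline_533):
        a = Isochromat(z_position=-1e-3, t1_ms=1048.0, t2_ms=50.0)
        b = Isochromat(z_position=2e-3, t1_ms=300.0, t2_ms=60.0)
        s_union = ensemble_signal([a, b], timeline_533)
        s_sum = ensemble_signal([a], timeline_533) \
            + ensemble_signal([b], timeline_533)
        np.testing.assert_allclose(s_union, s_sum, rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(
            ensemble_signal([a, a], timeline_533),
            2.0 * ensemble_signal([a], timeline_533), rtol=1e-12)

    def test_empty_ensemble_rejected(self, timeline_533):
        with pytest.raises(ValueError):
            ensemble_signal([], timeline_533)

    def test_edge_spins_contribute_little(self, params50):
        """Spins a full slice-thickness off center see the sinc stopband:
        their transverse response after one excitation is < 10 % of the
        center spin's."""
        events = ms.make_sinc_pulse(dt_us=10.0)
        tl = Timeline.from_events(
            events + [TimelineEvent(duration_s=1e-9, adc_image_index=0)])
        center = np.abs(simulate_isochromat(
            Isochromat(0.0, RELAX_OFF_MS, RELAX_OFF_MS), tl))[0]
        edge = np.abs(simulate_isochromat(
            Isochromat(6e-3, RELAX_OFF_MS, RELAX_OFF_MS), tl))[0]
        assert edge < 0.10 * center


def test_molli_sample_converges_with_dt(timing_rr1000, positions21):
    """Halving the simulation step from 10 us to 5 us changes every MOLLI
    sample by < 0.5 % (edge spins precess ~4 rad per 50 us step under the
    slice gradient, so convergence at this level needs the finer steps)."""
    from mollisim.dictionary import simulate_entry
    sigs = {}
    for dt in (10.0, 5.0):
        p = ms.default_acquisition_params(dt_us=dt)
        tl = ms.build_timeline(p, "5(3p)3", timing_rr1000)
        sigs[dt] = simulate_entry(1048.0, 50.0, tl, positions21)
    rel = np.abs(sigs[5.0] - sigs[10.0]) / np.abs(sigs[5.0])
    assert np.max(rel) < 0.005
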