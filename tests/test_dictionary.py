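"""Grid enumeration, slice-profile sampling, dictionary build/persist."""

import numpy as np
import pytest

import mollisim as ms
from mollisim.dictionary import (DigestMismatchError, GridSpec,
                                 SignalDictionary, build_dictionary,
                                 enumerate_grid, load_dictionary,
                                 save_dictionary, simulate_entry,
                                 slice_spin_positions)


class TestEnumerateGrid:
    def test_hand_counted_exclusion(self):
        spec = GridSpec(t1_start_ms=200, t1_stop_ms=201, t1_step_ms=1,
                        t2_start_ms=199, t2_stop_ms=201, t2_step_ms=1)
        pairs = enumerate_grid(spec)
        assert pairs.shape == (5, 2)
        assert [tuple(p) for p in pairs] == [
            (200, 199), (200, 200), (201, 199), (201, 200), (201, 201)]

    def test_full_physiological_grid_against_brute_force(self):
        spec = GridSpec()   # 200-1900 / 20-400, 1 ms, T2 <= T1
        count = enumerate_grid(spec).shape[0]
        brute = sum(1 for t1 in range(200, 1901)
                    for t2 in range(20, 401) if t2 <= t1)
        assert count == brute == 627_981

    def test_rectangular_count_closed_form(self):
        spec = GridSpec(t1_start_ms=600, t1_stop_ms=700, t1_step_ms=5,
                        t2_start_ms=20, t2_stop_ms=100, t2_step_ms=10)
        pairs = enumerate_grid(spec)
        assert pairs.shape[0] == 21 * 9      # exclusion vacuous here
        assert np.all(pairs[:, 1] <= pairs[:, 0])

    def test_half_open_axis(self):
        spec = GridSpec(t1_start_ms=600, t1_stop_ms=2000, t1_step_ms=5,
                        t1_stop_inclusive=False,
                        t2_start_ms=20, t2_stop_ms=400, t2_step_ms=5)
        assert spec.t1_values()[-1] == 1995
        assert spec.t1_values().size == 280

    def test_sorted_and_unique(self):
        pairs = enumerate_grid(GridSpec(t1_step_ms=100, t2_step_ms=100))
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        np.testing.assert_array_equal(order, np.arange(pairs.shape[0]))
        assert np.unique(pairs, axis=0).shape == pairs.shape

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            enumerate_grid(GridSpec(t1_start_ms=100, t1_stop_ms=100,
                                    t1_step_ms=1, t2_start_ms=300,
                                    t2_stop_ms=300, t2_step_ms=1))


class TestSpinPositions:
    def test_three_spins_span_thickness(self):
        np.testing.assert_allclose(
            slice_spin_positions(3, 6.0, 1.0), [-3e-3, 0.0, 3e-3])

    def test_21_spins_double_fov(self):
        z = slice_spin_positions(21, 6.0, 2.0)
        assert z.size == 21
        assert z[0] == pytest.approx(-6e-3)
        assert np.diff(z) == pytest.approx(0.6e-3)
        assert z[10] == 0.0

    def test_even_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            slice_spin_positions(20, 6.0, 2.0)

    def test_profile_sum_converges(self, timeline_533):
        """Per-spin ensemble signal converges as the slice profile is
        sampled more finely (201-spin reference)."""
        ref = simulate_entry(1048.0, 50.0, timeline_533,
                             slice_spin_positions(201, 6.0, 2.0)) / 201
        errs = []
        for n in (21, 51, 101):
            s = simulate_entry(1048.0, 50.0, timeline_533,
                               slice_spin_positions(n, 6.0, 2.0)) / n
            errs.append(np.max(np.abs(s - ref) / ref))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.015


class TestSimulateEntry:
    def test_deterministic(self, timeline_533, positions21):
        a = simulate_entry(1048.0, 50.0, timeline_533, positions21)
        b = simulate_entry(1048.0, 50.0, timeline_533, positions21)
        np.testing.assert_array_equal(a, b)

    def test_first_group_first_image_is_minimum(self, timeline_533,
                                                positions21):
        """The image closest to the inversion has the smallest recovery
        -- but magnitudes near the zero crossing dip lower, so the robust
        property is that the *sorted-TI* signal shape fits an IR model
        whose pole exceeds every sample (checked via the conventional
        fit elsewhere); here: the TI=114 ms sample sits on the negative
        pole, i.e. the polarity-restored fit flips it."""
        sig = simulate_entry(1048.0, 50.0, timeline_533, positions21)
        order = np.argsort(timeline_533.effective_tis_ms)
        fit = ms.fit_ir3(timeline_533.effective_tis_ms[order], sig[order])
        assert fit.inversion_index >= 1

    def test_no_relaxation_limit_has_no_contrast(self, timeline_533):
        """With relaxation disabled the on-resonance slice-center spin
        shows no relaxation contrast: images of the same bSSFP parity
        within a group are identical.  (Opposite-parity images alternate
        because each 75-pulse shot flips the phase parity; off-center
        spins scramble between shots, so the property is a single-spin
        one.)"""
        from mollisim.bloch import Isochromat, simulate_isochromat
        sig = np.abs(simulate_isochromat(
            Isochromat(z_position=0.0, t1_ms=1e12, t2_ms=1e12),
            timeline_533))
        g0 = sig[:5]
        np.testing.assert_allclose(g0[[0, 2, 4]], g0[0], rtol=1e-6)
        np.testing.assert_allclose(g0[[1, 3]], g0[1], rtol=1e-6, atol=1e-9)
        g1 = sig[5:]
        np.testing.assert_allclose(g1[[0, 2]], g1[0], rtol=1e-6)

    def test_invalid_pair_rejected(self, timeline_533, positions21):
        with pytest.raises(ValueError):
            simulate_entry(-100.0, 50.0, timeline_533, positions21)


class TestBuildDictionary:
    @pytest.fixture(scope="class")
    def toy_dict(self, params50, timing_rr1000):
        spec = GridSpec(t1_start_ms=800, t1_stop_ms=1000, t1_step_ms=100,
                        t2_start_ms=40, t2_stop_ms=80, t2_step_ms=20)
        return spec, build_dictionary(spec, params50, "5(3p)3",
                                      timing_rr1000)

    def test_toy_grid_shape_and_order(self, toy_dict):
        _, d = toy_dict
        assert d.n_entries == 9
        order = np.lexsort((d.t2_ms, d.t1_ms))
        np.testing.assert_array_equal(order, np.arange(9))

    def test_workers_do_not_change_result(self, toy_dict, params50,
                                          timing_rr1000):
        spec, d1 = toy_dict
        d4 = build_dictionary(spec, params50, "5(3p)3", timing_rr1000,
                              n_workers=4)
        np.testing.assert_array_equal(d1.signals, d4.signals)
        assert d1.meta["digest"] == d4.meta["digest"]

    def test_entry_matches_standalone_simulation(self, toy_dict, params50,
                                                 timing_rr1000, positions21,
                                                 timeline_533):
        _, d = toy_dict
        i = d.entry_index(900.0, 60.0)
        standalone = simulate_entry(900.0, 60.0, timeline_533, positions21)
        np.testing.assert_allclose(d.signals[i], standalone, rtol=1e-12)

    def test_signal_bounds(self, coarse_dict, params50):
        assert np.all(coarse_dict.signals > 0)
        assert np.all(coarse_dict.signals < params50.n_slice_spins)

    def test_neighbors_distinct_but_close(self, coarse_dict):
        """Signals vary continuously over the grid and distinct (T1,T2)
        give distinct vectors (subsampled check)."""
        d = coarse_dict
        sub = np.arange(0, d.n_entries, 7)
        norm = d.signals[sub] / np.linalg.norm(d.signals[sub], axis=1,
                                               keepdims=True)
        assert np.unique(np.round(norm, 9), axis=0).shape[0] == sub.size
        # adjacent T1 at fixed T2=60: one 20 ms step moves the normalized
        # signal by a small bounded amount
        i = d.entry_index(1000.0, 60.0)
        j = d.entry_index(1020.0, 60.0)
        a = d.signals[i] / np.linalg.norm(d.signals[i])
        b = d.signals[j] / np.linalg.norm(d.signals[j])
        assert 0 < np.linalg.norm(a - b) < 0.05


class TestPersistence:
    def test_round_trip(self, coarse_dict, tmp_path):
        path = tmp_path / "dict.h5"
        save_dictionary(path, coarse_dict)
        loaded = load_dictionary(path,
                                 expected_digest=coarse_dict.meta["digest"])
        np.testing.assert_array_equal(loaded.signals, coarse_dict.signals)
        np.testing.assert_array_equal(loaded.t1_ms, coarse_dict.t1_ms)
        np.testing.assert_array_equal(loaded.tis_ms, coarse_dict.tis_ms)
        assert loaded.meta == coarse_dict.meta

    def test_digest_mismatch_refused(self, coarse_dict, tmp_path,
                                     timing_rr1000):
        path = tmp_path / "dict.h5"
        save_dictionary(path, coarse_dict)
        other = ms.default_acquisition_params(dt_us=50.0, tr_ms=3.0,
                                              te_ms=1.5)
        digest = ms.config_digest(other, "5(3p)3", timing_rr1000)
        with pytest.raises(DigestMismatchError):
            load_dictionary(path, expected_digest=digest)
        # override flag lets an explicit user decision through
        assert load_dictionary(path, expected_digest=digest,
                               allow_mismatch=True).n_entries \
            == coarse_dict.n_entries

    def test_truncated_file_rejected(self, coarse_dict, tmp_path):
        path = tmp_path / "dict.h5"
        save_dictionary(path, coarse_dict)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(OSError):
            load_dictionary(path)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            SignalDictionary(t1_ms=[800, 900], t2_ms=[50, 50],
                             signals=np.ones((3, 8)), tis_ms=np.ones(8))
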