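import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iedwaves import (classify_events, collect_mua_times, detect_ied_candidates,
                      extract_extrema_times, fit_plane, permutation_test_wave,
                      qa_filter)
from iedwaves.circular import angle_difference
from iedwaves.synthetic import _planar_delays


def _times_dict(t):
    return {i: float(t[i]) for i in range(len(t))}


class TestFitPlane:
    def test_closed_form_x_gradient(self, geometry):
        # t = 0.8 * x ms: 0.8 ms/mm gradient -> 125 cm/s heading +x
        pos = geometry.positions()
        fit = fit_plane(_times_dict(0.8e-3 * pos[:, 0]), geometry)
        assert fit.beta_x_ms_per_mm == pytest.approx(0.8, abs=1e-9)
        assert fit.beta_y_ms_per_mm == pytest.approx(0.0, abs=1e-9)
        assert fit.speed_cm_s == pytest.approx(125.0, abs=1e-6)
        assert fit.direction_rad == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_at_reported_median_speed(self, geometry):
        # 45 degrees at 20.9 cm/s
        pos = geometry.positions()
        delays = _planar_delays(pos, np.pi / 4, 20.9)
        fit = fit_plane(_times_dict(delays), geometry)
        assert fit.speed_cm_s == pytest.approx(20.9, rel=1e-9)
        assert np.rad2deg(fit.direction_rad) == pytest.approx(45.0, abs=1e-9)

    def test_rotation_equivariance(self, geometry):
        pos = geometry.positions()
        delays = _planar_delays(pos, 0.3, 60.0)
        psi = 1.1
        rot = np.array([[np.cos(psi), -np.sin(psi)], [np.sin(psi), np.cos(psi)]])
        fit0 = fit_plane(delays, pos)
        fit1 = fit_plane(delays, pos @ rot.T)
        assert angle_difference(fit1.direction_rad, fit0.direction_rad + psi) < 1e-9
        assert fit1.speed_cm_s == pytest.approx(fit0.speed_cm_s, rel=1e-12)

    def test_scale_law_double_delay_halves_speed(self, geometry):
        pos = geometry.positions()
        delays = _planar_delays(pos, 2.0, 80.0)
        s1 = fit_plane(delays, pos).speed_cm_s
        s2 = fit_plane(2 * delays, pos).speed_cm_s
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_lad_robust_to_outlier_channels(self, geometry):
        pos = geometry.positions()
        rng = np.random.default_rng(5)
        lad_err, ols_err = [], []
        for _ in range(50):
            phi = rng.uniform(0, 2 * np.pi)
            delays = _planar_delays(pos, phi, 40.0)
            bad = rng.choice(100, 20, replace=False)
            noisy = delays.copy()
            noisy[bad] += rng.choice([-1, 1], 20) * 5e-3
            lad = fit_plane(noisy, pos, method="lad")
            ols = fit_plane(noisy, pos, method="ols")
            lad_err.append(np.rad2deg(angle_difference(lad.direction_rad, phi)))
            ols_err.append(np.rad2deg(angle_difference(ols.direction_rad, phi)))
        assert np.mean(lad_err) < 5.0
        assert np.mean(lad_err) < np.mean(ols_err)

    def test_rank_deficient_raises(self, geometry):
        times = {i: 0.001 * i for i in range(10)}  # all in row 0
        with pytest.raises(ValueError, match="rank"):
            fit_plane(times, geometry)

    def test_zero_gradient_not_traveling(self, geometry):
        fit = fit_plane({i: 1.0 for i in range(100)}, geometry)
        assert np.isnan(fit.speed_cm_s)
        assert not fit.is_traveling

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(phi=st.floats(0, 2 * np.pi - 1e-6),
           speed=st.floats(15.0, 150.0))
    def test_exact_recovery_any_plane(self, geometry, phi, speed):
        delays = _planar_delays(geometry.positions(), phi, speed)
        fit = fit_plane(delays, geometry.positions())
        assert fit.speed_cm_s == pytest.approx(speed, rel=1e-6)
        assert angle_difference(fit.direction_rad, phi) < 1e-6


class TestPermutation:
    def test_exact_plane_minimum_p(self, geometry):
        delays = _planar_delays(geometry.positions(), 1.0, 50.0)
        p = permutation_test_wave(delays, geometry.positions(), n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_constant_times_not_traveling(self, geometry):
        p = permutation_test_wave(np.full(100, 2.0), geometry.positions(),
                                  n_perm=200, seed=0)
        assert p > 0.5

    def test_p_respects_add_one_floor(self, geometry):
        delays = _planar_delays(geometry.positions(), 0.0, 30.0)
        p = permutation_test_wave(delays, geometry.positions(), n_perm=99, seed=1)
        assert p >= 1 / 100


def _truth_event(rec, truth, i):
    """IEDEvent built from the planted ground truth (bypasses the detector)."""
    from iedwaves.core_io import IEDEvent
    t0 = float(truth.t0[i])
    return IEDEvent(event_time_s=t0,
                    channel_peak_times_s={ch: t0 for ch in range(100)},
                    channel_amplitudes_uv={ch: 500.0 for ch in range(100)},
                    n_detecting_channels=100)


class TestEventTiming:
    def test_noiseless_extraction_matches_planted_plane(self, noiseless_recording):
        rec, truth = noiseless_recording
        ev = _truth_event(rec, truth, 0)
        times = extract_extrema_times(rec, ev)
        assert len(times) == 100
        fit = fit_plane(times, rec.geometry)
        row = truth.iloc[0]
        assert np.rad2deg(angle_difference(fit.direction_rad,
                                           row.direction_rad)) < 2.0
        assert fit.speed_cm_s == pytest.approx(row.speed_cm_s, rel=0.05)

    def test_flat_channel_excluded(self, noiseless_recording):
        rec, truth = noiseless_recording
        rec.lfp[7, :] = 0.0
        times = extract_extrema_times(rec, _truth_event(rec, truth, 1))
        assert 7 not in times

    def test_mua_window_boundary(self, noiseless_recording):
        rec, truth = noiseless_recording
        ev = _truth_event(rec, truth, 2)
        med = float(np.median(list(ev.channel_peak_times_s.values())))
        rec.mua_times[3] = np.array([med + 0.08])  # outside +/-50 ms
        rec.mua_times[4] = np.array([med + 0.02])
        spikes = collect_mua_times(rec, ev)
        assert 3 not in spikes
        assert 4 in spikes


class TestClassifyEvents:
    def test_all_planted_traveling(self, planted_recording):
        rec, _ = planted_recording
        events = qa_filter(detect_ied_candidates(rec), rec)
        res = classify_events(events, rec, n_perm=200, seed=0)
        assert res["summary"]["ied_lfp"]["fraction_traveling"] == 1.0
        # MUA-based detection holds at a less-than-or-equal rate
        assert (res["summary"]["ied_mua"]["n_traveling"]
                <= res["summary"]["ied_lfp"]["n_traveling"])
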