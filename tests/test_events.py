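"""Event detection: mid-swing segmentation, IC/TC localization (conventional
and fused), and mid-stance detection."""

import numpy as np
import pytest

from runstride.config import IcConfig, MsConfig, TcConfig
from runstride.events import (
    detect_ic_avgs,
    detect_ic_fused,
    detect_ms,
    detect_msw,
    detect_tc_fused,
    ms_weight,
)

FS = 200.0


def _gauss_bumps(centers, amp, sigma_t, noise_sd, duration, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * FS)) / FS
    x = rng.normal(0, noise_sd, len(t)) if noise_sd else np.zeros(len(t))
    for c in centers:
        x += amp * np.exp(-0.5 * ((t - c) / sigma_t) ** 2)
    return t, x


class TestMsw:
    def test_flat_signal_has_no_strides(self):
        with pytest.raises(ValueError, match="no complete stride|no peaks"):
            detect_msw(np.zeros(1000), FS)

    def test_recovers_constructed_peaks(self):
        t, x = _gauss_bumps([1.0, 1.75, 2.5], amp=8.0, sigma_t=0.05, noise_sd=0.1,
                            duration=3.5, seed=5)
        msw = detect_msw(x, FS)
        assert len(msw) == 3
        assert np.all(np.abs(msw - [1.0, 1.75, 2.5]) <= 1.0 / FS + 1e-9)

    def test_close_peaks_deduplicated_keeping_larger(self):
        t = np.arange(int(3.0 * FS)) / FS
        x = np.zeros(len(t))
        x[int(1.0 * FS)] = 5.0
        x[int(1.1 * FS)] = 6.0  # 0.1 s apart: keep the larger
        x[int(2.2 * FS)] = 6.0
        msw = detect_msw(x, FS, min_separation_s=0.4)
        assert np.allclose(msw, [1.1, 2.2])

    def test_equal_close_peaks_keep_earlier(self):
        t = np.arange(int(3.0 * FS)) / FS
        x = np.zeros(len(t))
        x[int(1.0 * FS)] = 6.0
        x[int(1.1 * FS)] = 6.0
        x[int(2.2 * FS)] = 6.0
        msw = detect_msw(x, FS, min_separation_s=0.4)
        assert np.allclose(msw, [1.0, 2.2])

    def test_short_signal_raises(self):
        with pytest.raises(ValueError, match="1 s"):
            detect_msw(np.zeros(50), FS)


class TestIcAvgs:
    def test_interpolated_zero_crossing(self):
        # sine lobe crossing zero at exactly t = 0.50 s
        t = np.arange(int(1.0 * FS)) / FS
        wx = np.sin(2 * np.pi * 1.0 * (0.50 - t))  # positive before 0.5, negative after
        wx[t < 0.1] = 0.1
        neg, zc = detect_ic_avgs(t, wx, FS, (0.1, 0.9))
        assert zc == pytest.approx(0.50, abs=0.5 / FS)

    def test_strictly_positive_signal_has_no_crossing(self):
        t = np.arange(int(1.0 * FS)) / FS
        wx = 1.0 + 0.1 * np.sin(2 * np.pi * t)
        neg, zc = detect_ic_avgs(t, wx, FS, (0.0, 0.99))
        assert zc is None

    def test_negative_peak_found(self):
        t = np.arange(int(1.0 * FS)) / FS
        wx = -np.exp(-0.5 * ((t - 0.55) / 0.04) ** 2)
        neg, _ = detect_ic_avgs(t, wx, FS, (0.0, 0.99), negpeak_frac=0.99)
        assert neg == pytest.approx(0.55, abs=1.0 / FS)


def _stride_signals(t_kinematic=None, t_kinetic=None, duration=1.2):
    """wx with a single down-crossing at t_kinematic; a_ap with a single
    spike at t_kinetic."""
    t = np.arange(int(duration * FS)) / FS
    wx = np.zeros(len(t))
    a = np.zeros(len(t))
    if t_kinematic is not None:
        wx = 2.0 * (t_kinematic - t)  # crosses + to - exactly there
    if t_kinetic is not None:
        a += 10.0 * np.exp(-0.5 * ((t - t_kinetic) / 0.01) ** 2)
    return t, wx, a


class TestIcFused:
    def test_weighted_combination(self):
        t, wx, a = _stride_signals(t_kinematic=0.50, t_kinetic=0.48)
        ic, cand, flags = detect_ic_fused(
            t, wx, a, FS, ic_coarse=0.50, stride_duration=0.8, stride_window=(0.1, 1.1),
            cfg=IcConfig(w_acc=0.7),
        )
        assert cand["kinematic"] == pytest.approx(0.50, abs=1e-6)
        assert cand["kinetic"] == pytest.approx(0.48, abs=0.5 / FS)
        assert ic == pytest.approx(0.7 * 0.48 + 0.3 * 0.50, abs=2e-3)

    def test_coincident_candidates(self):
        t, wx, a = _stride_signals(t_kinematic=0.50, t_kinetic=0.50)
        ic, _, _ = detect_ic_fused(t, wx, a, FS, 0.50, 0.8, (0.1, 1.1), IcConfig(w_acc=0.3))
        assert ic == pytest.approx(0.50, abs=2e-3)

    def test_degenerate_weight_takes_acceleration_peak(self):
        t, wx, a = _stride_signals(t_kinematic=0.52, t_kinetic=0.46)
        ic, cand, _ = detect_ic_fused(t, wx, a, FS, 0.50, 0.8, (0.1, 1.1), IcConfig(w_acc=1.0))
        assert ic == cand["kinetic"]

    def test_missing_kinematic_falls_back_to_kinetic(self):
        t, wx, a = _stride_signals(t_kinetic=0.48)
        wx[:] = 1.0  # never crosses
        ic, cand, flags = detect_ic_fused(t, wx, a, FS, 0.50, 0.8, (0.1, 1.1))
        assert "no_kinematic_ic" in flags
        assert ic == cand["kinetic"]


class TestTcFused:
    def test_weighted_combination(self):
        # toe-off dip at 0.82 (kinematic inflections nearby), propulsive
        # spike at 0.80
        t = np.arange(int(1.4 * FS)) / FS
        wx = -3.0 * np.exp(-0.5 * ((t - 0.82) / 0.05) ** 2)
        a = 10.0 * np.exp(-0.5 * ((t - 0.80) / 0.01) ** 2)
        tc, cand, flags = detect_tc_fused(t, wx, a, FS, ic=0.5, stride_duration=0.74,
                                          cfg=TcConfig(w_acc=0.7))
        assert cand["kinetic"] == pytest.approx(0.80, abs=0.5 / FS)
        expected = 0.7 * cand["kinetic"] + 0.3 * cand["kinematic"]
        assert tc == pytest.approx(expected, abs=1e-9)
        assert tc > 0.5

    def test_tc_never_before_ic(self, sim_default):
        from runstride.pipeline import analyze

        rec, _ = sim_default
        res = analyze(rec)
        for s in res.events.strides:
            assert s.tc > s.ic


class TestMsWeight:
    def test_first_stride_weight_is_one(self):
        assert ms_weight(0.5, None) == 1.0

    def test_unchanged_variance_gives_one(self):
        assert ms_weight(0.4, 0.4) == 1.0

    def test_printed_arithmetic(self):
        # var 0.4 against previous 0.2: w = 0.4 / (0.4 + 0.2) = 2/3
        assert ms_weight(0.4, 0.2) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_always_in_unit_interval(self, rng):
        for _ in range(200):
            v, pv = rng.uniform(0, 2, 2)
            assert 0.0 <= ms_weight(v, pv) <= 1.0


class TestDetectMs:
    def _signals(self, quiet_gyro_at, quiet_acc_at, duration=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration * FS)) / FS
        gyr = rng.normal(0, 1.0, (len(t), 3))
        gyr *= (1.0 - np.exp(-0.5 * ((t - quiet_gyro_at) / 0.04) ** 2))[:, None]
        acc = rng.normal(0, 1.0, (len(t), 2))
        acc *= (1.0 - np.exp(-0.5 * ((t - quiet_acc_at) / 0.04) ** 2))[:, None]
        return t, gyr, acc

    def test_first_stride_takes_gyro_candidate(self):
        t, gyr, acc = self._signals(quiet_gyro_at=0.45, quiet_acc_at=0.60)
        ms, var, flags = detect_ms(t, gyr, acc, FS, ic=0.2, tc=0.8, prev_var=None)
        # w = 1 on the first stride: ms equals the gyro-energy minimum
        assert ms == pytest.approx(0.45, abs=0.05)

    def test_blended_between_candidates(self):
        t, gyr, acc = self._signals(quiet_gyro_at=0.40, quiet_acc_at=0.62)
        ms1, var1, _ = detect_ms(t, gyr, acc, FS, 0.2, 0.8, prev_var=None)
        ms2, var2, _ = detect_ms(t, gyr, acc, FS, 0.2, 0.8, prev_var=var1 * 0.5)
        lo, hi = sorted([ms1, 0.62])
        assert lo - 0.06 <= ms2 <= hi + 0.06

    def test_matches_bruteforce_scan(self, rng):
        cfg = MsConfig()
        t = np.arange(int(1.0 * FS)) / FS
        gyr = rng.normal(0, 1.0, (len(t), 3))
        acc = rng.normal(0, 1.0, (len(t), 2))
        ic, tc = 0.15, 0.85
        ms, var, _ = detect_ms(t, gyr, acc, FS, ic, tc, prev_var=None, cfg=cfg)
        # exhaustive re-scan from first principles
        ct = tc - ic
        i_lo = int(np.floor((ic + cfg.trim_frac * ct) * FS + 0.5))
        i_hi = int(np.floor((tc - cfg.trim_frac * ct) * FS + 0.5))
        L = max(int(round(cfg.window_frac * ct * FS)), 2)
        best_e, best_v, t_w, t_v, v_at_tv = np.inf, np.inf, None, None, None
        for j in range(i_lo, i_hi - L + 2):
            g = gyr[j : j + L]
            a = acc[j : j + L]
            e = float(np.mean(np.sum(g**2, axis=1)))
            v = float(np.var(a[:, 0]) + np.var(a[:, 1]))
            c = t[j] + (L - 1) / (2 * FS)
            if e < best_e:
                best_e, t_w = e, c
            if v < best_v:
                best_v, t_v, v_at_tv = v, c, v
        assert ms == pytest.approx(t_w, abs=1e-12)  # first stride: w = 1
        assert var == pytest.approx(best_v, abs=1e-12)

    def test_zero_gyro_ties_break_earliest(self):
        t = np.arange(int(1.0 * FS)) / FS
        gyr = np.zeros((len(t), 3))
        acc = np.zeros((len(t), 2))
        cfg = MsConfig()
        ms, _, flags = detect_ms(t, gyr, acc, FS, 0.2, 0.8, prev_var=None, cfg=cfg)
        ct = 0.6
        i_lo = int(np.floor((0.2 + cfg.trim_frac * ct) * FS + 0.5))
        L = max(int(round(cfg.window_frac * ct * FS)), 2)
        earliest = t[i_lo] + (L - 1) / (2 * FS)
        assert ms == pytest.approx(earliest, abs=1e-12)

    def test_short_stance_falls_back_to_midpoint(self):
        t = np.arange(int(1.0 * FS)) / FS
        ms, _, flags = detect_ms(t, np.zeros((len(t), 3)), np.zeros((len(t), 2)),
                                 FS, 0.500, 0.515, prev_var=None)
        assert "stance_too_short" in flags
        assert ms == pytest.approx(0.5075, abs=1e-9)


class TestEventOrdering:
    def test_ordering_on_detected_strides(self, results_default):
        ev = results_default.events
        for k, s in enumerate(ev.strides):
            assert ev.msw[k] < s.ic < s.ms < s.tc < ev.msw[k + 1]
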