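"""Calibration, dF/F0, paired-pulse and quantal estimators, decay fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from astrokir.estimators import (
    GinkoCalibration,
    PPRUndefinedError,
    TraceSeries,
    decay_time,
    dff,
    efold_time,
    fit_ginko_calibration,
    ginko_invert,
    ginko_response,
    ppr_from_dff,
    pr_from_trials,
    subtract_residual,
)
from astrokir.synthetic_data import gen_paired_dff, gen_transient


class TestGinko:
    def test_reference_points(self):
        assert ginko_response(0.0) == pytest.approx(9340 * np.log(2.74), rel=1e-12)
        assert ginko_response(10.0) == pytest.approx(23_768, rel=1e-3)

    def test_log_identity(self):
        calib = GinkoCalibration()
        lhs = ginko_response(calib.b * (np.e - 1.0), calib) - ginko_response(0.0, calib)
        assert lhs == pytest.approx(calib.a, rel=1e-12)

    def test_roundtrip_identity(self):
        k = np.linspace(0.0, 20.0, 201)
        back = ginko_invert(ginko_response(k))
        np.testing.assert_allclose(back, k, rtol=1e-10, atol=1e-10)

    def test_signal_below_range_rejected(self):
        with pytest.raises(ValueError):
            ginko_invert(9340 * np.log(2.74) - 100.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ginko_response(-0.1)


class TestGinkoFit:
    def test_noiseless_recovery(self):
        k = np.geomspace(0.1, 10.0, 8)
        points = pd.DataFrame({"k_out_mM": k, "ratio": 9340 * np.log(k + 2.74)})
        fit = fit_ginko_calibration(points)
        assert fit.calibration.a == pytest.approx(9340.0, rel=1e-4)
        assert fit.calibration.b == pytest.approx(2.74, rel=1e-4)
        assert fit.rmse < 1e-6

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(7)
        k = np.geomspace(0.1, 10.0, 8)
        ratio = 9340 * np.log(k + 2.74) * (1 + rng.normal(0, 0.02, k.size))
        fit = fit_ginko_calibration(pd.DataFrame({"k_out_mM": k, "ratio": ratio}))
        assert fit.calibration.a == pytest.approx(9340.0, rel=0.10)
        assert fit.calibration.b == pytest.approx(2.74, rel=0.10)

    def test_degenerate_grid_rejected(self):
        points = pd.DataFrame({"k_out_mM": [2.5, 2.5, 2.5], "ratio": [1.0, 1.1, 0.9]})
        with pytest.raises(ValueError):
            fit_ginko_calibration(points)


class TestDff:
    def _trace(self, values):
        t = np.arange(len(values)) * 1e-3
        return TraceSeries(t=t, values=np.asarray(values, dtype=float))

    def test_constant_trace_is_zero(self):
        out = dff(self._trace([5.0] * 100), (0.0, 0.05))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_peak_fraction(self):
        values = [100.0] * 50 + [130.0] * 10 + [100.0] * 40
        out = dff(self._trace(values), (0.0, 0.049))
        assert out.values.max() == pytest.approx(0.30)

    @settings(derandomize=True, max_examples=25)
    @given(gain=st.floats(min_value=0.1, max_value=100.0))
    def test_gain_invariance(self, gain):
        base = np.concatenate([np.full(50, 10.0), np.full(50, 14.0)])
        a = dff(self._trace(base), (0.0, 0.049))
        b = dff(self._trace(base * gain), (0.0, 0.049))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12, atol=1e-12)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            dff(self._trace([0.0] * 50 + [1.0] * 50), (0.0, 0.049))


class TestPprFromDff:
    def test_identical_pulses_give_unity(self):
        trace, _ = gen_paired_dff(peak1=0.25, peak2=0.25, noise_sd=0.0)
        assert ppr_from_dff(trace) == pytest.approx(1.0, rel=0.02)

    def test_constructed_plateaus(self):
        t = np.arange(0, 0.3, 5e-4)
        v = np.zeros_like(t)
        v[(t >= 0.11) & (t < 0.13)] = 0.20
        v[(t >= 0.16) & (t < 0.18)] = 0.30
        trace = TraceSeries(t=t, values=v)
        assert ppr_from_dff(trace, stim_times=[0.1, 0.15]) == pytest.approx(1.5, rel=1e-9)

    def test_alpha_function_bias_below_two_percent(self):
        trace, truth = gen_paired_dff(peak1=0.2, peak2=0.3, noise_sd=0.0)
        assert ppr_from_dff(trace) == pytest.approx(truth["ppr"], rel=0.02)

    def test_window_search_matches_brute_force(self):
        """Overlapping responses: the implementation's windowed average equals
        an exhaustive search over the same half-open windows."""
        trace, _ = gen_paired_dff(peak1=0.2, peak2=0.3, rise_tau=0.02, noise_sd=0.0)
        s1, s2 = trace.stim_times
        isi = s2 - s1
        half = 5e-3

        def brute(lo, hi):
            sel = np.nonzero((trace.t >= lo - 1e-12) & (trace.t < hi - 1e-12))[0]
            ip = sel[np.argmax(trace.values[sel])]
            tp = trace.t[ip]
            w = (trace.t >= max(tp - half, lo) - 1e-12) & (trace.t <= min(tp + half, hi) + 1e-12)
            return trace.values[w].mean()

        expected = brute(s2, s2 + isi) / brute(s1, s2)
        assert ppr_from_dff(trace) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_first_response_rejected(self):
        t = np.arange(0, 0.3, 1e-3)
        trace = TraceSeries(t=t, values=np.zeros_like(t))
        with pytest.raises(ValueError):
            ppr_from_dff(trace, stim_times=[0.1, 0.15])


class TestPrFromTrials:
    @staticmethod
    def _table(s1, s2):
        return pd.DataFrame({"success1": list(s1), "success2": list(s2)})

    def test_counting_example(self):
        s1 = [1] * 12 + [0] * 14
        s2 = [1] * 20 + [0] * 6
        res = pr_from_trials(self._table(s1, s2))
        assert res.p1 == pytest.approx(12 / 26)
        assert res.p2 == pytest.approx(20 / 26)
        assert res.ppr == pytest.approx((20 / 26) / (12 / 26))

    def test_all_failures_ppr_undefined(self):
        with pytest.raises(PPRUndefinedError):
            pr_from_trials(self._table([0] * 20, [1] * 20))

    def test_trial_floor_enforced(self):
        table = self._table([1] * 14, [1] * 14)
        with pytest.raises(ValueError, match="15-trial"):
            pr_from_trials(table)
        assert pr_from_trials(table, min_trials=14).p1 == 1.0

    def test_exhaustive_counting_equality(self):
        """Estimator equals direct counting on every pulse-1 outcome sequence
        up to n = 12 (pulse 2 held at an alternating pattern)."""
        for n in range(1, 13):
            s2 = [k % 2 for k in range(n)]
            if sum(s2) == 0:
                s2[0] = 1
            for bits in range(1, 2**n):  # skip all-failure pulse 1 (PPR undefined)
                s1 = [(bits >> k) & 1 for k in range(n)]
                res = pr_from_trials(self._table(s1, s2), min_trials=1)
                assert res.p1 == sum(s1) / n
                assert res.p2 == sum(s2) / n
                assert res.ppr == (sum(s2) / n) / (sum(s1) / n)

    def test_joint_exhaustive_small_n(self):
        """Both pulses enumerated jointly for n = 4."""
        n = 4
        for o1 in itertools.product((0, 1), repeat=n):
            if sum(o1) == 0:
                continue
            for o2 in itertools.product((0, 1), repeat=n):
                res = pr_from_trials(self._table(o1, o2), min_trials=1)
                assert (res.p1, res.p2) == (sum(o1) / n, sum(o2) / n)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=15, max_size=60))
    def test_reorder_invariance(self, outcomes):
        s1 = [int(a) for a, _ in outcomes]
        s2 = [int(b) for _, b in outcomes]
        if sum(s1) == 0:
            s1[0] = 1
        table = self._table(s1, s2)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert pr_from_trials(table) == pr_from_trials(shuffled)


class TestDecayTime:
    def test_pure_exponential_self_consistency(self):
        trace, _ = gen_transient(tau=1.85, noise_sd=0.0)
        assert decay_time(trace, t0=0.4) == pytest.approx(1.85, rel=1e-3)

    def test_invariance_under_scale_and_offset(self):
        trace, _ = gen_transient(tau=1.13, noise_sd=0.0)
        tau0 = decay_time(trace, t0=0.4)
        shifted = TraceSeries(t=trace.t, values=3.7 * trace.values + 11.0)
        assert decay_time(shifted, t0=0.4) == pytest.approx(tau0, rel=1e-6)

    def test_fast_transient_with_noise(self):
        trace, _ = gen_transient(tau=0.0129, fs=1000.0, noise_sd=0.02,
                                 duration=0.6, onset=0.05, seed=3)
        assert decay_time(trace, t0=0.0) == pytest.approx(0.0129, rel=0.10)

    def test_biexponential_flagged_between_components(self):
        t = np.arange(0, 10, 1e-3)
        v = 0.6 * np.exp(-t / 0.5) + 0.4 * np.exp(-t / 3.0)
        fit = decay_time(TraceSeries(t=t, values=v), t0=0.0, full=True)
        assert 0.5 < fit.tau < 3.0
        mono, _ = gen_transient(tau=1.0, noise_sd=0.0)
        mono_fit = decay_time(mono, t0=0.4, full=True)
        assert fit.r_squared < mono_fit.r_squared  # goodness-of-fit flags the mismatch

    def test_efold_agrees_for_pure_exponential(self):
        trace, _ = gen_transient(tau=1.85, noise_sd=0.0)
        assert efold_time(trace, t0=0.4) == pytest.approx(1.85, rel=0.01)

    def test_non_decaying_rejected(self):
        t = np.arange(0, 1, 1e-3)
        with pytest.raises(ValueError):
            decay_time(TraceSeries(t=t, values=np.linspace(0, 1, t.size)), t0=0.0)


class TestSubtractResidual:
    def test_identity_and_zero(self):
        trace, _ = gen_transient(noise_sd=0.0)
        zeroed = subtract_residual(trace, trace)
        np.testing.assert_array_equal(zeroed.values, 0.0)
        untouched = subtract_residual(trace, TraceSeries(t=trace.t, values=np.zeros_like(trace.values)))
        np.testing.assert_array_equal(untouched.values, trace.values)

    def test_shifted_base_interpolates(self):
        t = np.arange(0, 1, 1e-3)
        total = TraceSeries(t=t, values=np.sin(2 * np.pi * t))
        shift = 4e-4  # within half a sample
        residual = TraceSeries(t=t + shift - 5e-4, values=np.sin(2 * np.pi * (t + shift - 5e-4)))
        out = subtract_residual(total, residual)
        expected = total.values - np.interp(t, residual.t, residual.values)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_non_overlapping_rejected(self):
        a = TraceSeries(t=np.arange(0, 1, 1e-2), values=np.zeros(100))
        b = TraceSeries(t=np.arange(5, 6, 1e-2), values=np.zeros(100))
        with pytest.raises(ValueError):
            subtract_residual(a, b)
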