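"""Normalization, response magnitude, recovery half-time, aggregation, Hill shift."""

import numpy as np
import pandas as pd
import pytest

from wormlearn import calcium, synth
from wormlearn.types import FluorTrace, StimulusProtocol, ValidationError

from conftest import exp_recovery_trace


def _trace(f, fs=10.0, norm_state="raw"):
    f = np.asarray(f, float)
    return FluorTrace(t=np.arange(len(f)) / fs, f=f, animal_id="t", norm_state=norm_state)


class TestNormalizeDff0:
    def test_constant_trace_becomes_one(self):
        tr = _trace(np.full(100, 3.7))
        out = calcium.normalize_dff0(tr, baseline_t=5.0)
        np.testing.assert_allclose(out.f, 1.0)
        assert out.norm_state == "dff0"

    def test_scalar_scale_invariance(self):
        tr = _trace(np.linspace(1, 2, 100))
        doubled = _trace(2 * np.linspace(1, 2, 100))
        a = calcium.normalize_dff0(tr, 5.0)
        b = calcium.normalize_dff0(doubled, 5.0)
        np.testing.assert_allclose(a.f, b.f, rtol=1e-12)

    def test_baseline_outside_span_rejected(self):
        with pytest.raises(ValidationError):
            calcium.normalize_dff0(_trace(np.ones(10)), baseline_t=100.0)

    def test_renormalization_refused(self):
        tr = calcium.normalize_dff0(_trace(np.ones(50)), 1.0)
        with pytest.raises(ValidationError):
            calcium.normalize_dff0(tr, 1.0)


class TestNormalizeDffmax:
    def test_tail_means_define_scale(self):
        """Samples 0..99 with 5% tails: lo = mean{0..4} = 2, hi = mean{95..99} = 97."""
        tr = _trace(np.arange(100.0))
        out = calcium.normalize_dffmax(tr, tail_frac=0.05)
        k = np.flatnonzero(np.isclose(tr.f, 2.0))[0]
        assert out.f[k] == pytest.approx(0.0)
        assert out.f[97] == pytest.approx(1.0)
        assert out.norm_state == "dffmax"

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=200)
        a = calcium.normalize_dffmax(_trace(f))
        b = calcium.normalize_dffmax(_trace(3.2 * f + 7.0))
        np.testing.assert_allclose(a.f, b.f, rtol=1e-9, atol=1e-12)

    def test_constant_trace_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            calcium.normalize_dffmax(_trace(np.ones(100)))

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            calcium.normalize_dffmax(_trace(np.arange(10.0)), tail_frac=0.05)


def _single_block_protocol(conc=1e-6):
    return StimulusProtocol(intervals=[(30.0, 60.0, conc)], kind="odor")


class TestResponseMagnitude:
    def test_step_suppression(self):
        """f = 1 pre-pulse, 0.4 during the pulse -> magnitude 0.6."""
        protocol = _single_block_protocol()
        t = np.arange(0.0, 90.0, 0.1)
        f = np.where((t >= 30.0) & (t < 60.0), 0.4, 1.0)
        tr = FluorTrace(t=t, f=f, norm_state="dffmax")
        assert calcium.response_magnitude(tr, protocol, 1e-6) == pytest.approx(0.6)

    def test_flat_trace_zero(self):
        protocol = _single_block_protocol()
        t = np.arange(0.0, 90.0, 0.1)
        tr = FluorTrace(t=t, f=np.full_like(t, 0.8), norm_state="dffmax")
        assert calcium.response_magnitude(tr, protocol, 1e-6) == pytest.approx(0.0)

    def test_late_developing_suppression_uses_last_window(self):
        """Suppression reaching 0.3 only in the last 10 s: magnitude 0.7."""
        protocol = _single_block_protocol()
        t = np.arange(0.0, 90.0, 0.1)
        f = np.ones_like(t)
        f[(t >= 30.0) & (t < 50.0)] = 0.8
        f[(t >= 50.0) & (t < 60.0)] = 0.3
        tr = FluorTrace(t=t, f=f, norm_state="dffmax")
        assert calcium.response_magnitude(tr, protocol, 1e-6) == pytest.approx(0.7)

    def test_window_outside_trace_rejected(self):
        protocol = StimulusProtocol(intervals=[(1.0, 31.0, 1e-6)], kind="odor")
        t = np.arange(0.0, 60.0, 0.1)
        tr = FluorTrace(t=t, f=np.ones_like(t), norm_state="dffmax")
        with pytest.raises(ValidationError):
            calcium.response_magnitude(tr, protocol, 1e-6)

    def test_raw_trace_rejected(self):
        protocol = _single_block_protocol()
        t = np.arange(0.0, 90.0, 0.1)
        with pytest.raises(ValidationError, match="normalized"):
            calcium.response_magnitude(FluorTrace(t=t, f=np.ones_like(t)), protocol, 1e-6)


class TestRecoveryHalfTime:
    @pytest.mark.parametrize("fs", [2.0, 10.0, 50.0])
    @pytest.mark.parametrize("tau", [8.0, 20.0])
    def test_exponential_recovery_equals_tau_ln2(self, fs, tau):
        tr = exp_recovery_trace(fs=fs, tau=tau)
        protocol = _single_block_protocol()
        ht = calcium.recovery_half_time(tr, protocol, 1e-6)
        assert ht.kind == "value"
        assert abs(ht.value - tau * np.log(2)) <= 1.0 / fs + 1e-12

    def test_subthreshold_magnitude_not_computed(self):
        tr = exp_recovery_trace(fs=10.0, tau=10.0, depth=0.05)
        ht = calcium.recovery_half_time(tr, _single_block_protocol(), 1e-6, threshold=0.075)
        assert ht.kind == "not_computed" and ht.value is None

    def test_no_recovery_within_window_is_lower_bound(self):
        tr = exp_recovery_trace(fs=10.0, tau=1e6, t_end=300.0)
        ht = calcium.recovery_half_time(tr, _single_block_protocol(), 1e-6)
        assert ht.kind == "lower_bound"
        assert ht.value == pytest.approx(300.0 - 60.0, abs=0.2)


class TestAggregation:
    @staticmethod
    def _metric(mag, responded, ht=None):
        return calcium.PulseMetrics(
            concentration=1e-6, response_magnitude=mag, responded=responded,
            half_time=ht, animal_id="x",
        )

    def test_minority_responders_suppress_half_time_average(self):
        ms = [self._metric(0.2, True, calcium.HalfTime(5.0, "value")) for _ in range(3)]
        ms += [self._metric(0.01, False) for _ in range(7)]
        row = calcium.aggregate_block(ms)
        assert row["suppressed"] is True
        assert np.isnan(row["mean_half_time"])
        assert row["responder_frac"] == pytest.approx(0.3)

    def test_full_response_keeps_both_averages(self):
        ms = [self._metric(0.5, True, calcium.HalfTime(4.0 + k, "value")) for k in range(10)]
        row = calcium.aggregate_block(ms)
        assert row["mean_half_time"] == pytest.approx(np.mean([4.0 + k for k in range(10)]))
        assert row["half_time_lower_bound"] is False

    def test_mixed_lower_bounds_flag_the_mean(self):
        ms = [self._metric(0.5, True, calcium.HalfTime(4.0, "value")) for _ in range(5)]
        ms += [self._metric(0.5, True, calcium.HalfTime(90.0, "lower_bound")) for _ in range(5)]
        row = calcium.aggregate_block(ms)
        assert row["half_time_lower_bound"] is True

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            calcium.aggregate_block([])

    def test_half_time_on_nonresponder_rejected(self):
        with pytest.raises(ValidationError):
            self._metric(0.01, False, calcium.HalfTime(4.0, "value"))


class TestDoseResponseTable:
    def test_noiseless_cohort_monotone_magnitude(self, odor_protocol, noiseless_params):
        traces = [synth.simulate_awc_trace(noiseless_params, odor_protocol)]
        summary, per = calcium.dose_response_table(traces, odor_protocol)
        mags = summary.sort_values("concentration")["mean_magnitude"].to_numpy()
        assert np.all(np.diff(mags) >= -1e-9)
        assert len(summary) == 6 and per["animal_id"].nunique() == 1

    def test_empty_cohort_rejected(self, odor_protocol):
        with pytest.raises(ValidationError):
            calcium.dose_response_table([], odor_protocol)


class TestPerConcentrationWelch:
    def test_identical_groups_t_zero(self):
        df = pd.DataFrame(
            {"concentration": [1e-6] * 4, "response_magnitude": [0.1, 0.2, 0.3, 0.4]}
        )
        out = calcium.per_concentration_welch(df, df.copy())
        assert out.loc[0, "t"] == pytest.approx(0.0)

    def test_insufficient_n_omitted_with_reason(self):
        a = pd.DataFrame({"concentration": [1e-6], "response_magnitude": [0.1]})
        b = pd.DataFrame({"concentration": [1e-6] * 3, "response_magnitude": [0.1, 0.2, 0.3]})
        out = calcium.per_concentration_welch(a, b)
        assert "insufficient" in out.loc[0, "omitted_reason"]

    def test_three_vs_three_brute_force(self):
        a = pd.DataFrame({"concentration": [1e-6] * 3, "response_magnitude": [0.30, 0.35, 0.25]})
        b = pd.DataFrame({"concentration": [1e-6] * 3, "response_magnitude": [0.10, 0.05, 0.12]})
        out = calcium.per_concentration_welch(a, b)
        ya, yb = a["response_magnitude"], b["response_magnitude"]
        se2 = ya.var() / 3 + yb.var() / 3
        t = (ya.mean() - yb.mean()) / np.sqrt(se2)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)


class TestDynamicRangeShift:
    def test_identical_cohorts_unit_ratios(self, odor_protocol):
        params = synth.AwcModelParams(noise_sd=0.0)
        tr = synth.simulate_awc_trace(params, odor_protocol)
        summary, _ = calcium.dose_response_table([tr], odor_protocol)
        shift = calcium.dynamic_range_shift(summary, summary.copy())
        assert shift.detection_threshold_fold == pytest.approx(1.0)
        assert shift.saturation_fold == pytest.approx(1.0)
        assert shift.ec50_fold == pytest.approx(1.0, rel=1e-6)

    def test_tau_only_change_leaves_ec50_ratio_near_one(self, odor_protocol):
        """shift_fold=1 with altered recovery: EC50 ratio ~1, half-times differ."""
        params = synth.AwcModelParams(
            noise_sd=0.0, shift_fold=1.0, tau_rec_conditioned_scale=0.4,
        )
        naive = synth.simulate_awc_trace(params, odor_protocol, conditioned=False)
        cond = synth.simulate_awc_trace(params, odor_protocol, conditioned=True)
        ns, _ = calcium.dose_response_table([naive], odor_protocol)
        cs, _ = calcium.dose_response_table([cond], odor_protocol)
        shift = calcium.dynamic_range_shift(ns, cs)
        assert shift.ec50_fold == pytest.approx(1.0, rel=0.1)
        both = (ns["n_half_time"] > 0) & (cs["n_half_time"] > 0)
        assert (cs.loc[both, "mean_half_time"] < ns.loc[both, "mean_half_time"]).all()

    def test_too_few_concentrations_rejected(self):
        small = pd.DataFrame({"concentration": [1e-8, 1e-7], "mean_magnitude": [0.1, 0.5]})
        with pytest.raises(ValidationError):
            calcium.dynamic_range_shift(small, small)
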