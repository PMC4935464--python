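"""Generator correctness: protocol structure, model ground truth, reproducibility."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormlearn import synth
from wormlearn.reversals import analyze_pulses
from wormlearn.types import ValidationError


class TestOdorProtocol:
    def test_six_blocks_of_three_pulses(self, odor_protocol):
        assert len(odor_protocol.intervals) == 18
        assert len(odor_protocol.concentrations) == 6
        np.testing.assert_allclose(
            odor_protocol.concentrations, [11e-9 * 10**k for k in range(6)]
        )
        for c in odor_protocol.concentrations:
            assert len(odor_protocol.intervals_at(c)) == 3

    def test_within_block_onsets_spaced_twice_pulse(self, odor_protocol):
        for c in odor_protocol.concentrations:
            onsets = [a for a, _ in odor_protocol.intervals_at(c)]
            np.testing.assert_allclose(np.diff(onsets), 60.0)

    def test_single_concentration_single_pulse(self):
        p = synth.make_odor_protocol([1e-6], n_pulses_per_conc=1)
        assert p.intervals == [(30.0, 60.0, 1e-6)]

    def test_empty_and_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            synth.make_odor_protocol([])
        with pytest.raises(ValidationError):
            synth.make_odor_protocol([1e-6, 1e-7])


class TestLightSchedule:
    def test_default_ten_pulses_every_two_minutes(self, light_schedule):
        onsets = light_schedule.onsets()
        np.testing.assert_allclose(onsets, np.arange(10) * 120.0)
        np.testing.assert_allclose(light_schedule.offsets() - onsets, 20.0)

    def test_single_pulse(self):
        assert synth.make_light_schedule(n_pulses=1).intervals == [(0.0, 20.0, 1.0)]

    def test_period_equal_pulse_rejected(self):
        with pytest.raises(ValidationError):
            synth.make_light_schedule(pulse_s=20, period_s=20)


class TestAwcTrace:
    def test_hill_midpoint_gives_half_maximal_depth(self):
        """At c = EC50_eff the steady-state suppression is d_max/2."""
        params = synth.AwcModelParams(noise_sd=0.0, overshoot_amp=0.0)
        protocol = synth.make_odor_protocol([params.ec50], pulse_s=60.0, n_pulses_per_conc=1)
        tr = synth.simulate_awc_trace(params, protocol, conditioned=False)
        on, off = protocol.intervals_at(params.ec50)[0]
        late = tr.f[(tr.t >= off - 5) & (tr.t < off)]
        np.testing.assert_allclose(late, 1.0 - params.d_max / 2, atol=1e-6)

    def test_conditioned_midpoint_shifts_with_ec50(self):
        params = synth.AwcModelParams(noise_sd=0.0, overshoot_amp=0.0, shift_fold=10.0)
        c = params.ec50 * 10.0
        protocol = synth.make_odor_protocol([c], pulse_s=60.0, n_pulses_per_conc=1)
        tr = synth.simulate_awc_trace(params, protocol, conditioned=True)
        on, off = protocol.intervals_at(c)[0]
        late = tr.f[(tr.t >= off - 5) & (tr.t < off)]
        np.testing.assert_allclose(late, 1.0 - params.d_max / 2, atol=1e-6)

    def test_no_odor_gives_constant_baseline(self):
        from wormlearn.types import StimulusProtocol

        params = synth.AwcModelParams(noise_sd=0.0)
        protocol = StimulusProtocol(intervals=[], kind="odor")
        tr = synth.simulate_awc_trace(params, protocol, post_s=120.0)
        np.testing.assert_array_equal(tr.f, params.f0)

    def test_bit_reproducible_given_seed(self, odor_protocol):
        params = synth.AwcModelParams(seed=7)
        a = synth.simulate_awc_trace(params, odor_protocol)
        b = synth.simulate_awc_trace(params, odor_protocol)
        np.testing.assert_array_equal(a.f, b.f)

    def test_dose_monotone_without_noise(self, noiseless_trace, odor_protocol):
        """Steady suppression depth is non-decreasing in concentration."""
        depths = []
        for c in odor_protocol.concentrations:
            on, off = odor_protocol.intervals_at(c)[0]
            depths.append(1.0 - noiseless_trace.f[(noiseless_trace.t >= off - 5) & (noiseless_trace.t < off)].mean())
        assert np.all(np.diff(depths) >= -1e-9)

    def test_conditioning_changes_nothing_when_scales_are_unity(self, odor_protocol):
        params = synth.AwcModelParams(
            noise_sd=0.0, shift_fold=1.0,
            tau_rec_conditioned_scale=1.0, overshoot_conditioned_scale=1.0,
        )
        a = synth.simulate_awc_trace(params, odor_protocol, conditioned=False)
        b = synth.simulate_awc_trace(params, odor_protocol, conditioned=True)
        np.testing.assert_array_equal(a.f, b.f)

    def test_invalid_sampling_rate(self, odor_protocol):
        with pytest.raises(ValidationError):
            synth.simulate_awc_trace(synth.AwcModelParams(), odor_protocol, fs=0.0)

    def test_oscillations_appear_only_after_removal(self):
        base = synth.AwcModelParams(noise_sd=0.0, osc_amp=0.0)
        osc = synth.AwcModelParams(noise_sd=0.0, osc_amp=0.2)
        protocol = synth.make_odor_protocol([1e-5], n_pulses_per_conc=1)
        a = synth.simulate_awc_trace(base, protocol)
        b = synth.simulate_awc_trace(osc, protocol)
        on, off = protocol.intervals[0][:2]
        pre = b.t < on
        post = b.t >= off
        np.testing.assert_array_equal(a.f[pre], b.f[pre])
        assert np.max(np.abs(a.f[post] - b.f[post])) > 0.05


class TestCellImage:
    def test_target_exact_without_noise(self):
        img = synth.simulate_cell_image(2.0, size=64, noise_sd=0.0)
        fn = img.pixels.ravel()[img.nucleus_roi].mean()
        fc = img.pixels.ravel()[img.cytoplasm_roi].mean()
        assert fn / fc == pytest.approx(2.0, abs=1e-12)

    def test_target_one_means_indistinguishable(self):
        img = synth.simulate_cell_image(1.0, size=64, noise_sd=0.0)
        fn = img.pixels.ravel()[img.nucleus_roi].mean()
        fc = img.pixels.ravel()[img.cytoplasm_roi].mean()
        assert fn == pytest.approx(fc)

    def test_noisy_index_unbiased_over_seeds(self):
        """Measured index within 3 SE of target over 100 seeds."""
        target = 1.5
        vals = []
        for s in range(100):
            img = synth.simulate_cell_image(target, size=48, noise_sd=8.0, seed=s)
            px = img.pixels.ravel()
            vals.append(px[img.nucleus_roi].mean() / px[img.cytoplasm_roi].mean())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se + 1e-9

    def test_nucleus_exceeding_cell_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_cell_image(1.0, nucleus_radius_frac=0.5, cell_radius_frac=0.4)


class TestTracks:
    def test_no_base_rate_puts_all_events_in_light(self, light_schedule):
        params = synth.ReversalModelParams(r_base=0.0, r_stim=20.0, seed=1)
        tracks = synth.simulate_tracks(params, light_schedule, 10, 1200.0)
        for tr in tracks:
            for ev in tr.events:
                assert light_schedule.level_at(ev) > 0

    def test_during_minus_after_matches_dead_time_corrected_rate(self, light_schedule):
        """Poisson expectation over the 20-s windows, with the bout dead-time
        correction r_eff = r/(1 + r*E[bout]) for the thinned process."""
        params = synth.ReversalModelParams(
            r_base=2.0, r_stim=10.0, rev_duration_min=0.2, rev_duration_mean=0.5, seed=5
        )
        ebout = params.rev_duration_mean
        r_d = params.r_stim / 60.0
        r_a = params.r_base / 60.0
        expect = (r_d / (1 + r_d * ebout) - r_a / (1 + r_a * ebout)) * 20.0
        n_animals, n_seeds = 20, 12
        stats = []
        for s in range(n_seeds):
            p = synth.ReversalModelParams(**{**params.__dict__, "seed": s})
            tracks = synth.simulate_tracks(p, light_schedule, n_animals, 1200.0)
            summ = analyze_pulses([tr.events for tr in tracks], light_schedule)
            stats.append(summ.during_minus_after / n_animals)
        mean = np.mean(stats)
        sem = np.std(stats, ddof=1) / np.sqrt(n_seeds)
        assert abs(mean - expect) < max(4 * sem, 0.15 * expect)

    def test_homogeneous_rates_give_zero_mean_statistic(self, light_schedule):
        stats = []
        for s in range(40):
            params = synth.ReversalModelParams(r_base=4.0, r_stim=4.0, seed=s)
            tracks = synth.simulate_tracks(params, light_schedule, 10, 1200.0)
            summ = analyze_pulses([tr.events for tr in tracks], light_schedule)
            stats.append(summ.during_minus_after)
        sem = np.std(stats, ddof=1) / np.sqrt(len(stats))
        assert abs(np.mean(stats)) < 4 * sem + 1e-9

    def test_bit_reproducible(self, light_schedule):
        params = synth.ReversalModelParams(seed=3)
        a = synth.simulate_tracks(params, light_schedule, 3, 300.0)
        b = synth.simulate_tracks(params, light_schedule, 3, 300.0)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.events, tb.events)

    def test_requires_light_schedule(self, odor_protocol):
        with pytest.raises(ValidationError):
            synth.simulate_tracks(synth.ReversalModelParams(), odor_protocol, 1, 10.0)


class TestPlates:
    def test_certain_odor_side(self):
        p = synth.simulate_plate(1.0, 0.0, 0.0, 0.0, 200, seed=0)
        assert p.n_odor == 200

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_counts_always_sum_to_n(self, seed):
        p = synth.simulate_plate(0.4, 0.3, 0.2, 0.1, 150, seed=seed)
        assert p.n_total == 150

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            synth.simulate_plate(0.5, 0.5, 0.5, -0.5, 10)
        with pytest.raises(ValidationError):
            synth.simulate_plate(0.5, 0.1, 0.1, 0.1, 10)
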