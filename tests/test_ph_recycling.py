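"""Normalization, round segmentation, tau fitting, the EB statistic, and
rounds-to-block with censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endurance_lab as el
from endurance_lab import CalibrationError, FitError, FluorescenceTrace, RoundResponse, ValidationError
from endurance_lab.ph_recycling import (
    compute_eb,
    endurance_rounds,
    fit_decay_tau,
    normalize_to_peak,
    normalize_to_total_pool,
    segment_rounds,
)


def exponential_trace(tau=8.0, t_peak=5.0, peak=1.0, baseline=0.0, dt=0.1, t_end=60.0):
    t = np.arange(0.0, t_end, dt)
    v = np.where(t < t_peak, baseline, baseline + (peak - baseline) * np.exp(-(t - t_peak) / tau))
    return FluorescenceTrace(t, v)


class TestTotalPoolNormalization:
    def make_protocol(self):
        return el.endurance_protocol(rounds=1)

    def make_trace(self, proto, f0=10.0, plateau=110.0, peak=30.0):
        t = proto.time_axis()
        v = np.full(t.size, f0)
        a, b = proto.round_windows()[0]
        v[(t >= a) & (t < b + 2)] = peak
        na, nb = proto.nh4cl_epoch
        v[(t >= na) & (t < nb)] = plateau
        return FluorescenceTrace(t, v)

    def test_peak_maps_to_percent_of_pool(self):
        proto = self.make_protocol()
        norm = normalize_to_total_pool(self.make_trace(proto), proto)
        a, b = proto.round_windows()[0]
        assert norm.window(a, b).max() == pytest.approx(20.0)  # (30-10)/(110-10)

    def test_flat_trace_normalizes_to_zero(self):
        proto = self.make_protocol()
        trace = self.make_trace(proto, f0=10.0, plateau=110.0, peak=10.0)
        norm = normalize_to_total_pool(trace, proto)
        t = trace.time
        outside_nh4 = t < proto.nh4cl_epoch[0]
        assert np.allclose(norm.values[outside_nh4], 0.0)

    def test_calibration_failure_when_plateau_below_baseline(self):
        proto = self.make_protocol()
        with pytest.raises(CalibrationError):
            normalize_to_total_pool(self.make_trace(proto, f0=10.0, plateau=5.0), proto)

    def test_generator_pool_fraction_recovered(self, clean_params, neuron_factory):
        proto = el.default_protocol(clean_params, "endurance", rounds=3)
        _, trace, _ = neuron_factory(clean_params, proto, 0, capacity_override=1.0)
        norm = normalize_to_total_pool(trace, proto)
        first = segment_rounds(norm, proto)[0]
        assert first.peak_value == pytest.approx(15.0, abs=0.05)  # 0.15 pool fraction per round


class TestPeakNormalization:
    def test_peak_maps_to_one_and_tail_to_fraction(self):
        t = np.arange(0, 30, 0.5)
        v = np.interp(t, [0, 5, 10, 15, 30], [0, 0, 5, 2, 2])  # ramp to 5, decay to 2
        trace = FluorescenceTrace(t, v)
        out = normalize_to_peak(trace, t_stim_start=5.0, t_stim_end=10.0)
        assert out.values[np.argmax(v)] == pytest.approx(1.0)
        assert out.values[-1] == pytest.approx(0.4)

    @settings(max_examples=25)
    @given(gain=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, gain, offset):
        t = np.arange(0, 30, 0.5)
        v = np.interp(t, [0, 5, 10, 15, 30], [0, 0, 5, 2, 2])
        a = normalize_to_peak(FluorescenceTrace(t, v), 5.0, 10.0)
        b = normalize_to_peak(FluorescenceTrace(t, gain * v + offset), 5.0, 10.0)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_non_responding_segment_rejected(self):
        t = np.arange(0, 30, 0.5)
        trace = FluorescenceTrace(t, np.full(t.size, 3.0))
        with pytest.raises(ValidationError, match="non-responding"):
            normalize_to_peak(trace, 5.0, 10.0)


class TestSegmentation:
    def test_seventeen_declared_rounds_give_seventeen_segments(self, clean_params, neuron_factory):
        proto = el.default_protocol(clean_params, "endurance", rounds=17)
        _, trace, _ = neuron_factory(clean_params, proto, 0)
        assert len(segment_rounds(trace, proto)) == 17

    def test_single_round_peak_location(self):
        proto = el.endurance_protocol(rounds=1)
        t = proto.time_axis()
        v = np.zeros(t.size)
        a, b = proto.round_windows()[0]
        i = np.argmin(np.abs(t - (b - 0.5)))
        v[i] = 4.2
        seg = segment_rounds(FluorescenceTrace(t, v), proto)
        assert seg[0].peak_value == pytest.approx(4.2)
        assert seg[0].t_peak == pytest.approx(t[i])

    def test_noise_off_peaks_match_surface_recurrence_oracle(self, clean_params, neuron_factory):
        proto = el.default_protocol(clean_params, "endurance", rounds=4)
        _, trace, _ = neuron_factory(clean_params, proto, 0, capacity_override=1.0)
        norm = normalize_to_total_pool(trace, proto)
        segs = segment_rounds(norm, proto)
        # oracle: surface fraction recurrence with full retrieval between rounds
        tau, frac = clean_params.endocytosis_tau, clean_params.exo_pool_fraction_per_round
        windows = [proto.reference_window()] + proto.round_windows()
        s = 0.0
        expected = []
        for k in range(1, len(windows)):
            s *= np.exp(-(windows[k][0] - windows[k - 1][1]) / tau)
            s_peak = s + frac * (1.0 - s)
            expected.append(100.0 * s_peak)
            s = s_peak
        for seg, exp in zip(segs, expected):
            assert seg.peak_value == pytest.approx(exp, abs=0.2)

    def test_rounds_beyond_trace_rejected(self, clean_params, neuron_factory):
        proto = el.default_protocol(clean_params, "endurance", rounds=3)
        _, trace, _ = neuron_factory(clean_params, proto, 0)
        longer = el.default_protocol(clean_params, "endurance", rounds=10)
        with pytest.raises(ValidationError):
            segment_rounds(trace, longer)


class TestTauFit:
    def test_noiseless_exponential_recovered(self):
        fit = fit_decay_tau(exponential_trace(tau=8.0), t_peak=5.0)
        assert fit.tau == pytest.approx(8.0, rel=1e-6)
        assert fit.converged and fit.resid_norm < 1e-10

    def test_constant_segment_rejected(self):
        t = np.arange(0, 30, 0.5)
        with pytest.raises(FitError, match="flat"):
            fit_decay_tau(FluorescenceTrace(t, np.ones(t.size)), t_peak=5.0)

    def test_too_few_points_rejected(self):
        trace = exponential_trace()
        with pytest.raises(FitError, match="few"):
            fit_decay_tau(trace, t_peak=59.7)

    def test_noisy_median_within_ten_percent(self):
        # 5% of peak additive noise, 100 seeds
        taus = []
        t = np.arange(0.0, 45.0, 0.25)
        clean = np.exp(-np.maximum(t - 5.0, 0.0) / 8.0)
        for s in range(100):
            rng = np.random.default_rng(s)
            noisy = clean + rng.normal(0, 0.05, t.size)
            taus.append(fit_decay_tau(FluorescenceTrace(t, noisy), t_peak=5.0).tau)
        assert abs(np.median(taus) - 8.0) / 8.0 < 0.10


class TestEb:
    def test_perfect_exponential_gives_e_minus_3(self):
        trace = exponential_trace(tau=8.0)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        eb = compute_eb(trace, rr, tau_ref=8.0)
        assert eb == pytest.approx(100.0 * np.exp(-3.0), abs=0.05)

    def test_no_decay_gives_100(self):
        t = np.arange(0, 60, 0.5)
        v = np.where(t >= 5.0, 1.0, 0.0)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        assert compute_eb(FluorescenceTrace(t, v), rr, 8.0) == pytest.approx(100.0)

    def test_fast_complete_decay_gives_zero(self):
        trace = exponential_trace(tau=1.0)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        assert compute_eb(trace, rr, tau_ref=8.0) == pytest.approx(0.0, abs=0.01)

    def test_probe_beyond_trace_rejected(self):
        trace = exponential_trace(t_end=20.0)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        with pytest.raises(ValidationError, match="beyond"):
            compute_eb(trace, rr, tau_ref=8.0)

    def test_post_stimulus_rise_clamped_with_warning(self):
        t = np.arange(0, 60, 0.5)
        v = np.where(t >= 5.0, 1.0, 0.0) + np.where(t >= 20.0, 0.5, 0.0)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        with pytest.warns(UserWarning, match="clamped"):
            eb = compute_eb(FluorescenceTrace(t, v), rr, 8.0)
        assert eb == 100.0

    @settings(max_examples=25)
    @given(gain=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
    def test_affine_invariance_of_eb(self, gain, offset):
        trace = exponential_trace(tau=8.0)
        transformed = FluorescenceTrace(trace.time, gain * trace.values + offset)
        rr = RoundResponse(1, 4.5, 5.0, 1.0, 5.0, 0.0)
        rr_t = RoundResponse(1, 4.5, 5.0, gain * 1.0 + offset, 5.0, offset)
        assert compute_eb(transformed, rr_t, 8.0) == pytest.approx(compute_eb(trace, rr, 8.0), abs=1e-9)

    def test_monotone_in_capacity(self, clean_params):
        proto = el.default_protocol(clean_params, "endurance", rounds=1)
        st_ = el.simulate_terminal_state(clean_params, proto, 0)
        ebs = []
        for cap in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            trace, _ = el.simulate_ph_trace(clean_params, proto, st_, 0, capacity_override=cap)
            norm = normalize_to_total_pool(trace, proto)
            rnd = segment_rounds(norm, proto)[0]
            ebs.append(compute_eb(norm, rnd, clean_params.endocytosis_tau))
        assert all(a >= b - 1e-9 for a, b in zip(ebs, ebs[1:]))


class TestEndurance:
    def test_first_crossing_is_reported(self):
        res = endurance_rounds([5, 6, 8, 20, 55, 70, 90])
        assert res.rounds_to_block == 5 and not res.censored

    def test_never_crossing_is_censored_at_max_rounds(self):
        res = endurance_rounds([10.0] * 30, threshold=50, max_rounds=30)
        assert res.rounds_to_block == 30 and res.censored

    def test_immediate_block(self):
        assert endurance_rounds([60.0]).rounds_to_block == 1

    def test_threshold_comparison_is_strict(self):
        res = endurance_rounds([50.0] * 5, threshold=50, max_rounds=30)
        assert res.censored  # EB exactly at threshold does not count as block

    def test_out_of_range_eb_rejected(self):
        with pytest.raises(ValidationError):
            endurance_rounds([5.0, 120.0])
        with pytest.raises(ValidationError):
            endurance_rounds([])
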