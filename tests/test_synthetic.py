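"""The generators must be deterministic, bounded, and reduce to closed forms
with noise off; presets must encode the experimental manipulations."""

import numpy as np
import pytest

import endurance_lab as el
from endurance_lab import PRESET_NAMES, StimulusProtocol, ValidationError
from endurance_lab.synth import simulate_if_image, SULPIRIDE_SCALE, TH_FACTOR_DEFAULT
from endurance_lab.if_quant import quantify_cells


class TestPresets:
    def test_all_presets_load(self):
        for name in PRESET_NAMES:
            assert el.condition_presets(name).endocytosis_tau > 0

    def test_unknown_preset_lists_choices(self):
        with pytest.raises(ValidationError) as err:
            el.condition_presets("da_42")
        for name in PRESET_NAMES:
            assert name in str(err.value)

    def test_gp_knockdown_halves_gp_activity_only(self):
        base = el.condition_presets("da_0gluc")
        kd = el.condition_presets("da_gpkd")
        assert kd.gp_activity == pytest.approx(base.gp_activity / 2)
        assert kd.replace(gp_activity=base.gp_activity) == base

    def test_gpi_is_full_block(self):
        base = el.condition_presets("da_0gluc")
        gpi = el.condition_presets("da_gpi")
        assert gpi.gp_activity == 0.0
        assert gpi.replace(gp_activity=base.gp_activity) == base

    def test_sulpiride_halves_effective_store(self):
        base = el.condition_presets("da_0gluc")
        sul = el.condition_presets("da_sulpiride")
        assert sul.d2r_tone == pytest.approx(0.546)
        assert sul.glycogen_store_0 == base.glycogen_store_0
        effective = sul.glycogen_store_0 * sul.d2r_tone
        assert effective == pytest.approx(0.546 * base.glycogen_store_0 * base.d2r_tone)


class TestTerminalState:
    def test_deterministic(self, clean_params, short_endurance_protocol):
        a = el.simulate_terminal_state(clean_params, short_endurance_protocol, 7)
        b = el.simulate_terminal_state(clean_params, short_endurance_protocol, 7)
        assert np.array_equal(a.atp, b.atp) and np.array_equal(a.glycogen, b.glycogen)

    @pytest.mark.parametrize("preset", PRESET_NAMES)
    def test_bounded_and_glycogen_non_increasing(self, preset):
        params = el.condition_presets(preset)
        proto = el.default_protocol(params, "endurance", rounds=8)
        st = el.simulate_terminal_state(params, proto, 3)
        assert np.all((st.atp >= 0) & (st.atp <= 1))
        assert np.all((st.glycogen >= 0) & (st.glycogen <= 1))
        assert np.all(np.diff(st.glycogen) <= 1e-12)

    def test_steady_state_in_5mM_glucose_without_stimulation(self, clean_params):
        proto = StimulusProtocol(
            rounds=1, first_round_start_s=100.0, glucose_timeline=((0.0, 5.0),), duration_s=120.0
        )
        st = el.simulate_terminal_state(clean_params, proto, 0)
        pre = st.atp[st.time < 100.0]
        assert np.all(pre == 1.0)

    def test_no_production_path_is_non_increasing(self, clean_params):
        params = clean_params.replace(glycogen_store_0=0.0)
        proto = el.atp_long_train_protocol(glucose_mM=0.0)
        st = el.simulate_terminal_state(params, proto, 0)
        a, b = proto.long_train_window()
        train = (st.time >= a) & (st.time <= b)
        assert np.all(np.diff(st.atp[train]) <= 1e-15)
        assert st.atp[-1] < 0.7  # 600 APs without fuel cost a large ATP fraction

    def test_glycogen_reserve_raises_minimum_atp(self, clean_params):
        proto = el.atp_long_train_protocol(glucose_mM=0.0)
        with_store = el.simulate_terminal_state(clean_params.replace(glycogen_store_0=0.8), proto, 5)
        without = el.simulate_terminal_state(clean_params.replace(glycogen_store_0=0.0), proto, 5)
        assert with_store.atp.min() > without.atp.min()


class TestPhTrace:
    def test_bit_identical_for_same_seed(self, quiet_params, short_endurance_protocol):
        st = el.simulate_terminal_state(quiet_params, short_endurance_protocol, 1)
        t1, _ = el.simulate_ph_trace(quiet_params, short_endurance_protocol, st, 42)
        t2, _ = el.simulate_ph_trace(quiet_params, short_endurance_protocol, st, 42)
        assert np.array_equal(t1.values, t2.values)

    def test_full_capacity_decay_reaches_e_minus_3_at_3tau(self, clean_params, short_endurance_protocol):
        st = el.simulate_terminal_state(clean_params, short_endurance_protocol, 0)
        trace, _ = el.simulate_ph_trace(clean_params, short_endurance_protocol, st, 0, capacity_override=1.0)
        norm = el.normalize_to_total_pool(trace, short_endurance_protocol)
        for rnd in el.segment_rounds(norm, short_endurance_protocol):
            eb = el.compute_eb(norm, rnd, clean_params.endocytosis_tau)
            assert eb == pytest.approx(100.0 * np.exp(-3.0), abs=0.6)

    def test_zero_capacity_pins_signal_at_peak(self, clean_params, short_endurance_protocol):
        st = el.simulate_terminal_state(clean_params, short_endurance_protocol, 0)
        trace, _ = el.simulate_ph_trace(clean_params, short_endurance_protocol, st, 0, capacity_override=0.0)
        a, b = short_endurance_protocol.round_windows()[0]
        peak = trace.window(a, b + 2.0).max()
        after = trace.window(b + 2.0, a + 40.0)
        assert np.all(after >= peak - 1e-9)

    def test_state_span_mismatch_rejected(self, clean_params, short_endurance_protocol):
        st = el.simulate_terminal_state(clean_params, short_endurance_protocol, 0)
        other = el.default_protocol(clean_params, "endurance", rounds=3)
        with pytest.raises(ValidationError, match="cover"):
            el.simulate_ph_trace(clean_params, other, st, 0)


class TestAtpRatioTraces:
    def test_constant_atp_gives_constant_ratio(self, clean_params):
        # saturating glucose: uptake covers even the in-train demand, ATP stays at 1
        proto = el.atp_long_train_protocol(glucose_mM=25.0)
        params = clean_params.replace(glucose_mM=25.0)
        traces, _ = el.simulate_atp_ratio_traces(params, proto, n_rois=3, seed=0)
        ratio = el.compute_ratio(traces)
        for roi in ratio.rois:
            v = ratio.values(roi, "ratio")
            assert np.allclose(v, v[0])

    def test_ratio_recovers_atp_shape(self, clean_params):
        proto = el.atp_long_train_protocol(glucose_mM=0.0)
        traces, gt = el.simulate_atp_ratio_traces(clean_params, proto, n_rois=5, seed=0)
        neuron = el.neuron_average_and_baseline(el.compute_ratio(traces), proto)
        expected = 100.0 * np.asarray(gt.extras["response_noise_free"])
        assert np.allclose(neuron.values, expected, rtol=1e-6)

    def test_default_roi_count_matches_practice(self, quiet_params):
        proto = el.atp_long_train_protocol()
        traces, _ = el.simulate_atp_ratio_traces(quiet_params, proto, seed=0)
        assert 40 <= len(traces.rois) <= 60

    def test_zero_rois_rejected(self, quiet_params):
        with pytest.raises(ValidationError):
            el.simulate_atp_ratio_traces(quiet_params, el.atp_long_train_protocol(), n_rois=0, seed=0)


class TestIfImage:
    def test_noise_off_glycogen_equals_gs(self):
        img, rois, _ = simulate_if_image(
            "da_0gluc", n_cells=8, seed=0, noise_off=True, slope_base=1.0, th_factor=1.0
        )
        rec = quantify_cells(img, rois)
        assert np.allclose(rec["glycogen"], rec["gs"], rtol=1e-5, atol=1e-3)

    def test_ground_truth_th_scaling(self):
        _, _, gt = simulate_if_image("da_0gluc", n_cells=10, seed=1)
        assert gt.extras["th_factor"] == pytest.approx(TH_FACTOR_DEFAULT)
        _, _, gt_sul = simulate_if_image("da_sulpiride", n_cells=10, seed=1)
        assert gt_sul.extras["th_factor"] == pytest.approx(TH_FACTOR_DEFAULT * SULPIRIDE_SCALE)
        assert SULPIRIDE_SCALE == pytest.approx(1.0 - 0.454, abs=1e-3)

    def test_guarantees_both_th_classes(self):
        _, rois, _ = simulate_if_image("da_0gluc", n_cells=2, seed=0)
        cells = rois[rois["kind"] == "signal"]
        assert set(cells["th_status"]) == {"positive", "negative"}

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            simulate_if_image("da_0gluc", n_cells=40, frame_shape=(32, 32), seed=0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValidationError):
            simulate_if_image("da_0gluc", n_cells=1, seed=0)

    def test_deterministic(self):
        a, _, _ = simulate_if_image("da_0gluc", n_cells=6, seed=9)
        b, _, _ = simulate_if_image("da_0gluc", n_cells=6, seed=9)
        assert np.array_equal(a, b)
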