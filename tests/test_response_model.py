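"""Trace-model analytics, dose–response, sampling, and preset anchors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfdyn.features import Trace, peak_features
from nfdyn.response_model import (
    DoseModel,
    HeterogeneityParams,
    PreparationPreset,
    PulseParams,
    ResponderClass,
    StnfrModifier,
    activation_probability,
    pulse_value,
    pulse_width_at_half_max,
    sample_cell,
    sample_population,
    solve_shape_for_width,
)


def dense_width_above(params: PulseParams, level: float, t_max=2000.0, dt=0.01):
    """Brute-force oracle: length of the region where the pulse exceeds level."""
    t = np.arange(0.0, t_max, dt)
    v = pulse_value(params, t)
    return float(np.count_nonzero(v > level) * dt)


class TestPulseValue:
    def test_maximum_at_tau(self):
        p = PulseParams(baseline=1, amplitude=1, time_to_peak=50, shape=4)
        assert pulse_value(p, 50.0) == pytest.approx(2.0, abs=1e-12)

    def test_onset_equals_baseline(self):
        p = PulseParams(baseline=1, amplitude=1, time_to_peak=50, shape=4)
        assert pulse_value(p, 0.0) == pytest.approx(1.0)
        assert pulse_value(p, -10.0) == pytest.approx(1.0)

    def test_width_above_level_matches_dense_oracle(self):
        p = PulseParams(baseline=1, amplitude=1, time_to_peak=50, shape=4)
        analytic = pulse_width_at_half_max(50, 4)  # level 1.5 = half max here
        assert dense_width_above(p, 1.5) == pytest.approx(analytic, abs=0.05)

    def test_rejects_nonfinite_time(self):
        p = PulseParams(baseline=1, amplitude=1, time_to_peak=50, shape=4)
        with pytest.raises(ValueError):
            pulse_value(p, np.nan)

    def test_continuous_at_secondary_onset(self):
        p = PulseParams(
            baseline=1, amplitude=1, time_to_peak=50, shape=4,
            secondary_amp=1.0, secondary_time=200.0, secondary_decay=60.0,
        )
        eps = 1e-6
        assert pulse_value(p, 200.0 + eps) == pytest.approx(
            pulse_value(p, 200.0 - eps), abs=1e-4
        )

    @settings(deadline=None, max_examples=50)
    @given(
        b=st.floats(0.2, 2.0),
        A=st.floats(0.1, 3.0),
        tau=st.floats(10.0, 200.0),
        s=st.floats(0.5, 30.0),
    )
    def test_peak_location_and_value_property(self, b, A, tau, s):
        """Dense-grid search confirms the pure pulse peaks at tau with b+A."""
        p = PulseParams(baseline=b, amplitude=A, time_to_peak=tau, shape=s)
        t = np.linspace(0, 5 * tau, 20001)
        v = pulse_value(p, t)
        i = np.argmax(v)
        assert abs(t[i] - tau) < 5 * tau / 20000 * 2
        assert v[i] == pytest.approx(b + A, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PulseParams(baseline=-1, amplitude=1, time_to_peak=50, shape=4)
        with pytest.raises(ValueError):
            PulseParams(baseline=1, amplitude=1, time_to_peak=0, shape=4)
        with pytest.raises(ValueError):
            PulseParams(
                baseline=1, amplitude=1, time_to_peak=50, shape=4,
                responder_class=ResponderClass.INACTIVE,
            )


class TestShapeSolver:
    @pytest.mark.parametrize("target", [30.0, 60.0, 120.0])
    def test_round_trip_against_dense_oracle(self, target):
        s = solve_shape_for_width(50.0, target)
        p = PulseParams(baseline=0, amplitude=1, time_to_peak=50, shape=s)
        measured = dense_width_above(p, 0.5)
        assert measured == pytest.approx(target, abs=0.1)

    def test_monotonicity_wider_means_flatter(self):
        widths = [20.0, 50.0, 100.0, 300.0]
        shapes = [solve_shape_for_width(50.0, w) for w in widths]
        assert all(a > b for a, b in zip(shapes, shapes[1:]))

    def test_bracketed_solution_exists(self):
        s = solve_shape_for_width(50.0, 50.0)
        assert s > 0
        assert pulse_width_at_half_max(50.0, s) == pytest.approx(50.0, abs=0.1)

    def test_unachievable_width_names_feasible_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            solve_shape_for_width(50.0, 0.01)


class TestDoseModel:
    def test_half_activation_at_K(self):
        d = DoseModel(pmax=0.8, K=0.1, h=1.5)
        assert activation_probability(d, 0.1) == pytest.approx(0.4)

    def test_zero_at_zero_concentration(self):
        d = DoseModel(pmax=0.8, K=0.1, h=1.5)
        assert activation_probability(d, 0.0) == 0.0

    def test_negative_concentration_rejected(self):
        d = DoseModel(pmax=0.8, K=0.1, h=1.5)
        with pytest.raises(ValueError):
            activation_probability(d, -1.0)

    def test_sigma_maximally_active_by_5e3(self, presets):
        d = presets["Sigma"].dose_model
        assert activation_probability(d, 5e-3) >= 0.9 * d.pmax

    def test_up_window_and_low_conc_inertness(self, presets):
        d = presets["UP"].dose_model
        assert activation_probability(d, 5.0) >= 0.9 * d.pmax
        assert activation_probability(d, 0.5) < 0.9 * d.pmax
        assert activation_probability(d, 5e-7) < 0.01

    def test_eb_active_at_lowest_concentration(self, presets):
        d = presets["EB"].dose_model
        assert activation_probability(d, 5e-7) >= 0.9 * d.pmax

    @settings(deadline=None, max_examples=50)
    @given(
        pmax=st.floats(0.1, 1.0),
        K=st.floats(1e-7, 10.0),
        h=st.floats(0.3, 4.0),
    )
    def test_monotone_nondecreasing_property(self, pmax, K, h):
        d = DoseModel(pmax=pmax, K=K, h=h)
        concs = np.logspace(-8, 2, 40)
        p = [activation_probability(d, c) for c in concs]
        assert all(b >= a - 1e-12 for a, b in zip(p, p[1:]))


def _single_class_preset(preset: PreparationPreset, cls: str, **het) -> PreparationPreset:
    from dataclasses import replace

    mix = {"transient": 0.0, "persistent": 0.0, "secondary": 0.0}
    mix[cls] = 1.0
    return replace(
        preset,
        heterogeneity=HeterogeneityParams(class_mix=mix, **het),
    )


class TestSampling:
    def test_zero_variance_recovers_central_params(self, presets):
        preset = _single_class_preset(
            presets["Sigma"], "transient",
            cv_amplitude=0.0, cv_time_to_peak=0.0, cv_baseline=0.0,
        )
        central = preset.central_pulse(0.5)
        cell = sample_cell(preset, 0.5, False, rng=1)
        assert cell.active
        assert cell.params.amplitude == pytest.approx(central.amplitude)
        assert cell.params.time_to_peak == pytest.approx(central.time_to_peak)
        assert cell.params.baseline == pytest.approx(central.baseline)

    def test_active_fraction_at_K_matches_binomial(self, presets):
        """10,000 draws at c = K: fraction within 3 binomial SEs of pmax/2."""
        preset = presets["Sigma"]
        K = preset.dose_model.K
        grid = np.array([-5.0, 0.0, 30.0, 60.0, 120.0])  # coarse grid for speed
        cells = sample_population(preset, K, False, 10_000, rng=7, time_grid=grid)
        frac = np.mean([c.active for c in cells])
        p = preset.dose_model.pmax / 2
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) <= 3 * se

    def test_stnfr_zero_factor_eliminates_persistent(self, presets):
        from dataclasses import replace

        preset = replace(
            presets["Sigma"],
            stnfr_modifier=StnfrModifier(persistent_prob_factor=0.0),
        )
        grid = np.array([-5.0, 0.0, 30.0, 60.0])
        cells = sample_population(preset, 0.5, True, 500, rng=3, time_grid=grid)
        assert all(c.responder_class is not ResponderClass.PERSISTENT for c in cells)

    def test_sampling_reproducible_bitwise(self, presets):
        a = sample_population(presets["UP"], 0.5, False, 20, rng=42)
        b = sample_population(presets["UP"], 0.5, False, 20, rng=42)
        for ca, cb in zip(a, b):
            assert ca.responder_class == cb.responder_class
            np.testing.assert_array_equal(ca.true_trace, cb.true_trace)

    def test_true_features_from_same_code_path(self, presets):
        cell = sample_cell(presets["UP"], 5.0, False, rng=5)
        if cell.active:
            trace = Trace(
                track_id=0,
                time=cell.time_grid,
                values=cell.true_trace,
                valid=np.ones_like(cell.true_trace, dtype=bool),
            )
            ref = peak_features(trace)
            assert cell.true_features.peak_amp == ref.peak_amp
            assert cell.true_features.time_to_peak == ref.time_to_peak


class TestPresetAnchors:
    """Central-parameter ratios measured on noiseless dense-grid traces."""

    @staticmethod
    def _central_features(preset, conc):
        params = preset.central_pulse(conc)
        t = np.arange(-15.0, 600.0, 0.5)
        trace = Trace(
            track_id=0,
            time=t,
            values=np.asarray(pulse_value(params, t)),
            valid=np.ones_like(t, dtype=bool),
        )
        return peak_features(trace)

    def test_amplitude_and_tau_ratios_at_half_microgram(self, presets):
        f = {name: self._central_features(presets[name], 0.5) for name in presets}
        amp = {k: v.peak_amp - v.baseline for k, v in f.items()}
        assert 1 - amp["EB"] / amp["Sigma"] == pytest.approx(0.51, abs=0.01)
        assert amp["UP"] / amp["Sigma"] == pytest.approx(1.17, abs=0.01)
        assert f["EB"].time_to_peak / f["Sigma"].time_to_peak == pytest.approx(3.0, rel=0.02)
        assert f["UP"].time_to_peak / f["Sigma"].time_to_peak == pytest.approx(1.45, rel=0.02)

    def test_width_ratio_sigma_vs_eb(self, presets):
        f_s = self._central_features(presets["Sigma"], 0.5)
        f_e = self._central_features(presets["EB"], 0.5)
        assert f_s.peak_width / f_e.peak_width == pytest.approx(1.475, rel=0.02)

    def test_up_time_to_peak_series(self, presets):
        taus = [
            self._central_features(presets["UP"], c).time_to_peak
            for c in (5.0, 0.5, 0.05)
        ]
        assert taus == pytest.approx([52.0, 69.0, 129.0], abs=1.0)
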