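"""Inverse pipeline: ramp splitting, baselines, θ, Tm, van't Hoff fits."""

import numpy as np
import pytest
from sklearn.base import clone

from quadmelt import thermo
from quadmelt.analysis import (
    MeltCurve,
    ThetaProfile,
    VantHoffAnalyzer,
    analyze_curve,
    fit_baselines,
    fraction_folded,
    hysteresis,
    melting_temperature,
    molecularity_test,
    split_ramps,
    transition_separation,
    vant_hoff_fit,
)
from quadmelt.exceptions import (
    AnalysisError,
    DegenerateBaselineError,
    NoTransitionError,
    ValidationError,
)
from quadmelt.simulate import SimSpec, simulate_concentration_series, simulate_curve
from quadmelt.thermo import Molecularity, ThermoParams, predicted_tm


def _protocol_trace(n=161):
    """Temperatures of a 90→10→90→10 °C protocol, time-ordered."""
    down = np.linspace(90, 10, n)
    up = np.linspace(10, 90, n)
    t = np.concatenate([down, up[1:], down[1:]])
    return t, np.linspace(0.4, 0.3, t.size)


class TestSplitRamps:
    def test_cool_heat_cool_protocol_gives_three_ramps(self):
        t, s = _protocol_trace()
        curves = split_ramps(t, s)
        assert [c.ramp_direction for c in curves] == ["cooling", "heating", "cooling"]
        assert [c.meta["ramp_index"] for c in curves] == [0, 1, 2]

    def test_single_heating_ramp(self):
        t = np.linspace(10, 90, 100)
        curves = split_ramps(t, np.zeros_like(t) + 0.3)
        assert len(curves) == 1
        assert curves[0].ramp_direction == "heating"

    def test_constant_temperature_rejected(self):
        with pytest.raises(AnalysisError):
            split_ramps(np.full(50, 25.0), np.zeros(50))

    def test_short_segment_discarded_with_warning(self):
        t = np.concatenate([np.linspace(10, 90, 100), np.linspace(89, 85, 5)])
        with pytest.warns(UserWarning, match="discarding"):
            curves = split_ramps(t, np.zeros_like(t))
        assert len(curves) == 1


def _curve_from_lines(lower, upper, theta, t):
    lo = lower[0] * t + lower[1]
    up = upper[0] * t + upper[1]
    return MeltCurve(t, theta * lo + (1 - theta) * up)


class TestBaselines:
    def test_exact_two_line_step_recovered(self):
        t = np.linspace(10, 90, 321)
        theta = (t < 50).astype(float)  # hard step between two lines
        curve = _curve_from_lines((0.001, 0.30), (-0.0005, 0.48), theta, t)
        fit = fit_baselines(curve)
        assert fit.lower == pytest.approx((0.001, 0.30), abs=1e-9)
        assert fit.upper == pytest.approx((-0.0005, 0.48), abs=1e-9)

    def test_simulated_baselines_recovered_within_2_percent(self):
        # unimolecular transition centred in the scan: both plateaus are
        # reached, so fixed windows see essentially pure baseline
        p = ThermoParams(-300.0, -300e3 / 323.15, Molecularity.UNIMOLECULAR)
        spec = SimSpec(
            params=p, ramp_pattern=("heating",),
            lower_baseline=(0.0005, 0.30), upper_baseline=(0.0003, 0.45),
        )
        fit = fit_baselines(simulate_curve(spec)[0])
        assert fit.lower[0] == pytest.approx(0.0005, rel=0.02)
        assert fit.upper[0] == pytest.approx(0.0003, rel=0.02)

    def test_constant_signal_gives_zero_slopes(self):
        t = np.linspace(10, 90, 100)
        fit = fit_baselines(MeltCurve(t, np.full_like(t, 0.42)))
        assert fit.lower[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.upper[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_window_rejected(self):
        t = np.linspace(10, 90, 30)
        curve = MeltCurve(t, np.linspace(0.3, 0.4, 30))
        with pytest.raises(ValidationError):
            fit_baselines(curve, windows=((10, 11), (80, 90)))

    def test_bad_window_fraction_rejected(self):
        t = np.linspace(10, 90, 30)
        with pytest.raises(ValidationError):
            fit_baselines(MeltCurve(t, np.zeros(30)), window_frac=0.5)


class TestFractionFolded:
    t = np.linspace(10, 90, 101)

    def _baselines(self):
        curve = _curve_from_lines((0.0, 0.3), (0.0, 0.5), (self.t < 50).astype(float), self.t)
        return fit_baselines(curve)

    def test_signal_on_folded_baseline_is_one(self):
        b = self._baselines()
        curve = MeltCurve(self.t, b.lower_at(self.t))
        assert fraction_folded(curve, b).theta == pytest.approx(1.0)

    def test_signal_on_unfolded_baseline_is_zero(self):
        b = self._baselines()
        curve = MeltCurve(self.t, b.upper_at(self.t))
        assert fraction_folded(curve, b).theta == pytest.approx(0.0)

    def test_midpoint_signal_is_half(self):
        b = self._baselines()
        curve = MeltCurve(self.t, 0.5 * (b.lower_at(self.t) + b.upper_at(self.t)))
        assert fraction_folded(curve, b).theta == pytest.approx(0.5)

    def test_affine_signal_rescaling_invariance(self, sloped_spec):
        from quadmelt.analysis import BaselineFit

        curve = simulate_curve(sloped_spec)[0]
        b = fit_baselines(curve)
        theta = fraction_folded(curve, b).theta
        gain, offset = 3.7, -0.2
        curve2 = MeltCurve(curve.temperature_c, gain * curve.signal + offset)
        b2 = BaselineFit(
            lower=(gain * b.lower[0], gain * b.lower[1] + offset),
            upper=(gain * b.upper[0], gain * b.upper[1] + offset),
            windows=b.windows,
        )
        assert fraction_folded(curve2, b2).theta == pytest.approx(theta, abs=1e-12)

    def test_coincident_baselines_rejected(self):
        b = fit_baselines(MeltCurve(self.t, np.full_like(self.t, 0.4)))
        with pytest.raises(DegenerateBaselineError):
            fraction_folded(MeltCurve(self.t, np.full_like(self.t, 0.4)), b)


class TestMeltingTemperature:
    def test_symmetric_sigmoid_midpoint(self):
        t = np.linspace(20, 70, 201)
        theta = 1.0 / (1.0 + np.exp((t - 45.0) / 3.0))
        assert melting_temperature(ThetaProfile(t, theta)) == pytest.approx(45.0, abs=1e-6)

    def test_model_curve_matches_closed_form(self, duplex_params):
        t = np.arange(10.0, 90.25, 0.25)
        theta = thermo.theta_from_params(duplex_params, thermo.to_kelvin(t))
        tm = melting_temperature(ThetaProfile(t, theta))
        tm_true = thermo.to_celsius(predicted_tm(duplex_params))
        assert tm == pytest.approx(tm_true, abs=0.1)

    def test_derivative_method_on_symmetric_profile(self):
        # for a symmetric sigmoid the dθ/dT extremum coincides with the
        # crossing (bimolecular transitions are skewed, so the two methods
        # legitimately differ there and both are reported)
        t = np.linspace(20, 70, 201)
        theta = 1.0 / (1.0 + np.exp((t - 45.0) / 3.0))
        tm_d = melting_temperature(ThetaProfile(t, theta), method="derivative")
        assert tm_d == pytest.approx(45.0, abs=0.1)

    def test_no_transition_raises(self):
        t = np.linspace(10, 90, 100)
        with pytest.raises(NoTransitionError):
            melting_temperature(ThetaProfile(t, np.full_like(t, 0.95)))

    def test_multiple_crossings_warns_first_used(self):
        t = np.linspace(0, 10, 200)
        theta = 0.5 + 0.4 * np.cos(t)  # oscillates through 0.5 repeatedly
        with pytest.warns(UserWarning, match="crossings"):
            tm = melting_temperature(ThetaProfile(t, theta), smooth_window=5)
        assert tm == pytest.approx(np.pi / 2, abs=0.1)


class TestVantHoffFit:
    def test_noise_free_round_trip_recovers_thermodynamics(self, sloped_spec):
        curve = simulate_curve(sloped_spec)[0]
        profile = fraction_folded(curve, fit_baselines(curve))
        fit = vant_hoff_fit(profile, "bimolecular_hetero", 6e-6)
        assert fit.params.delta_H == pytest.approx(-336.4, rel=0.01)
        assert fit.delta_G_std == pytest.approx(-67.5, abs=0.5)
        assert fit.r_squared > 0.999

    def test_exactly_linear_ln_k_gives_unit_r_squared(self, duplex_params):
        t = np.arange(35.0, 80.0, 0.25)
        theta = thermo.theta_from_params(duplex_params, thermo.to_kelvin(t))
        fit = vant_hoff_fit(ThetaProfile(t, theta), "bimolecular_hetero", 6e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_unimolecular_quadruplex_like_curve(self):
        p = ThermoParams(-200.0, -565.0, Molecularity.UNIMOLECULAR)
        tm_true_k = predicted_tm(p)
        assert tm_true_k == pytest.approx(354.0, abs=0.1)
        t = np.arange(40.0, 95.0, 0.25)
        theta = thermo.theta_from_params(p, thermo.to_kelvin(t))
        fit = vant_hoff_fit(ThetaProfile(t, theta), "unimolecular")
        assert fit.params.delta_H == pytest.approx(-200.0, rel=0.01)
        assert thermo.to_kelvin(fit.tm_obs_c) == pytest.approx(tm_true_k, abs=0.2)

    def test_too_few_in_window_points_raise(self):
        t = np.linspace(10, 90, 30)
        with pytest.raises(AnalysisError):
            vant_hoff_fit(
                ThetaProfile(t, np.full_like(t, 0.99)), "unimolecular"
            )


class TestVantHoffAnalyzer:
    def test_full_pipeline_round_trip(self, sloped_spec):
        curve = simulate_curve(sloped_spec)[0]
        an = VantHoffAnalyzer(molecularity="bimolecular_hetero", c_total=6e-6)
        an.fit(curve)
        assert an.delta_H_ == pytest.approx(-336.4, rel=0.001)
        assert an.delta_S_ == pytest.approx(-902.0, rel=0.001)
        assert an.tm_ == pytest.approx(58.77, abs=0.05)
        assert an.r_squared_ > 0.999

    def test_parameter_grid_round_trip(self, rng):
        # broad/sharp transitions across the instrument range
        for _ in range(12):
            dh = rng.uniform(-450.0, -150.0)
            tm_c = rng.uniform(35.0, 65.0)
            ds = dh * 1e3 / thermo.to_kelvin(tm_c) - thermo.R * np.log(6e-6 / 4)
            p = ThermoParams(dh, ds, "bimolecular_hetero", 6e-6)
            curve = simulate_curve(
                SimSpec(params=p, ramp_pattern=("heating",),
                        lower_baseline=(0.0005, 0.30),
                        upper_baseline=(0.0003, 0.45))
            )[0]
            an = VantHoffAnalyzer(molecularity="bimolecular_hetero", c_total=6e-6)
            an.fit(curve)
            assert an.delta_H_ == pytest.approx(dh, rel=0.01)
            assert an.delta_S_ == pytest.approx(ds, rel=0.01)
            assert an.tm_ == pytest.approx(tm_c, abs=0.2)

    def test_noisy_triplicates_mean_dg_within_1_kj(self, duplex_params):
        from quadmelt.compare import aggregate_replicates

        spec = SimSpec(
            params=duplex_params, ramp_pattern=("heating",),
            lower_baseline=(0.0005, 0.30), upper_baseline=(0.0003, 0.45),
            noise_sigma=0.002 * 0.15,  # 0.2% of the transition amplitude
            n_replicates=3, seed=11,
        )
        fits = [
            analyze_curve(c, molecularity="bimolecular_hetero", c_total=6e-6)
            for c in simulate_curve(spec)
        ]
        summary = aggregate_replicates(fits, pair="sim")
        truth = -67.4687
        assert abs(summary.delta_G.value - truth) < 1.0

    def test_predict_reproduces_noise_free_signal(self, sloped_spec):
        curve = simulate_curve(sloped_spec)[0]
        an = VantHoffAnalyzer(molecularity="bimolecular_hetero", c_total=6e-6).fit(curve)
        assert an.predict(curve.temperature_c) == pytest.approx(curve.signal, abs=1e-6)

    def test_sklearn_clone_and_params_round_trip(self):
        an = VantHoffAnalyzer(c_total=6e-6, theta_window=(0.2, 0.8), refine=False)
        cloned = clone(an)
        assert cloned.get_params() == an.get_params()
        cloned.set_params(smooth_window=15)
        assert cloned.smooth_window == 15 and an.smooth_window == 11

    def test_accepts_temperature_signal_arrays(self, sloped_spec):
        curve = simulate_curve(sloped_spec)[0]
        an = VantHoffAnalyzer(molecularity="bimolecular_hetero", c_total=6e-6)
        an.fit(curve.temperature_c, curve.signal)
        assert an.delta_H_ == pytest.approx(-336.4, rel=0.005)


class TestDiagnostics:
    def test_identical_curves_no_hysteresis(self, sloped_spec):
        curve = simulate_curve(sloped_spec)[0]
        fit = analyze_curve(curve, molecularity="bimolecular_hetero", c_total=6e-6)
        rep = hysteresis(fit, fit)
        assert rep.delta_tm_c == 0.0 and not rep.flagged

    def test_offset_pair_flagged(self, sloped_spec):
        from dataclasses import replace

        spec = replace(sloped_spec, ramp_pattern=("cooling", "heating"),
                       hysteresis_offset=2.0)
        cool, heat = simulate_curve(spec)
        fit_c = analyze_curve(cool, molecularity="bimolecular_hetero", c_total=6e-6)
        fit_h = analyze_curve(heat, molecularity="bimolecular_hetero", c_total=6e-6)
        rep = hysteresis(fit_h, fit_c)
        assert rep.delta_tm_c == pytest.approx(2.0, abs=0.1)
        assert rep.flagged

    def test_equilibrium_simulator_pair_not_flagged(self, sloped_spec):
        from dataclasses import replace

        spec = replace(sloped_spec, ramp_pattern=("cooling", "heating"))
        cool, heat = simulate_curve(spec)
        fit_c = analyze_curve(cool, molecularity="bimolecular_hetero", c_total=6e-6)
        fit_h = analyze_curve(heat, molecularity="bimolecular_hetero", c_total=6e-6)
        rep = hysteresis(fit_h, fit_c)
        assert rep.delta_tm_c < 0.1 and not rep.flagged

    @pytest.mark.parametrize(
        "tm_duplex,tm_quad,passed",
        [(58.6, 80.0, False), (51.4, 80.0, True), (60.0, 60.0, False)],
    )
    def test_transition_separation_threshold(self, tm_duplex, tm_quad, passed):
        rep = transition_separation(tm_duplex, tm_quad, min_sep=25.0)
        assert rep.passed is passed
        assert rep.separation_c == pytest.approx(abs(tm_quad - tm_duplex))


class TestMolecularityTest:
    def test_bimolecular_series_slope_matches_theory(self, duplex_params):
        series = simulate_concentration_series(
            duplex_params, [1.5e-6, 3e-6, 6e-6, 12e-6],
            lower_baseline=(0.0, 0.30), upper_baseline=(0.0, 0.45),
        )
        tm_series = []
        for c, curve in series:
            fit = analyze_curve(curve, molecularity="bimolecular_hetero", c_total=c)
            tm_series.append((c, thermo.to_kelvin(fit.tm_obs_c)))
        rep = molecularity_test(tm_series, delta_H=-336.4)
        expected = thermo.R / (-336.4e3)
        assert rep.slope == pytest.approx(expected, rel=0.05)
        assert rep.classification == "bimolecular"

    def test_constant_tm_classified_unimolecular(self):
        tm_series = [(1e-6, 354.0), (3e-6, 354.0), (1e-5, 354.0)]
        rep = molecularity_test(tm_series, delta_H=-200.0)
        assert rep.slope == pytest.approx(0.0, abs=1e-12)
        assert rep.classification == "unimolecular"

    def test_unimolecular_series_round_trip(self):
        p = ThermoParams(-200.0, -565.0, Molecularity.UNIMOLECULAR)
        series = simulate_concentration_series(
            p, [1.5e-6, 3e-6, 6e-6], t_start=40.0, t_end=95.0,
            lower_baseline=(0.0, 0.30), upper_baseline=(0.0, 0.45),
        )
        tm_series = [
            (c, thermo.to_kelvin(analyze_curve(curve, molecularity="unimolecular").tm_obs_c))
            for c, curve in series
        ]
        rep = molecularity_test(tm_series, delta_H=-200.0)
        assert rep.classification == "unimolecular"

    def test_two_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            molecularity_test([(1e-6, 330.0), (2e-6, 331.0)], delta_H=-300.0)


class TestMeltCurveValidation:
    def test_non_monotone_temperatures_rejected(self):
        t = np.concatenate([np.linspace(10, 50, 15), np.linspace(49, 20, 15)])
        with pytest.raises(ValidationError):
            MeltCurve(t, np.zeros_like(t))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            MeltCurve(np.linspace(10, 90, 10), np.zeros(10))

    def test_non_finite_signal_rejected(self):
        t = np.linspace(10, 90, 30)
        s = np.zeros(30)
        s[5] = np.nan
        with pytest.raises(ValidationError):
            MeltCurve(t, s)
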