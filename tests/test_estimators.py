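"""Estimators: chord/regression rates, the three fits, bias table, correction."""

import numpy as np
import pytest

from intmm import (
    DesignSpec,
    DomainError,
    ErrorModel,
    FitFailureError,
    FitResult,
    KineticParameters,
    Measurement,
    RateEstimate,
    above_km_grid,
    below_km_grid,
    bias_table,
    chord_rate,
    chord_rates,
    consistency_diagnostic,
    correct_apparent,
    default_grid,
    fit_hanes_woolf,
    fit_hyperbolic,
    fit_integrated,
    initial_rate,
    perturb,
    product_at_time,
    regression_rates,
    simulate_design,
    single_point_specificity,
    time_to_product,
)


def exact_rates(params, grid):
    return [RateEstimate(s0=float(s), v_hat=float(initial_rate(params, s)))
            for s in grid]


class TestChordRate:
    def test_half_conversion_chord(self, unit_params):
        t = time_to_product(unit_params, 0.35, 0.175)
        r = chord_rate(Measurement(0.35, t, 0.175))
        assert r.v_hat == pytest.approx(0.20157872296161458, rel=1e-12)

    def test_sixty_percent_chord(self, unit_params):
        r = chord_rate(Measurement(0.35, 1.1263, 0.21))
        assert r.v_hat == pytest.approx(0.18645, abs=5e-5)

    def test_zero_product_zero_rate(self):
        assert chord_rate(Measurement(1.0, 2.0, 0.0)).v_hat == 0.0

    def test_zero_time_rejected(self):
        with pytest.raises(DomainError):
            chord_rate(Measurement(1.0, 0.0, 0.0))


class TestRegressionRates:
    def test_exact_line_through_origin(self):
        pts = [Measurement(1.0, t, 0.3 * t) for t in (0.1, 0.2, 0.3)]
        v1, v2 = regression_rates(pts)
        assert v1.v_hat == pytest.approx(0.3, rel=1e-12)
        assert v2.v_hat == pytest.approx(0.3, rel=1e-12)
        assert v2.intercept == pytest.approx(0.0, abs=1e-14)

    def test_two_points_give_the_chord(self, unit_params):
        t1, t2 = 0.2, 0.4
        p1 = product_at_time(unit_params, 0.7, t1)
        p2 = product_at_time(unit_params, 0.7, t2)
        _, v2 = regression_rates([Measurement(0.7, t1, p1), Measurement(0.7, t2, p2)])
        assert v2.v_hat == pytest.approx((p2 - p1) / (t2 - t1), rel=1e-10)

    def test_early_window_origin_regression_near_initial_rate(self, unit_params):
        # a dense window covering the first ~10% of conversion at s0 = 0.35
        t = np.linspace(0.001, 0.0141, 10) * 10
        p = product_at_time(unit_params, 0.35, t)
        v1, _ = regression_rates([Measurement(0.35, float(ti), float(pi))
                                  for ti, pi in zip(t, p)])
        assert v1.v_hat == pytest.approx(initial_rate(unit_params, 0.35), rel=0.05)

    def test_identical_times_singular(self):
        pts = [Measurement(1.0, 0.5, 0.1), Measurement(1.0, 0.5, 0.12)]
        with pytest.raises(FitFailureError):
            regression_rates(pts)


class TestHanesWoolf:
    def test_exact_rates_recover_truth(self, unit_params, grid):
        fit = fit_hanes_woolf(exact_rates(unit_params, grid))
        assert fit.V_hat == pytest.approx(1.0, rel=1e-10)
        assert fit.Km_hat == pytest.approx(1.0, rel=1e-10)
        assert fit.se_V == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("f,V_ref,Km_ref", [
        # frozen from this package's own exact simulation (unrounded chords)
        (0.1, 1.0151617587662771, 1.0699735673698034),
        (0.5, 1.1248834431432324, 1.5662423425786904),
        (0.7, 1.265901194611942, 2.2012811701346275),
    ])
    def test_constant_time_bias_values(self, constant_time_dataset, f, V_ref, Km_ref):
        fit = fit_hanes_woolf(chord_rates(constant_time_dataset(f).measurements))
        assert fit.V_hat == pytest.approx(V_ref, rel=1e-9)
        assert fit.Km_hat == pytest.approx(Km_ref, rel=1e-9)

    def test_needs_three_distinct_s0(self):
        rates = [RateEstimate(0.5, 0.2), RateEstimate(1.0, 0.3)]
        with pytest.raises(FitFailureError):
            fit_hanes_woolf(rates)


class TestHyperbolic:
    def test_exact_rates_recover_truth(self, unit_params, grid):
        fit = fit_hyperbolic(exact_rates(unit_params, grid))
        assert fit.V_hat == pytest.approx(1.0, rel=1e-6)
        assert fit.Km_hat == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.7])
    def test_agrees_with_hanes_woolf_within_five_percent(self, constant_time_dataset, f):
        rates = chord_rates(constant_time_dataset(f).measurements)
        hyp = fit_hyperbolic(rates)
        hw = fit_hanes_woolf(rates)
        assert hyp.V_hat == pytest.approx(hw.V_hat, rel=0.05)
        assert hyp.Km_hat == pytest.approx(hw.Km_hat, rel=0.05)


class TestIntegratedFit:
    @pytest.mark.parametrize("strategy", ["constant_time", "constant_conversion"])
    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5, 0.7])
    @pytest.mark.parametrize("make_grid", [default_grid, below_km_grid, above_km_grid])
    def test_noiseless_recovery_everywhere(self, unit_params, strategy, f, make_grid):
        spec = DesignSpec(strategy, tuple(make_grid()), f, unit_params)
        fit = fit_integrated(simulate_design(spec).measurements)
        assert fit.V_hat == pytest.approx(1.0, rel=1e-3)
        assert fit.Km_hat == pytest.approx(1.0, rel=1e-3)

    def test_two_exact_points_solve_the_line(self, unit_params):
        ms = [Measurement(0.35, time_to_product(unit_params, 0.35, 0.175), 0.175),
              Measurement(2.45, time_to_product(unit_params, 2.45, 0.5), 0.5)]
        fit = fit_integrated(ms)
        assert fit.V_hat == pytest.approx(1.0, rel=1e-10)
        assert fit.Km_hat == pytest.approx(1.0, rel=1e-10)

    def test_noisy_recovery_with_recorded_seed(self, constant_time_dataset):
        ds = perturb(constant_time_dataset(0.6), ErrorModel("relative_uniform", 0.05),
                     np.random.default_rng(42))
        fit = fit_integrated(ds.measurements)
        assert fit.V_hat == pytest.approx(1.0, rel=0.10)
        assert fit.Km_hat == pytest.approx(1.0, rel=0.10)

    def test_positive_slope_flags_model_violation(self):
        # y grows with x: impossible for the irreversible uninhibited model
        ms = [Measurement(1.0, 1.0, 0.2), Measurement(1.0, 0.5, 0.3),
              Measurement(1.0, 0.4, 0.35)]
        with pytest.raises(FitFailureError):
            fit_integrated(ms)

    def test_zero_product_points_warn_and_drop(self, unit_params, grid):
        ds = simulate_design(DesignSpec("constant_time", grid, 0.5, unit_params))
        ms = list(ds.measurements) + [Measurement(5.0, 0.8681, 0.0)]
        with pytest.warns(UserWarning):
            fit = fit_integrated(ms)
        assert fit.n_points == len(grid)


class TestSinglePointSpecificity:
    @pytest.mark.parametrize("f,pct", [(0.1, 71.245), (0.3, 64.981), (0.6, 53.272)])
    def test_apparent_over_true_ratio(self, unit_params, f, pct):
        s0 = 0.35
        t = time_to_product(unit_params, s0, f * s0)
        est = single_point_specificity(Measurement(s0, t, f * s0), unit_params)
        assert 100 * est.correction == pytest.approx(pct, abs=5e-3)

    def test_underestimation_worsens_with_conversion(self, unit_params):
        s0 = 0.35
        corrs = []
        for f in np.linspace(0.05, 0.9, 12):
            t = time_to_product(unit_params, s0, f * s0)
            corrs.append(single_point_specificity(Measurement(s0, t, f * s0),
                                                  unit_params).correction)
        assert all(c < 1 for c in corrs)
        assert np.all(np.diff(corrs) < 0)

    def test_small_fraction_small_s0_tends_to_truth(self, unit_params):
        s0, f = 1e-4, 1e-4
        t = time_to_product(unit_params, s0, f * s0)
        est = single_point_specificity(Measurement(s0, t, f * s0), unit_params)
        assert est.correction == pytest.approx(1.0, abs=1e-3)


@pytest.fixture(scope="module")
def table(unit_params):
    return bias_table(unit_params, default_grid())


class TestBiasTable:

    def test_bias_monotone_in_conversion(self, table):
        assert np.all(np.diff(table.V_app) > 0)
        assert np.all(np.diff(table.Km_app) > 0)
        assert np.all(np.diff(table.ratio) < 0)

    def test_km_inflation_exceeds_v_inflation(self, table):
        assert np.all(table.Km_app > table.V_app)

    def test_vanishing_conversion_is_unbiased(self, unit_params):
        row = bias_table(unit_params, default_grid(), fractions=(1e-5,)).iloc[0]
        assert row.V_app == pytest.approx(1.0, abs=1e-3)
        assert row.Km_app == pytest.approx(1.0, abs=1e-3)

    def test_below_km_grid_more_biased_than_above(self, unit_params):
        for f in (0.3, 0.5):
            below = bias_table(unit_params, below_km_grid(), fractions=(f,)).iloc[0]
            above = bias_table(unit_params, above_km_grid(), fractions=(f,)).iloc[0]
            assert below.V_app > above.V_app
            assert below.Km_app > above.Km_app


class TestCorrectApparent:
    def test_forward_then_inverse_is_identity(self, unit_params, grid):
        spec = DesignSpec("constant_time", grid, 0.7, unit_params)
        fit = fit_hanes_woolf(chord_rates(simulate_design(spec).measurements))
        corrected = correct_apparent(fit, spec)
        assert corrected.V == pytest.approx(1.0, rel=1e-6)
        assert corrected.Km == pytest.approx(1.0, rel=1e-6)

    def test_inverting_rounded_published_style_values(self, unit_params, grid):
        # apparent values carried at 3-4 digits invert to within ~2% of truth
        spec = DesignSpec("constant_time", grid, 0.1, unit_params)
        fit = FitResult("hanes_woolf", 1.017, 1.074, 0.004, 0.007, 7, 0.0)
        corrected = correct_apparent(fit, spec)
        assert corrected.V == pytest.approx(1.0, rel=0.02)
        assert corrected.Km == pytest.approx(1.0, rel=0.02)

    def test_zero_conversion_limit_changes_nothing(self, unit_params, grid):
        spec = DesignSpec("constant_time", grid, 1e-4, unit_params)
        fit = fit_hanes_woolf(chord_rates(simulate_design(spec).measurements))
        corrected = correct_apparent(fit, spec)
        assert corrected.V == pytest.approx(fit.V_hat, rel=1e-3)
        assert corrected.Km == pytest.approx(fit.Km_hat, rel=1e-3)


class TestConsistencyDiagnostic:
    def test_noiseless_half_conversion_matches_expectation(self, unit_params, grid):
        spec = DesignSpec("constant_time", grid, 0.5, unit_params)
        ds = simulate_design(spec)
        hw = fit_hanes_woolf(chord_rates(ds.measurements))
        fint = fit_integrated(ds.measurements)
        diag = consistency_diagnostic(hw, fint, spec)
        assert diag.ratio_Km == pytest.approx(1.566, abs=2e-3)
        assert diag.expected_ratio_Km == pytest.approx(diag.ratio_Km, rel=1e-6)
        assert not diag.violation

    def test_vanishing_conversion_ratios_are_one(self, unit_params, grid):
        spec = DesignSpec("constant_time", grid, 1e-4, unit_params)
        ds = simulate_design(spec)
        diag = consistency_diagnostic(fit_hanes_woolf(chord_rates(ds.measurements)),
                                      fit_integrated(ds.measurements), spec)
        assert diag.ratio_V == pytest.approx(1.0, abs=1e-3)
        assert diag.ratio_Km == pytest.approx(1.0, abs=1e-3)

    def test_apparent_below_integrated_is_flagged(self, unit_params, grid):
        spec = DesignSpec("constant_time", grid, 0.5, unit_params)
        hmm = FitResult("hanes_woolf", 0.8, 0.7, 0.0, 0.0, 7, 0.0)
        fint = FitResult("integrated", 1.0, 1.0, 0.0, 0.0, 7, 0.0)
        diag = consistency_diagnostic(hmm, fint, spec)
        assert diag.violation
        assert any("< 1" in n for n in diag.notes)
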