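"""Logistic fitting, goodness of fit, threshold inversion and model ranking."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from defolmap.calibration import (
    LogisticFit,
    ThresholdSet,
    compare_models,
    derive_threshold_set,
    fit_logistic,
    invert_threshold,
    logistic_forward,
    mcfadden_r2,
    read_fit_json,
    read_thresholds_json,
    slope_sign_warning,
    write_fit_json,
    write_thresholds_json,
)
from defolmap.errors import ConfigurationError, DataError
from defolmap.synthetic_scene import simulate_logistic_samples
from conftest import REFERENCE_COEFS, REFERENCE_R2

A_MSI, B_MSI = REFERENCE_COEFS["dMSI"]


class TestLogisticForward:
    def test_half_response_at_minus_a_over_b(self):
        for a, b in [(2.0, 0.5), (-3.36, -0.0093)]:
            assert logistic_forward(a, b, -a / b) == pytest.approx(0.5)

    def test_zero_slope_gives_constant_response(self):
        y = logistic_forward(1.2, 0.0, np.array([-1e6, 0.0, 1e6]))
        assert np.allclose(y, 1 / (1 + np.exp(-1.2)))

    def test_ten_percent_response_at_nil_low_limit(self):
        assert logistic_forward(A_MSI, B_MSI, -125.04) == pytest.approx(0.100, abs=5e-4)

    def test_overflow_safe_in_the_far_tails(self):
        assert logistic_forward(0.0, 1.0, -1e6) == 0.0
        assert logistic_forward(0.0, 1.0, 1e6) == 1.0


class TestFitLogistic:
    def test_recovers_generating_parameters_from_exact_curve(self):
        x = np.linspace(-800, 300, 20)
        y = logistic_forward(A_MSI, B_MSI, x)
        fit = fit_logistic((x, y))
        assert fit.a == pytest.approx(A_MSI, abs=1e-6)
        assert fit.b == pytest.approx(B_MSI, abs=1e-6)

    def test_matches_independent_glm_implementation(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        samples = simulate_logistic_samples(A_MSI, B_MSI, n=50, seed=5)
        fit = fit_logistic(samples)
        x = np.array([s.x for s in samples])
        y = np.array([s.y for s in samples])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = statsmodels.GLM(
                y, statsmodels.add_constant(x), family=statsmodels.families.Binomial()
            ).fit()
        assert fit.a == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.b == pytest.approx(glm.params[1], abs=1e-6)

    @pytest.mark.parametrize(
        "x, y, match",
        [
            ([1, 2, 3], [0.1, 0.2, 0.3], "at least 4"),
            ([1, 1, 1, 1], [0.1, 0.2, 0.3, 0.4], "all x"),
            ([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5], "all y"),
            ([1, 2, 3, 4], [0.1, 0.2, 0.3, 1.4], "outside"),
        ],
    )
    def test_degenerate_inputs_raise(self, x, y, match):
        with pytest.raises(DataError, match=match):
            fit_logistic((np.array(x, float), np.array(y, float)))

    def test_permuted_predictor_gives_near_zero_r2(self):
        """With x and y decoupled, the slope and McFadden R^2 collapse."""
        r2s = []
        for seed in range(100):
            samples = simulate_logistic_samples(A_MSI, B_MSI, n=50, seed=seed)
            x = np.array([s.x for s in samples])
            y = np.array([s.y for s in samples])
            np.random.default_rng(seed).shuffle(x)
            r2s.append(fit_logistic((x, y)).r2_mcfadden)
        assert np.median(r2s) < 0.05

    def test_strong_signal_draw_reaches_high_r2(self):
        fit = fit_logistic(simulate_logistic_samples(A_MSI, B_MSI, n=50, seed=7))
        assert 0.5 < fit.r2_mcfadden < 1.0

    def test_likelihood_ordering_saturated_full_null(self):
        fit = fit_logistic(simulate_logistic_samples(A_MSI, B_MSI, n=50, seed=11))
        assert fit.loglik_sat >= fit.loglik_full >= fit.loglik_null
        assert fit.r2_mcfadden >= 0.0


class TestMcFadden:
    def test_full_equals_null_gives_zero(self):
        fit = LogisticFit("", 0.0, 0.0, 0.0, 10, loglik_full=-30.0, loglik_null=-30.0, loglik_sat=0.0)
        assert mcfadden_r2(fit) == 0.0

    def test_full_reaching_saturated_gives_one(self):
        fit = LogisticFit("", 0.0, 1.0, 0.0, 10, loglik_full=-1e-12, loglik_null=-30.0, loglik_sat=0.0)
        assert mcfadden_r2(fit) == pytest.approx(1.0)

    def test_zero_or_positive_null_likelihood_rejected(self):
        bad = LogisticFit("", 0, 1, 0, 10, loglik_full=-1.0, loglik_null=0.0)
        with pytest.raises(DataError):
            mcfadden_r2(bad)


class TestThresholds:
    def test_inversion_reproduces_reference_limits(self):
        fit = LogisticFit("dMSI", A_MSI, B_MSI, 0.815, 50, -1.0, -2.0)
        assert round(invert_threshold(fit, 0.10)) == -125
        a, b = REFERENCE_COEFS["dMID"]
        assert round(invert_threshold(LogisticFit("dMID", a, b, 0, 50, -1, -2), 0.70)) == -949

    def test_half_boundary_is_minus_a_over_b(self):
        fit = LogisticFit("", 2.0, -0.5, 0, 10, -1, -2)
        assert invert_threshold(fit, 0.5) == pytest.approx(-2.0 / -0.5)

    def test_invalid_boundary_or_zero_slope_raise(self):
        fit = LogisticFit("", 1.0, -1.0, 0, 10, -1, -2)
        with pytest.raises(ConfigurationError):
            invert_threshold(fit, 1.0)
        with pytest.raises(ConfigurationError):
            invert_threshold(LogisticFit("", 1.0, 0.0, 0, 10, -1, -2), 0.5)

    def test_threshold_set_for_decreasing_and_increasing_models(self):
        msi = derive_threshold_set(LogisticFit("dMSI", A_MSI, B_MSI, 0, 50, -1, -2))
        assert msi.limits_x_rounded == (-125, -295, -453) and msi.orientation == "decreasing"
        a, b = REFERENCE_COEFS["dNDMI"]
        ndmi = derive_threshold_set(LogisticFit("dNDMI", a, b, 0, 50, -1, -2))
        assert ndmi.limits_x_rounded == (963, 2081, 3121) and ndmi.orientation == "increasing"

    def test_symmetric_boundaries_with_zero_intercept_are_symmetric(self):
        fit = LogisticFit("", 0.0, 0.004, 0, 10, -1, -2)
        ts = derive_threshold_set(fit, boundaries_y=(0.2, 0.8))
        assert ts.limits_x[0] == pytest.approx(-ts.limits_x[1])

    def test_round_trip_forward_of_inverted_boundary(self):
        fit = LogisticFit("dMSI", A_MSI, B_MSI, 0, 50, -1, -2)
        for y in np.arange(0.1, 0.95, 0.1):
            assert logistic_forward(fit.a, fit.b, invert_threshold(fit, y)) == pytest.approx(y, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-0.05, 0.05).filter(lambda v: abs(v) > 1e-4),
    )
    def test_limits_strictly_monotone_with_slope_sign(self, a, b):
        ts = derive_threshold_set(LogisticFit("", a, b, 0, 10, -1, -2))
        diffs = np.diff(ts.limits_x)
        assert np.all(diffs < 0) if b < 0 else np.all(diffs > 0)

    def test_threshold_set_rejects_non_monotone_limits(self):
        with pytest.raises(DataError):
            ThresholdSet("x", limits_x=(1.0, 3.0, 2.0), orientation="increasing")


class TestCompareModels:
    def _fits(self):
        return [
            LogisticFit(name, *REFERENCE_COEFS[name], r2_mcfadden=REFERENCE_R2[name], n=50, loglik_full=-1, loglik_null=-2)
            for name in REFERENCE_COEFS
        ]

    def test_reference_r2_ranking_puts_moisture_stress_first(self):
        ranking = compare_models(self._fits())
        assert ranking.best.index_name == "dMSI"
        assert [f.index_name for f in ranking.fits] == ["dMSI", "dNDVI", "dNBR", "dNDMI", "dMID"]

    def test_single_fit_ranks_itself(self):
        fit = self._fits()[0]
        assert compare_models([fit]).best is fit

    def test_equal_r2_breaks_ties_lexicographically_and_flags_them(self):
        a = LogisticFit("dNBR", 0, 1, 0.5, 10, -1, -2)
        b = LogisticFit("dMID", 0, 1, 0.5, 10, -1, -2)
        ranking = compare_models([a, b])
        assert [f.index_name for f in ranking.fits] == ["dMID", "dNBR"]
        assert ranking.ties == [("dMID", "dNBR")]

    def test_empty_list_raises(self):
        with pytest.raises(ConfigurationError):
            compare_models([])


def test_slope_sign_warning_flags_inverted_burn_ratio():
    a, b = REFERENCE_COEFS["dNBR"]
    warn = slope_sign_warning(LogisticFit("dNBR", a, b, 0, 50, -1, -2))
    assert warn is not None and "dNBR" in warn
    assert slope_sign_warning(LogisticFit("dMSI", A_MSI, B_MSI, 0, 50, -1, -2)) is None


def test_fit_and_thresholds_survive_json_round_trip(tmp_path):
    fit = fit_logistic(simulate_logistic_samples(A_MSI, B_MSI, n=50, seed=3), index_name="dMSI")
    write_fit_json(tmp_path / "fit.json", fit)
    back = read_fit_json(tmp_path / "fit.json")
    assert (back.a, back.b, back.r2_mcfadden, back.n) == (fit.a, fit.b, fit.r2_mcfadden, fit.n)

    ts = derive_threshold_set(fit)
    write_thresholds_json(tmp_path / "thr.json", ts)
    back_ts = read_thresholds_json(tmp_path / "thr.json")
    assert back_ts.limits_x == ts.limits_x and back_ts.orientation == ts.orientation
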