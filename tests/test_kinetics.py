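"""Power-law release model: prediction, normalization, fitting, mechanism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanoaroma import (
    ConcentrationMeasurement,
    FitOptions,
    ReleaseCurve,
    classify_mechanism,
    fit_peppas,
    goodness_of_fit,
    normalize_release,
    peppas_predict,
)
from nanoaroma.errors import (
    CannotNormalizeError,
    FitFailureError,
    InsufficientDataError,
)
from nanoaroma.kinetics import loglog_ols_estimate


def power_law_curve(k, n, times=None):
    t = np.geomspace(1, 2000, 20) if times is None else np.asarray(times, float)
    return ReleaseCurve(t, np.clip(k * t**n, 0, 1), m_infinity=1.0,
                        m_infinity_source="supplied")


class TestPredict:
    @pytest.mark.parametrize(
        "k, n, t, expected",
        [
            (0.0189, 0.47, 1.0, 0.0189),  # t=1 returns k itself
            (0.0189, 0.47, 0.0, 0.0),
            (0.0189, 0.47, 100.0, 0.1646),  # k * 100^0.47
            (0.0786, 0.30, 630.0, 0.5435),  # nanocapsule parameters at their plateau time
        ],
    )
    def test_oracle_values(self, k, n, t, expected):
        assert peppas_predict(k, n, t) == pytest.approx(expected, abs=5e-5)

    @given(
        k=st.floats(min_value=1e-4, max_value=0.5),
        n=st.floats(min_value=0.05, max_value=1.5),
        t=st.floats(min_value=0.1, max_value=1e4),
        lam=st.floats(min_value=1.1, max_value=10),
    )
    def test_monotone_and_homogeneous(self, k, n, t, lam):
        """Strictly increasing in t; scaling t by lam scales output by lam^n."""
        f1, f2 = peppas_predict(k, n, t), peppas_predict(k, n, lam * t)
        assert f2 > f1
        assert f2 == pytest.approx(f1 * lam**n, rel=1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            peppas_predict(0.0, 0.5, 1.0)
        with pytest.raises(ValueError):
            peppas_predict(0.1, -0.5, 1.0)


class TestNormalizeRelease:
    def make_series(self, values, times=None):
        times = range(len(values)) if times is None else times
        return [
            ConcentrationMeasurement("α-Pinene", v, time=float(t))
            for t, v in zip(times, values)
        ]

    def test_plateau_self_normalization(self):
        values = [0.1, 0.4, 0.8, 1.0, 1.005, 0.995, 1.0]
        curve = normalize_release(self.make_series(values))
        assert curve.m_infinity_source == "plateau-estimated"
        assert curve.fractions[-1] == pytest.approx(1.0, abs=0.02)

    def test_supplied_m_infinity(self):
        values = [1.0, 2.0, 4.0]
        curve = normalize_release(self.make_series(values), m_infinity=4.0)
        assert curve.m_infinity_source == "supplied"
        assert curve.fractions.max() == pytest.approx(1.0)

    def test_no_plateau_no_asymptote(self):
        values = [1.0, 2.0, 4.0, 8.0, 16.0]
        with pytest.raises(CannotNormalizeError):
            normalize_release(self.make_series(values))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            normalize_release(self.make_series([1.0, 2.0]))


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        obs = np.array([0.1, 0.5, 0.9, 1.0])
        g = goodness_of_fit(obs, obs.copy())
        assert (g.r_squared, g.sse, g.rmse) == (1.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        g = goodness_of_fit([0.0, 1.0, 0.5], [0.0, 0.9, 0.5], n_params=1)
        assert g.sse == pytest.approx(0.01)
        assert g.rmse == pytest.approx(np.sqrt(0.01 / 3))

    def test_two_parameter_fit_needs_four_points(self):
        with pytest.raises(ValueError, match="n_params"):
            goodness_of_fit([0.0, 1.0, 0.5], [0.0, 0.9, 0.5], n_params=2)

    def test_adjusted_r_squared_formula(self):
        # N=10, p=2, R2=0.9 -> 1 - 0.1 * 9/7 = 0.87142857
        rng = np.random.default_rng(7)
        obs = np.linspace(0, 1, 10)
        # craft predictions with the exact SSE for R2 = 0.9
        sst = ((obs - obs.mean()) ** 2).sum()
        resid = np.zeros(10)
        resid[0] = np.sqrt(0.1 * sst)
        g = goodness_of_fit(obs, obs + resid, n_params=2)
        assert g.r_squared == pytest.approx(0.9)
        assert g.r_squared_adj == pytest.approx(0.8714, abs=5e-5)

    def test_adjusted_never_exceeds_plain(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(0, 1, 15)
        pred = obs + rng.normal(0, 0.05, 15)
        g = goodness_of_fit(obs, pred, n_params=2)
        assert g.r_squared_adj <= g.r_squared

    def test_zero_variance_undefined(self):
        with pytest.raises(ZeroDivisionError):
            goodness_of_fit([0.5, 0.5, 0.5, 0.5], [0.4, 0.5, 0.6, 0.5])

    def test_rmse_divisor_option(self):
        g = goodness_of_fit([0.0, 1.0, 0.5, 0.2], [0.1, 0.9, 0.5, 0.2],
                            n_params=1, rmse_divisor="n_minus_p")
        assert g.rmse == pytest.approx(np.sqrt(0.02 / 3))


class TestFitPeppas:
    def test_recovers_noiseless_parameters(self):
        fit = fit_peppas(power_law_curve(0.0234, 0.45))
        assert fit.k == pytest.approx(0.0234, rel=1e-4)
        assert fit.n == pytest.approx(0.45, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_matches_loglog_closed_form_on_noiseless_data(self):
        curve = power_law_curve(0.0189, 0.47)
        fit = fit_peppas(curve)
        k_ols, n_ols = loglog_ols_estimate(curve.times, curve.fractions)
        assert fit.k == pytest.approx(k_ols, abs=1e-6)
        assert fit.n == pytest.approx(n_ols, abs=1e-6)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        t = np.geomspace(1, 2000, 20)
        f = np.clip(0.03 * t**0.5 * (1 + rng.normal(0, 0.05, 20)), 0, 1)
        curve = ReleaseCurve(t, f)
        fits = [fit_peppas(curve) for _ in range(3)]
        assert fits[0].k == fits[1].k == fits[2].k
        assert fits[0].n == fits[1].n == fits[2].n

    def test_constant_fractions_fail(self):
        curve = ReleaseCurve(np.array([1.0, 2.0, 3.0, 4.0]),
                             np.full(4, 0.5))
        with pytest.raises(FitFailureError):
            fit_peppas(curve)

    def test_too_few_usable_points(self):
        curve = ReleaseCurve(np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.1, 0.2]))
        with pytest.raises(InsufficientDataError):
            fit_peppas(curve)

    def test_saturated_points_excluded_by_default(self):
        t = np.geomspace(1, 5000, 25)
        curve = ReleaseCurve(t, np.clip(0.05 * t**0.6, 0, 1))
        fit = fit_peppas(curve)
        assert fit.n_points_used == int((0.05 * t**0.6 < 1).sum())
        assert fit.n == pytest.approx(0.6, rel=1e-3)

    def test_early_window_cap(self):
        t = np.geomspace(1, 2000, 30)
        curve = ReleaseCurve(t, np.clip(0.02 * t**0.5, 0, 1))
        fit = fit_peppas(curve, FitOptions(early_window_cap=0.6))
        assert (0.02 * curve.times**0.5 <= 0.6).sum() == fit.n_points_used

    @pytest.mark.parametrize("sigma", [0.0, 0.02, 0.05])
    def test_recovery_error_grows_with_noise(self, sigma, results={}):
        """Median |n_hat - n| over 50 replicates increases with noise, 0 at sigma=0."""
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.geomspace(1, 2000, 20)
            clean = 0.0234 * t**0.45
            f = np.clip(clean * (1 + rng.normal(0, sigma, 20)), 0, 1)
            fit = fit_peppas(ReleaseCurve(t, f))
            errors.append(abs(fit.n - 0.45))
        results[sigma] = float(np.median(errors))
        if sigma == 0.0:
            assert results[0.0] < 1e-6
        elif sigma == 0.05 and 0.02 in results:
            assert results[0.05] > results[0.02] > results[0.0]


class TestMechanism:
    @pytest.mark.parametrize(
        "n, label",
        [
            (0.43, "Fickian"),
            (0.47, "anomalous (non-Fickian)"),
            (0.45, "anomalous (non-Fickian)"),  # band edge reads as anomalous
            (0.30, "quasi-Fickian/combined"),
            (0.85, "Case II"),
            (0.95, "super Case II"),
            (0.425, "Fickian"),
        ],
    )
    def test_sphere_bands(self, n, label):
        call = classify_mechanism(n, geometry="sphere")
        assert call.label == label
        assert call.geometry == "sphere"

    def test_slab_reference_exponents(self):
        assert classify_mechanism(0.5, geometry="slab").label == "Fickian"
        assert classify_mechanism(0.7, geometry="slab").label == "anomalous (non-Fickian)"

    def test_unsupported_geometry_lists_shapes(self):
        with pytest.raises(ValueError, match="sphere"):
            classify_mechanism(0.5, geometry="torus")

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            classify_mechanism(0.0)


class TestReleaseCurveValidation:
    @pytest.mark.parametrize(
        "times, fractions",
        [
            ([1.0, 1.0, 2.0], [0.1, 0.2, 0.3]),  # non-increasing
            ([1.0, 2.0, 3.0], [0.1, -0.2, 0.3]),  # negative fraction
            ([1.0, 2.0, 3.0], [0.1, 0.2, 1.2]),  # beyond noise slack
        ],
    )
    def test_invalid_curves_rejected(self, times, fractions):
        with pytest.raises(ValueError):
            ReleaseCurve(np.array(times), np.array(fractions))
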