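import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finwhale import detection as det
from finwhale.synthetic_data import distances_frame, sample_distances

from conftest import make_fixed_fit

W = 7000.0


class TestKeyFunctions:
    def test_half_normal_values(self):
        sigma = 1200.0
        assert det.g_half_normal(0.0, sigma) == 1.0
        assert det.g_half_normal(sigma, sigma) == pytest.approx(np.exp(-0.5))
        assert det.g_half_normal(3 * sigma, sigma) == pytest.approx(0.011109, abs=1e-6)
        with pytest.raises(ValueError):
            det.g_half_normal(100.0, 0.0)

    def test_hazard_rate_values(self):
        sigma = 1200.0
        for b in (0.5, 1.555, 4.0):
            assert det.g_hazard_rate(sigma, sigma, b) == pytest.approx(-np.expm1(-1.0))
        assert det.g_hazard_rate(0.0, sigma, 1.555) == 1.0
        # shoulder value at 2 sigma with the reported shape coefficient
        assert det.g_hazard_rate(2 * sigma, sigma, 1.555) == pytest.approx(
            0.288441, abs=1e-4
        )
        with pytest.raises(ValueError):
            det.g_hazard_rate(100.0, 1200.0, -1.0)

    def test_monotone_decreasing(self):
        x = np.linspace(0, W, 500)
        for g in (
            det.g_half_normal(x, 1500.0),
            det.g_hazard_rate(x, 1500.0, 1.555),
        ):
            assert np.all(np.diff(g) <= 1e-12)
            assert np.all((g > 0) & (g <= 1))


class TestEffectiveStripWidth:
    def test_perfect_detection_limit(self):
        model = det.DetectionModel(key=det.HALF_NORMAL, w_m=W)
        assert det.effective_strip_width(model, 1e9) == pytest.approx(W, rel=1e-9)

    def test_half_normal_closed_form(self):
        sigma = 400.0  # << w so the integral is effectively complete
        model = det.DetectionModel(key=det.HALF_NORMAL, w_m=W)
        assert det.effective_strip_width(model, sigma) == pytest.approx(
            sigma * np.sqrt(np.pi / 2), rel=1e-9
        )

    @pytest.mark.parametrize(
        "key, sigma, b",
        [(det.HALF_NORMAL, 1500.0, None), (det.HAZARD_RATE, 1200.0, 1.555)],
    )
    def test_quadrature_matches_trapezoid_oracle(self, key, sigma, b):
        model = det.DetectionModel(key=key, w_m=W)
        grid = np.linspace(0.0, W, 100_001)
        g = (
            det.g_half_normal(grid, sigma)
            if key == det.HALF_NORMAL
            else det.g_hazard_rate(grid, sigma, b)
        )
        oracle = np.trapezoid(g, grid)
        assert det.effective_strip_width(model, sigma, b=b) == pytest.approx(
            oracle, rel=1e-6
        )


class TestFitting:
    def test_half_normal_recovery(self, hn_fit):
        sigma_hat = np.exp(hn_fit.params[0])
        assert sigma_hat == pytest.approx(1500.0, rel=0.05)
        assert hn_fit.aic == pytest.approx(2 * 1 - 2 * hn_fit.loglik)

    def test_too_few_distinct_distances(self):
        df = distances_frame(np.array([100.0, 100.0]))
        with pytest.raises(det.FitError):
            det.fit_detection(df, det.HALF_NORMAL, (), W)

    def test_uniform_distances_boundary_warning(self):
        rng = np.random.default_rng(5)
        df = distances_frame(rng.uniform(0, W, size=400))
        with pytest.warns(UserWarning, match="no decline"):
            det.fit_detection(df, det.HALF_NORMAL, (), W)

    def test_wind_effect_sign_recovery(self):
        """A negative log-scale wind effect is recovered in most replicates."""
        b_true, sigma0, beta_w = 1.555, 1500.0, -0.0125
        hits = 0
        n_rep = 20
        n_obs = 2500
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            xs, winds = [], []
            while len(xs) < n_obs:
                wind = rng.uniform(0.0, 12.0, size=8000)
                x = rng.uniform(0.0, W, size=8000)
                g = det.g_hazard_rate(x, sigma0 * np.exp(beta_w * wind), b_true)
                acc = rng.uniform(size=8000) < g
                xs.extend(x[acc])
                winds.extend(wind[acc])
            df = distances_frame(np.asarray(xs[:n_obs]))
            df["wind_speed_ms"] = np.asarray(winds[:n_obs])
            fit = det.fit_detection(df, det.HAZARD_RATE, ("wind_speed",), W)
            beta_hat = fit.params[fit.param_names.index("wind_speed")]
            hits += beta_hat < 0
        assert hits / n_rep >= 0.9

    def test_affine_covariate_recoding_invariance(self):
        rng = np.random.default_rng(2)
        x = sample_distances(600, det.HAZARD_RATE, 1200.0, W, seed=2, shape=1.555)
        df = distances_frame(x)
        df["wind_speed_ms"] = rng.uniform(0, 12, size=len(df))
        fit_ms = det.fit_detection(df, det.HAZARD_RATE, ("wind_speed",), W)
        knots = df.copy()
        knots["wind_speed_ms"] = df["wind_speed_ms"] * 1.9438  # m/s -> knots
        fit_kn = det.fit_detection(knots, det.HAZARD_RATE, ("wind_speed",), W)
        assert fit_kn.loglik == pytest.approx(fit_ms.loglik, abs=1e-4)
        b_ms = fit_ms.params[fit_ms.param_names.index("wind_speed")]
        b_kn = fit_kn.params[fit_kn.param_names.index("wind_speed")]
        assert b_kn * 1.9438 == pytest.approx(b_ms, rel=1e-2)

    def test_single_level_covariate_dropped(self):
        x = sample_distances(200, det.HALF_NORMAL, 1500.0, W, seed=4)
        df = distances_frame(x)  # a single observer
        with pytest.warns(UserWarning, match="single level"):
            fit = det.fit_detection(df, det.HALF_NORMAL, ("obs",), W)
        assert fit.param_names == ["(intercept)"]


class TestAdjustments:
    def test_zero_coefficients_identical_to_key(self):
        model = det.DetectionModel(
            key=det.HALF_NORMAL, w_m=W, adjustment_orders=(2,)
        )
        x = np.linspace(0, W, 50)
        adjusted = det.detection_probability(model, x, 1500.0, adj_coefs=np.array([0.0]))
        np.testing.assert_allclose(adjusted, det.g_half_normal(x, 1500.0))

    def test_negative_density_configuration_invalid(self):
        model = det.DetectionModel(
            key=det.HALF_NORMAL, w_m=W, adjustment_orders=(2,)
        )
        assert not det._adjustment_valid(model, None, 1500.0, np.array([-2.0]))

    def test_order2_coefficient_recovery(self):
        a_true = 0.3
        sigma = 2000.0
        rng = np.random.default_rng(9)
        model = det.DetectionModel(key=det.HALF_NORMAL, w_m=W, adjustment_orders=(2,))
        xs = []
        while len(xs) < 5000:
            x = rng.uniform(0, W, size=20000)
            g = det.detection_probability(model, x, sigma, adj_coefs=np.array([a_true]))
            xs.extend(x[rng.uniform(size=20000) < np.clip(g, 0, 1)])
        fit = det.fit_with_adjustments(distances_frame(np.asarray(xs[:5000])), det.HALF_NORMAL, (2,), W)
        a_hat = fit.params[fit.param_names.index("cos2")]
        assert a_hat == pytest.approx(a_true, rel=0.10)

    def test_covariates_and_adjustments_exclusive(self):
        with pytest.raises(ValueError):
            det.DetectionModel(
                key=det.HALF_NORMAL, formula=("obs",), adjustment_orders=(2,)
            )


class TestAverageDetectability:
    def test_no_covariates_equals_esw_over_w(self, hn_fit):
        mu = hn_fit.esw_m[0]
        assert hn_fit.pa == pytest.approx(mu / W, rel=1e-12)
        assert 0 < hn_fit.pa <= 1

    def test_constant_p_identity(self, hn_fit):
        # all p_i equal -> P_a equals that common value exactly
        assert np.allclose(hn_fit.p, hn_fit.p[0])
        assert hn_fit.pa == pytest.approx(hn_fit.p[0])

    def test_recovers_population_average(self):
        """P_a from an observer-covariate fit tracks the true mixture average."""
        sigmas = {"A": 900.0, "B": 2400.0}
        b_true = 1.555
        rng = np.random.default_rng(21)
        rows = []
        for obs, sigma in sigmas.items():
            x = rng.uniform(0, W, size=20000)
            keep = rng.uniform(size=20000) < det.g_hazard_rate(x, sigma, b_true)
            rows.append(pd.DataFrame({"perp_distance_m": x[keep], "observer": obs}))
        df = pd.concat(rows, ignore_index=True)
        frame = distances_frame(df["perp_distance_m"].to_numpy())
        frame["observer"] = df["observer"].to_numpy()
        fit = det.fit_detection(frame, det.HAZARD_RATE, ("obs",), W)
        model = det.DetectionModel(key=det.HAZARD_RATE, w_m=W)
        true_pa = np.mean(
            [det.effective_strip_width(model, s, b=b_true) / W for s in sigmas.values()]
        )
        assert fit.pa == pytest.approx(true_pa, abs=2 * max(fit.se_pa, 0.01))


class TestModelSelection:
    def test_single_fit_delta_zero(self, hn_fit):
        table = det.model_selection([hn_fit])
        assert table["delta_aic"].tolist() == [0.0]

    def test_extra_parameter_penalty(self, hn_fit):
        import copy

        other = copy.copy(hn_fit)
        other.params = np.append(hn_fit.params, 0.0)
        other.aic = 2 * other.n_params - 2 * other.loglik
        table = det.model_selection([hn_fit, other])
        assert table["delta_aic"].iloc[1] == pytest.approx(2.0)

    def test_mixed_datasets_rejected(self, hn_fit):
        x = sample_distances(300, det.HALF_NORMAL, 1500.0, W, seed=8)
        other = det.fit_detection(distances_frame(x), det.HALF_NORMAL, (), W)
        with pytest.raises(ValueError, match="identical data"):
            det.model_selection([hn_fit, other])

    def test_observer_effect_detected_by_aic(self):
        """With a strong observer effect, ~obs beats the null in most replicates."""
        hits = 0
        n_rep = 15
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            rows = []
            for obs, sigma in (("A", 700.0), ("B", 2800.0)):
                x = rng.uniform(0, W, size=1200)
                keep = rng.uniform(size=1200) < det.g_hazard_rate(x, sigma, 1.555)
                rows.append(pd.DataFrame({"x": x[keep], "obs": obs}))
            df = pd.concat(rows, ignore_index=True)
            frame = distances_frame(df["x"].to_numpy())
            frame["observer"] = df["obs"].to_numpy()
            null = det.fit_detection(frame, det.HAZARD_RATE, (), W)
            obs_fit = det.fit_detection(frame, det.HAZARD_RATE, ("obs",), W)
            hits += obs_fit.aic < null.aic
        assert hits / n_rep >= 0.9

    def test_aic_ordering_unit_invariant(self, hn_fit):
        x_km = hn_fit.distances_m / 1000.0
        df_km = distances_frame(x_km)
        fit_km = det.fit_detection(df_km, det.HALF_NORMAL, (), W / 1000.0)
        # loglik shifts by n*log(1000) under the unit change, AIC gaps don't
        assert fit_km.loglik - hn_fit.loglik == pytest.approx(
            hn_fit.n * np.log(1000.0), rel=1e-4
        )


class TestCramerVonMises:
    def test_statistic_nonnegative(self, hn_fit):
        stat, p = det.cvm_test(hn_fit)
        assert stat >= 0
        assert 0 <= p <= 1

    def test_refuses_tiny_samples(self):
        fit = make_fixed_fit(np.array([10.0, 20.0, 30.0]), det.HALF_NORMAL, 1500.0, W)
        with pytest.raises(ValueError, match="at least 5"):
            det.cvm_test(fit)

    def test_pvalues_uniform_under_true_model(self):
        """PIT p-values against the true (fixed) model are uniform."""
        pvals = []
        for seed in range(120):
            x = sample_distances(400, det.HAZARD_RATE, 1200.0, W, seed=1000 + seed, shape=1.555)
            fit = make_fixed_fit(x, det.HAZARD_RATE, 1200.0, W, b=1.555)
            pvals.append(det.cvm_test(fit)[1])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_rejects_gross_misspecification(self):
        """Uniform distances against a steep half-normal are firmly rejected."""
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(50 + seed)
            x = rng.uniform(0, W, size=500)
            fit = make_fixed_fit(x, det.HALF_NORMAL, 800.0, W)
            rejections += det.cvm_test(fit)[1] < 0.05
        assert rejections >= 19
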