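"""Environmental response: covariate screen, inverse-link GLM, logistic fit,
bootstrap inference, prediction and potential-matched groups."""

import numpy as np
import pandas as pd
import pytest

from aposcape import (
    SimConfig,
    bootstrap_gradient,
    bounded_logistic,
    fit_glm_inverse_gaussian,
    fit_response,
    gen_env_gradient,
    pearson_screen,
    potential_matched_groups,
    predict_response,
    validate_against_garden,
)

TRUE_PARAMS = (0.05, 0.45, 1.2, 12.5)


@pytest.fixture
def gradient_data(rng):
    x = rng.uniform(11, 15, 20)
    y_clean = bounded_logistic(x, *TRUE_PARAMS)
    y_noisy = np.clip(y_clean + rng.normal(0, 0.05, 20), 0.001, 0.999)
    return x, y_clean, y_noisy


class TestPearsonScreen:
    def test_linear_proportion_gives_unit_correlation(self):
        env = pd.DataFrame({"population_id": list("abcde"), "mdr": [11, 12, 13, 14, 15.0]})
        s = np.linspace(0.1, 0.5, 5)
        props = pd.DataFrame({"population_id": list("abcde"), "sexual": s, "apomictic": 1 - s})
        out = pearson_screen(env, props)
        assert out["r_sexual"].iloc[0] == pytest.approx(1.0)

    def test_complementary_pathways_have_opposite_r(self, rng):
        env = pd.DataFrame({"population_id": [f"p{i}" for i in range(10)],
                            "mdr": rng.uniform(11, 15, 10)})
        s = rng.uniform(0.1, 0.9, 10)
        props = pd.DataFrame({"population_id": env["population_id"], "sexual": s,
                              "apomictic": 1 - s})
        out = pearson_screen(env, props)
        assert out["r_apomictic"].iloc[0] == pytest.approx(-out["r_sexual"].iloc[0])

    def test_synthetic_gradient_ranks_mdr_first(self, rng):
        cfg = SimConfig(n_populations=20, noise_sd=0.05)
        env, props, _ = gen_env_gradient(cfg, rng)
        out = pearson_screen(env, props, stage="seed")
        assert out["covariate"].iloc[0] == "mdr"
        assert out["r_sexual"].iloc[0] > 0.6
        assert bool(out["selected"].iloc[0])

    def test_constant_covariate_skipped(self, rng):
        env = pd.DataFrame({"population_id": list("abcd"), "flat": [1.0] * 4,
                            "mdr": [11, 12, 13, 14.0]})
        props = pd.DataFrame({"population_id": list("abcd"),
                              "sexual": [0.1, 0.2, 0.3, 0.4],
                              "apomictic": [0.9, 0.8, 0.7, 0.6]})
        with pytest.warns(UserWarning, match="constant"):
            out = pearson_screen(env, props)
        assert "flat" not in set(out["covariate"])


class TestInverseLinkGlm:
    def test_noise_free_coefficients_recovered(self):
        x = np.linspace(1, 10, 40)
        y = 1.0 / (0.5 + 0.1 * x)
        fit = fit_glm_inverse_gaussian(x, y)
        assert fit.intercept == pytest.approx(0.5, abs=1e-6)
        assert fit.slope == pytest.approx(0.1, abs=1e-6)

    def test_constant_response_zero_slope(self):
        x = np.linspace(1, 10, 20)
        fit = fit_glm_inverse_gaussian(x, np.full(20, 0.4))
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.t_values[1] == pytest.approx(0.0, abs=1e-6)

    def test_coverage_of_truth_under_noise(self, rng):
        hits, reps = 0, 200
        x = np.linspace(1, 5, 100)
        mu = 1.0 / (0.8 + 0.3 * x)
        for _ in range(reps):
            y = mu + rng.normal(0, 0.02, 100)
            fit = fit_glm_inverse_gaussian(x, y)
            se = abs(fit.slope / fit.t_values[1])
            hits += abs(fit.slope - 0.3) < 3 * se
        assert hits / reps >= 0.95

    def test_zero_response_rejected(self):
        with pytest.raises(ValueError):
            fit_glm_inverse_gaussian([1, 2, 3], [0.5, 0.0, 0.4])


class TestResponseFit:
    def test_noise_free_parameter_recovery(self, gradient_data):
        x, y_clean, _ = gradient_data
        fit = fit_response(x, y_clean)
        assert fit.rss < 1e-8
        assert fit.params == pytest.approx(TRUE_PARAMS, abs=0.05)

    def test_refinement_never_increases_rss(self, rng):
        for _ in range(20):
            x = rng.uniform(10, 16, 15)
            y = rng.uniform(0, 1, 15)
            fit = fit_response(x, y)
            assert fit.rss <= fit.grid_rss + 1e-12

    def test_flat_response_flags_unidentified_gradient(self):
        x = np.linspace(11, 15, 12)
        with pytest.warns(UserWarning, match="unidentified"):
            fit = fit_response(x, np.full(12, 0.3))
        assert not fit.k_identified
        assert bounded_logistic(13.0, *fit.params) == pytest.approx(0.3, abs=0.02)

    def test_upper_plateau_below_one(self, gradient_data):
        x, _, y = gradient_data
        fit = fit_response(x, y)
        assert 0.0 <= fit.s_lo < fit.s_hi < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_response([1, 2, 3], [0.1, 0.2, 0.3])


class TestBootstrap:
    def test_steep_noise_free_gradient_significant(self, gradient_data):
        x, y_clean, _ = gradient_data
        fit = fit_response(x, y_clean)
        boot = bootstrap_gradient(x, y_clean, fit=fit, B=200, rng_seed=7)
        assert boot.ci_k[0] > 0.0
        assert boot.p_k == pytest.approx(2 / 200)

    def test_reproducible_under_fixed_seed(self, gradient_data):
        x, _, y = gradient_data
        fit = fit_response(x, y)
        b1 = bootstrap_gradient(x, y, fit=fit, B=150, rng_seed=11)
        b2 = bootstrap_gradient(x, y, fit=fit, B=150, rng_seed=11)
        assert b1.ci_k == b2.ci_k and b1.p_k == b2.p_k
        assert np.array_equal(b1.k_samples, b2.k_samples)

    def test_null_gradient_ci_usually_covers_zero(self, rng):
        covered, reps = 0, 40
        for _ in range(reps):
            x = rng.uniform(11, 15, 20)
            y = np.clip(0.3 + rng.normal(0, 0.05, 20), 0.001, 0.999)
            fit = fit_response(x, y)
            boot = bootstrap_gradient(x, y, fit=fit, B=150, rng_seed=rng)
            covered += boot.ci_k[0] <= 0.0 <= boot.ci_k[1]
        assert covered / reps >= 0.8

    def test_too_few_replicates_rejected(self, gradient_data):
        x, _, y = gradient_data
        with pytest.raises(ValueError):
            bootstrap_gradient(x, y, B=50)


class TestPrediction:
    def test_midpoint_and_asymptotes(self, gradient_data):
        x, y_clean, _ = gradient_data
        fit = fit_response(x, y_clean)
        s_mid, a_mid = predict_response(fit, fit.x0)
        assert s_mid == pytest.approx((fit.s_lo + fit.s_hi) / 2, abs=1e-6)
        with pytest.warns(UserWarning, match="extrapolating"):
            s_low, _ = predict_response(fit, -1e3)
        assert s_low == pytest.approx(fit.s_lo, abs=1e-6)

    def test_pair_sums_to_one_within_open_bounds(self, gradient_data):
        x, _, y = gradient_data
        fit = fit_response(x, y)
        for mdr in np.linspace(*fit.x_span, 7):
            s, a = predict_response(fit, mdr)
            assert s + a == pytest.approx(1.0, abs=1e-12)
            assert fit.s_lo <= s <= fit.s_hi

    def test_heldout_prediction_near_truth(self, rng):
        cfg = SimConfig(n_populations=20, noise_sd=0.05)
        env, props, truth = gen_env_gradient(cfg, rng)
        merged = env.merge(props, on="population_id")
        fit = fit_response(merged["mdr"], merged["sexual"])
        with pytest.warns(UserWarning, match="extrapolating"):
            pred = predict_response(fit, 11.1)[0]
        assert pred == pytest.approx(
            bounded_logistic(11.1, *cfg.response_params), abs=2 * cfg.noise_sd
        )


class TestGardenValidation:
    def _fit(self, rng):
        x = rng.uniform(11, 15, 20)
        y = bounded_logistic(x, *TRUE_PARAMS)
        return fit_response(x, y)

    def test_exact_match_when_garden_equals_prediction(self, rng):
        fit = self._fit(rng)
        pred = bounded_logistic(13.0, *fit.params)
        r = validate_against_garden(fit, [pred] * 5, 13.0)
        assert r.p_value == 1.0 and r.test_name == "exact_match"

    def test_unbiased_garden_p_uniform(self, rng):
        fit = self._fit(rng)
        pred = bounded_logistic(13.0, *fit.params)
        ps = []
        for _ in range(200):
            obs = pred + rng.normal(0, 0.03, 7)
            ps.append(validate_against_garden(fit, obs, 13.0).p_value)
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.06
        assert 0.3 < np.mean(ps) < 0.7

    def test_large_offset_detected(self, rng):
        fit = self._fit(rng)
        pred = bounded_logistic(13.0, *fit.params)
        obs = pred + 0.15 + rng.normal(0, 0.03, 7)
        r = validate_against_garden(fit, obs, 13.0)
        assert r.p_value < 1e-3 and r.df == 6


class TestPotentialGroups:
    def test_close_potentials_form_one_group(self):
        df = pd.DataFrame(
            {
                "population_id": ["a", "b", "c"],
                "potential_sexual": [0.40, 0.41, 0.42],
                "mdr": [11.5, 12.5, 13.5],
                "efficiency_sexual": [0.2, 0.3, 0.4],
            }
        )
        groups = potential_matched_groups(df, tolerance=0.02)
        assert len(groups) == 1
        assert groups[0].trend_slope == pytest.approx(0.1)

    def test_distant_potentials_stay_separate(self):
        df = pd.DataFrame(
            {
                "population_id": ["a", "b", "c"],
                "potential_sexual": [0.40, 0.60, 0.80],
                "mdr": [11.0, 12.0, 13.0],
                "efficiency_sexual": [0.2, 0.3, 0.4],
            }
        )
        groups = potential_matched_groups(df, tolerance=0.02)
        assert len(groups) == 3
        assert all(g.trend_slope is None for g in groups)

    def test_positive_trend_recovered_in_noisy_groups(self, rng):
        hits, reps = 0, 40
        for _ in range(reps):
            mdr = rng.uniform(11, 15, 6)
            eff = 0.1 + 0.08 * mdr + rng.normal(0, 0.03, 6)
            df = pd.DataFrame(
                {
                    "population_id": [f"p{i}" for i in range(6)],
                    "potential_sexual": 0.5 + rng.uniform(-0.01, 0.01, 6),
                    "mdr": mdr,
                    "efficiency_sexual": eff,
                }
            )
            groups = potential_matched_groups(df, tolerance=0.02)
            slopes = [g.trend_slope for g in groups if g.trend_slope is not None]
            hits += bool(slopes) and all(s > 0 for s in slopes)
        assert hits / reps >= 0.95
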