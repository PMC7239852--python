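"""Reproductive-pathway statistics: proportions, potentials, efficiency, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aposcape import (
    NoClassifiableError,
    OvuleCounts,
    SeedCounts,
    chi2_goodness_of_fit,
    exact_goodness_of_fit_p,
    expected_seed_proportions,
    observed_proportions,
    parameter_correlations,
    pathway_efficiency,
    pool_counts,
    reproductive_potentials,
    round_half_up,
    season_compare,
    stage_shift_test,
    summarize_population,
)


def ov(mes, aes, mixed, aborted=0, multi=0, pop="p"):
    return OvuleCounts(pop, n_mes_only=mes, n_aes_only=aes, n_mixed=mixed,
                       n_multi_aes=multi, n_aborted=aborted)


class TestObservedProportions:
    @pytest.mark.parametrize("basis", ["competing_only", "shared_credit"])
    def test_symmetric_classes_give_half(self, basis):
        assert observed_proportions(ov(10, 10, 0), basis) == (0.5, 0.5)
        p = observed_proportions(ov(4, 4, 2), basis)
        assert p == pytest.approx((0.5, 0.5))

    def test_seed_counts_direct_ratio(self):
        p = observed_proportions(SeedCounts("p", n_sexual=7, n_apomictic=93))
        assert p == pytest.approx((0.07, 0.93))

    def test_bases_differ_when_mixed_asymmetric(self):
        c = ov(2, 6, 4)
        comp = observed_proportions(c, "competing_only")
        shared = observed_proportions(c, "shared_credit")
        assert comp[0] == pytest.approx(6 / 16)
        assert shared[0] == pytest.approx(4 / 12)

    def test_no_classifiable_raises(self):
        with pytest.raises(NoClassifiableError):
            observed_proportions(ov(0, 0, 0, aborted=5))
        with pytest.raises(NoClassifiableError):
            observed_proportions(SeedCounts("p", 0, 0, n_unclassified=4))

    @given(
        mes=st.integers(0, 200), aes=st.integers(0, 200),
        mixed=st.integers(0, 200), aborted=st.integers(0, 200),
    )
    def test_pair_sums_to_one(self, mes, aes, mixed, aborted):
        if mes + aes + mixed == 0:
            return
        for basis in ("competing_only", "shared_credit"):
            p = observed_proportions(ov(mes, aes, mixed, aborted), basis)
            assert abs(sum(p) - 1.0) < 1e-9
            assert 0.0 <= p[0] <= 1.0


class TestPotentialsAndExpected:
    def test_potentials_formula(self):
        assert reproductive_potentials(ov(3, 5, 2)) == pytest.approx((0.5, 0.7))
        assert reproductive_potentials(ov(12, 0, 0)) == (1.0, 0.0)
        assert reproductive_potentials(ov(0, 8, 0, aborted=2)) == pytest.approx((0.0, 0.8))

    def test_potentials_can_sum_above_one(self):
        s, a = reproductive_potentials(ov(3, 5, 9))
        assert s + a > 1.0

    def test_expected_props_split_mixed_evenly(self):
        assert expected_seed_proportions(ov(2, 2, 2)) == pytest.approx((0.5, 0.5))
        assert expected_seed_proportions(ov(0, 30, 0)) == (0.0, 1.0)

    @given(
        mes=st.integers(0, 100), aes=st.integers(0, 100),
        mixed=st.integers(0, 100), aborted=st.integers(0, 100),
    )
    def test_expected_props_plus_aborted_fraction_is_one(self, mes, aes, mixed, aborted):
        if mes + aes + mixed + aborted == 0:
            return
        c = ov(mes, aes, mixed, aborted)
        e = expected_seed_proportions(c)
        assert e[0] + e[1] + aborted / c.n_total == pytest.approx(1.0, abs=1e-12)


class TestEfficiency:
    def test_identity_when_observed_equals_expected(self):
        assert pathway_efficiency((0.3, 0.7), (0.3, 0.7)) == pytest.approx((1.0, 1.0))

    def test_published_symmetric_population(self):
        # expected 50/50 split collapsing to 7.6% sexual seeds
        eff = pathway_efficiency((0.076, 0.924), (0.500, 0.500))
        assert eff == pytest.approx((0.152, 1.848))

    def test_published_asymmetric_population(self):
        eff = pathway_efficiency((0.068, 0.932), (0.415, 0.585))
        assert eff[0] == pytest.approx(0.164, abs=5e-4)
        assert eff[1] == pytest.approx(1.594, abs=2e-3)

    def test_zero_expected_is_nan_not_infinity(self):
        with pytest.warns(UserWarning, match="undefined"):
            eff = pathway_efficiency((0.1, 0.9), (0.0, 1.0))
        assert np.isnan(eff[0]) and eff[1] == pytest.approx(0.9)


class TestChi2:
    def test_perfect_fit(self):
        chi2, p = chi2_goodness_of_fit((50, 50), (0.5, 0.5))
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_statistic(self):
        # (10-38.2)^2/38.2 + (90-61.8)^2/61.8 = 795.24/38.2 + 795.24/61.8
        chi2, p = chi2_goodness_of_fit((10, 90), (0.382, 0.618))
        assert chi2 == pytest.approx(795.24 / 38.2 + 795.24 / 61.8, rel=1e-12)
        assert chi2 == pytest.approx(33.686, abs=5e-4)

    def test_renormalizes_expected(self):
        a = chi2_goodness_of_fit((30, 70), (0.2, 0.3))
        b = chi2_goodness_of_fit((30, 70), (0.4, 0.6))
        assert a == pytest.approx(b)

    def test_zero_expected_errors(self):
        with pytest.raises(ValueError):
            chi2_goodness_of_fit((5, 5), (0.0, 1.0))

    def test_exact_enumeration_hand_case(self):
        # n=2, fair null: tables (2,0)/(0,2) have chi2=2, (1,1) has 0;
        # tail of chi2 >= 2 is 1/4 + 1/4
        assert exact_goodness_of_fit_p((2, 0), (0.5, 0.5)) == pytest.approx(0.5)
        assert exact_goodness_of_fit_p((1, 1), (0.5, 0.5)) == pytest.approx(1.0)

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        p_asym = chi2_goodness_of_fit((5, 25), (0.5, 0.5))[1]
        p_exact = exact_goodness_of_fit_p((5, 25), (0.5, 0.5))
        assert p_asym == pytest.approx(p_exact, abs=0.01)


class TestStageShift:
    def test_identical_lists(self):
        r = stage_shift_test([0.2, 0.3, 0.4], [0.2, 0.3, 0.4])
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 2

    def test_constant_shift_with_jitter_is_significant(self, rng):
        a = rng.uniform(0.2, 0.6, 12)
        b = a + 0.2 + rng.normal(0, 1e-4, 12)
        r = stage_shift_test(a, b, paired=True)
        assert r.p_value < 1e-3

    def test_zero_variance_nonzero_mean_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = stage_shift_test([0.1, 0.2], [0.3, 0.4])
        assert r.p_value == 0.0

    def test_welch_type_one_error_rate(self, rng):
        hits = 0
        reps = 1000
        for _ in range(reps):
            a, b = rng.normal(size=(2, 10))
            if stage_shift_test(a, b, paired=False).p_value < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 0.02


class TestCorrelations:
    def test_perfect_linear_relations(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "double": 2 * x, "neg": -x})
        r, p = parameter_correlations(df)
        assert r.loc["x", "double"] == pytest.approx(1.0)
        assert r.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T, equal_nan=True)

    def test_independent_uniforms_weakly_correlated(self, rng):
        df = pd.DataFrame(rng.uniform(size=(1000, 2)), columns=["a", "b"])
        r, _ = parameter_correlations(df)
        assert abs(r.loc["a", "b"]) < 0.1

    def test_zero_variance_column_is_nan(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "const": np.ones(10)})
        r, _ = parameter_correlations(df)
        assert np.isnan(r.loc["x", "const"]) and np.isnan(r.loc["const", "const"])


class TestSeasonCompare:
    def _seeds(self, fracs, n=200, season="early"):
        return [
            SeedCounts(f"p{i}", n_sexual=int(round(f * n)),
                       n_apomictic=n - int(round(f * n)), season=season)
            for i, f in enumerate(fracs)
        ]

    def test_identical_seasons(self):
        early = self._seeds([0.1, 0.2, 0.3])
        late = self._seeds([0.1, 0.2, 0.3], season="late")
        r = season_compare(early, late)
        assert r.statistic == pytest.approx(0.0) and r.p_value == pytest.approx(1.0)

    def test_seasonal_shift_detected(self, rng):
        base = rng.normal(0.3, 0.05, 9)
        early = self._seeds(np.clip(base, 0.01, 0.99))
        late = self._seeds(np.clip(base + 0.15, 0.01, 0.99), season="late")
        r = season_compare(early, late)
        assert r.p_value < 0.01
        assert r.test_name == "welch_t"

    def test_welch_close_to_permutation(self, rng):
        pe = rng.uniform(0.1, 0.5, 5)
        pl = rng.uniform(0.1, 0.5, 5)
        early, late = self._seeds(pe), self._seeds(pl, season="late")
        r = season_compare(early, late)
        obs_e = np.array([c.n_sexual / c.n_classified for c in early])
        obs_l = np.array([c.n_sexual / c.n_classified for c in late])
        pooled = np.concatenate([obs_e, obs_l])
        diff_obs = abs(obs_e.mean() - obs_l.mean())
        count = 0
        reps = 2000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            count += abs(perm[:5].mean() - perm[5:].mean()) >= diff_obs - 1e-12
        assert abs(r.p_value - count / reps) < 0.05

    def test_chi2_homogeneity_mode(self):
        early = self._seeds([0.1, 0.4])
        late = self._seeds([0.1, 0.4], season="late")
        r = season_compare(early, late, statistic="chi2_homogeneity")
        assert r.test_name == "chi2_homogeneity" and r.p_value == pytest.approx(1.0)

    def test_single_population_season_errors(self):
        with pytest.raises(ValueError):
            season_compare(self._seeds([0.1]), self._seeds([0.2, 0.3]))


class TestSummaries:
    def test_conservation_observed_equals_efficiency_times_expected(self):
        ovules = [ov(5, 7, 3, aborted=2, pop="pop1"), ov(6, 6, 4, pop="pop1")]
        seeds = [SeedCounts("pop1", n_sexual=9, n_apomictic=61)]
        s = summarize_population(ovules, seeds)
        for i in range(2):
            assert s.obs_seed_props[i] == pytest.approx(
                s.efficiency[i] * s.exp_seed_props[i], abs=1e-12
            )
        assert s.n_ovules == 33 and s.n_seeds == 70

    def test_pooling_sums_counts(self):
        pooled = pool_counts([ov(1, 2, 3, aborted=1), ov(4, 5, 6)])
        assert (pooled.n_mes_only, pooled.n_aes_only, pooled.n_mixed,
                pooled.n_aborted) == (5, 7, 9, 1)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            OvuleCounts("p", n_mes_only=-1, n_aes_only=1, n_mixed=0)
        with pytest.raises(ValueError):
            OvuleCounts("p", n_mes_only=1, n_aes_only=1, n_mixed=1, n_multi_aes=3)
        with pytest.raises(ValueError):
            OvuleCounts("p", n_mes_only=0, n_aes_only=0, n_mixed=0)


@pytest.mark.parametrize(
    "value,expected",
    [(0.1525, 0.153), (0.1524, 0.152), (1.0005, 1.001), (-0.0015, -0.002)],
)
def test_round_half_away_from_zero(value, expected):
    assert round_half_up(value) == expected
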