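"""Variance tests, transforms, AICc selection, and mixed-model recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from herdtrack import inference as inf
from herdtrack.evaluation import simulate_mixed_events


class TestLevene:
    def test_identical_groups_give_zero_F(self):
        res = inf.levene_test([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == 0.0
        assert res.df1 == 1 and res.df2 == 4

    def test_matches_brute_force_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(17)
        values = np.concatenate([rng.normal(0, 1, 25), rng.normal(2, 3, 30)])
        groups = np.array(["a"] * 25 + ["b"] * 30)
        res = inf.levene_test(values, groups)
        devs = []
        for g in ("a", "b"):
            v = values[groups == g]
            devs.append(np.abs(v - np.median(v)))
        z = np.concatenate(devs)
        gmean = z.mean()
        ssb = sum(len(d) * (d.mean() - gmean) ** 2 for d in devs)
        ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
        brute_F = (ssb / 1) / (ssw / (55 - 2))
        assert res.F == pytest.approx(brute_F, rel=1e-12)
        # independent implementation cross-check
        sp = stats.levene(values[groups == "a"], values[groups == "b"], center="median")
        assert res.F == pytest.approx(sp.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_invariant_to_adding_a_constant(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=40)
        g = np.repeat(["a", "b"], 20)
        assert inf.levene_test(v, g).F == pytest.approx(
            inf.levene_test(v + 100.0, g).F, rel=1e-9
        )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            inf.levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestVarianceRatio:
    def test_equal_variances_ratio_one_with_ci_containing_one(self):
        vr = inf.variance_ratio_ci(2.0, 50, 2.0, 50)
        assert vr.ratio == 1.0
        assert vr.ci_low < 1.0 < vr.ci_high

    def test_ratio_invariant_to_common_rescaling(self):
        a = inf.variance_ratio_ci(3.0, 30, 1.5, 40)
        b = inf.variance_ratio_ci(30.0, 30, 15.0, 40)
        assert a.ratio == pytest.approx(b.ratio)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_coverage_against_f_distribution(self):
        # CI from central F quantiles: ~95% coverage under equal variances
        rng = np.random.default_rng(8)
        cover = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(0, 1, 25)
            y = rng.normal(0, 1, 30)
            vr = inf.variance_ratio_ci(x.var(ddof=1), 25, y.var(ddof=1), 30)
            cover += vr.ci_low <= 1.0 <= vr.ci_high
        assert 0.92 < cover / reps < 0.98

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            inf.variance_ratio_ci(0.0, 10, 1.0, 10)


class TestTransforms:
    def test_departure_centered_on_seasonal_median(self):
        df = pd.DataFrame({"departure": [120.0, 124.0, 130.0], "season": ["spring"] * 3})
        out = inf.transform_variables(df, {"departure": ("center_median_by", "season")})
        assert list(out["departure"]) == [-4.0, 0.0, 6.0]

    def test_zscore_standardizes(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(3, 7, 500)})
        out = inf.transform_variables(df, {"x": "zscore"})
        assert abs(out["x"].mean()) < 1e-12
        assert out["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_log_round_trips(self):
        df = pd.DataFrame({"x": [0.5, 2.0, 7.0]})
        out = inf.transform_variables(df, {"x": "log"})
        np.testing.assert_allclose(np.exp(out["x"]), df["x"], rtol=1e-12)

    def test_log_of_nonpositive_names_the_row(self):
        df = pd.DataFrame({"x": [1.0, -2.0]})
        with pytest.raises(ValueError, match="row 1"):
            inf.transform_variables(df, {"x": "log"})


class TestCollinearity:
    def test_duplicated_column_excluded(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        allowed, excluded = inf.collinearity_screen(df, ["a", "b"])
        assert allowed == []
        assert excluded[0][:2] == ("a", "b")
        assert excluded[0][2] == pytest.approx(1.0)

    def test_independent_columns_allowed(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=10_000), "b": rng.normal(size=10_000)})
        allowed, excluded = inf.collinearity_screen(df, ["a", "b"])
        assert allowed == [("a", "b")]
        assert excluded == []

    def test_unit_threshold_excludes_nothing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 4, 6]})
        allowed, excluded = inf.collinearity_screen(df, ["a", "b"], r_max=1.0)
        assert excluded == []

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 4, 6]})
        _, excluded = inf.collinearity_screen(df, ["a", "b"])
        assert np.isnan(excluded[0][2])


class TestAICc:
    def test_worked_formula(self):
        assert inf.aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert inf.aicc(-100.0, 3, 10**9) == pytest.approx(206.0, abs=1e-6)

    def test_matches_brute_force_on_random_tuples(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            ll = rng.normal(-50, 20)
            k = int(rng.integers(1, 8))
            n = int(rng.integers(k + 2, 500))
            assert inf.aicc(ll, k, n) == pytest.approx(
                -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1), rel=1e-12
            )

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            inf.aicc(0.0, 5, 6)


def _cand(terms, k, aicc_val):
    return inf.ModelCandidate(tuple(terms), k, 0.0, aicc_val)


class TestSelectModel:
    def test_simpler_model_within_two_aicc_wins(self):
        sel = inf.select_model([_cand(["a", "b", "c"], 5, 100.0), _cand(["a"], 3, 101.4)])
        assert sel.selected.terms == ("a",)

    def test_model_beyond_two_aicc_not_selected(self):
        sel = inf.select_model([_cand(["a", "b"], 3, 100.0), _cand([], 2, 102.4)])
        assert sel.selected.terms == ("a", "b")

    def test_single_candidate_returned(self):
        sel = inf.select_model([_cand(["a"], 3, 50.0)])
        assert sel.selected.terms == ("a",)

    def test_never_selects_above_the_window(self):
        rng = np.random.default_rng(9)
        cands = [
            _cand([f"t{i}"], int(rng.integers(2, 6)), float(rng.normal(100, 5)))
            for i in range(20)
        ]
        sel = inf.select_model(cands)
        assert sel.selected.delta_aicc <= 2.0


class TestNakagawaR2:
    def test_worked_example(self):
        r2 = inf.nakagawa_r2(1.0, 1.0, 2.0)
        assert r2.r2_marginal == pytest.approx(0.25)
        assert r2.r2_conditional == pytest.approx(0.50)

    def test_no_random_variance_makes_them_equal(self):
        r2 = inf.nakagawa_r2(2.0, 0.0, 3.0)
        assert r2.r2_marginal == r2.r2_conditional

    def test_ordering_invariant(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            vf, vr, ve = rng.uniform(0.01, 5, 3)
            r2 = inf.nakagawa_r2(vf, vr, ve)
            assert 0 <= r2.r2_marginal <= r2.r2_conditional <= 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            inf.nakagawa_r2(0.0, 0.0, 0.0)


class TestCharacteristicModels:
    def test_known_sex_effect_recovered(self):
        df = simulate_mixed_events(n=400, beta_sex=0.35, seed=17)
        rep = inf.fit_characteristic_models(
            df, "y", ["sex", "season", "x"], interactions=[("sex", "season")]
        )
        terms = rep["selection"].selected.terms
        assert "sex" in terms
        est = rep["coefficients"].loc["sex[T.M]", "estimate"]
        assert 0.25 < est < 0.45
        assert 0 <= rep["r2"].r2_marginal <= rep["r2"].r2_conditional <= 1

    def test_logit_effect_sign_recovered(self):
        hits = 0
        for rep_i in range(20):
            df = simulate_mixed_events(n=400, beta_x=1.0, seed=100 + rep_i, binary=True)
            rep = inf.fit_characteristic_models(
                df, "y", ["sex", "x"], engine=inf.BinomialGLMEngine()
            )
            fitted = rep["selection"].selected.result
            if "x" in rep["selection"].selected.terms:
                hits += fitted.coefficients.loc["x", "estimate"] > 0
        assert hits >= 19  # sign recovered in >= 95% of replicates


class TestVarianceComparisonReport:
    def _events(self, male_scale=1.0, seed=0, n=200):
        rng = np.random.default_rng(seed)
        rows = []
        for sex in ("F", "M"):
            scale = male_scale if sex == "M" else 1.0
            for season in ("spring", "autumn"):
                for _ in range(n):
                    rows.append(
                        {
                            "sex": sex,
                            "season": season,
                            "departure": rng.normal(124 if season == "spring" else 260, 15 * scale),
                            "distance_roamed": np.exp(rng.normal(3, 0.5 * scale)),
                            "duration": np.exp(rng.normal(2, 0.5 * scale)),
                            "mean_speed": np.exp(rng.normal(-1, 0.4 * scale)),
                            "n_stopovers": rng.poisson(0.4),
                        }
                    )
        return pd.DataFrame(rows)

    def test_report_has_five_characteristics_by_four_contrasts(self):
        rep = inf.variance_comparison_report(self._events())
        assert len(rep) == 20
        assert rep["characteristic"].nunique() == 5
        assert rep["contrast"].nunique() == 4

    def test_equal_variances_give_unit_ratios(self):
        rep = inf.variance_comparison_report(self._events(seed=5))
        dep = rep[rep["characteristic"] == "departure"]
        assert np.allclose(dep["ratio"], 1.0, atol=0.35)

    def test_known_variance_contrast_detected(self):
        # males 2x the SD -> F/M variance ratio near 1/4 on log scale vars
        rep = inf.variance_comparison_report(self._events(male_scale=2.0, seed=7))
        row = rep[
            (rep["characteristic"] == "duration")
            & (rep["contrast"] == "spring: F vs M")
        ].iloc[0]
        assert 4 ** -1 * 0.75 < row["ratio"] < 4 ** -1 * 1.33
        assert row["levene_p"] < 0.01

    def test_missing_cell_skipped_with_flag(self):
        ev = self._events().query("~(sex == 'M' and season == 'spring')")
        rep = inf.variance_comparison_report(ev)
        skipped = rep[rep["skipped"]]
        assert len(skipped) > 0
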