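import math

import numpy as np
import pandas as pd
import pytest

from pgcvol.cohort_stats import (
    assign_tertiles, fit_poor_sleep_logit, fit_psqi_glm, group_compare,
    interaction_and_mediation, joint_tertile_test, lowess_curve,
)
from pgcvol.phantom import CohortSpec, PGCModel, PSQIModel, make_cohort


def _cohort_from(pgc, psqi, age=None, female=None):
    n = len(pgc)
    return pd.DataFrame({
        "id": np.arange(n),
        "age": np.asarray(age) if age is not None else np.full(n, 50.0),
        "sex": np.asarray(female) if female is not None else np.zeros(n, dtype=int),
        "pgc_uL": np.asarray(pgc, dtype=float),
        "psqi_total": np.asarray(psqi, dtype=float),
        "psqi_poor": np.asarray(psqi) >= 6,
    })


class TestTertiles:
    def test_equal_split_on_1_to_9(self):
        t = assign_tertiles(np.arange(1, 10, dtype=float))
        assert t.counts == (3, 3, 3)
        assert t.cutpoints == (3, 6)
        np.testing.assert_array_equal(t.labels, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_ties_group_to_lower_tertile_matching_sort_partition_oracle(self):
        values = np.array([0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 6, 7], dtype=float)
        t = assign_tertiles(values)
        # oracle: sort, find value at ceil(n/3) and ceil(2n/3), group ties down
        s = np.sort(np.rint(values).astype(int))
        n = len(s)
        c1, c2 = s[math.ceil(n / 3) - 1], s[math.ceil(2 * n / 3) - 1]
        expected = np.where(values <= c1, 1, np.where(values <= c2, 2, 3))
        np.testing.assert_array_equal(t.labels, expected)
        assert sum(t.counts) == n
        assert t.counts[0] > n / 3  # the tied block inflates tertile 1

    def test_skewed_sample_counts_near_balanced(self):
        pgc = make_cohort(CohortSpec(n=1009, seed=21))["pgc_uL"]
        t = assign_tertiles(pgc)
        assert sum(t.counts) == 1009
        for c in t.counts:
            assert 300 <= c <= 380

    def test_labels_monotone_in_value(self):
        rng = np.random.default_rng(5)
        v = rng.gamma(1.0, 50.0, size=200)
        t = assign_tertiles(v)
        order = np.argsort(v)
        assert (np.diff(t.labels[order]) >= 0).all()

    def test_invariant_under_increasing_integer_transform(self):
        rng = np.random.default_rng(6)
        v = rng.integers(0, 200, size=150).astype(float)
        base = assign_tertiles(v)
        for transform in (lambda x: 3 * x + 7, lambda x: x ** 3):
            np.testing.assert_array_equal(
                assign_tertiles(transform(v)).labels, base.labels)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            assign_tertiles([1.0, 2.0])
        with pytest.raises(ValueError, match="distinct"):
            assign_tertiles([1.0, 1.0, 2.0, 2.0, 1.0])


class TestGaussianGLM:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        n = 50
        cohort = _cohort_from(
            pgc=rng.gamma(1.0, 50.0, n),
            psqi=rng.integers(0, 21, n),
            age=rng.uniform(40, 90, n),
            female=rng.integers(0, 2, n),
        )
        t = assign_tertiles(cohort["pgc_uL"])
        fit = fit_psqi_glm(cohort, t, adjust=True)
        # closed-form least squares on a hand-built design matrix
        X = np.column_stack([
            np.ones(n),
            (t.labels == 2).astype(float),
            (t.labels == 3).astype(float),
            cohort["age"],
            cohort["sex"],
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ cohort["psqi_total"].to_numpy())
        got = [fit.terms[k].beta for k in
               ("intercept", "tertile_2", "tertile_3", "age", "female")]
        np.testing.assert_allclose(got, beta, atol=1e-8)
        for term in fit.terms.values():
            assert term.ci_low <= term.beta <= term.ci_high

    def test_constant_outcome_gives_zero_slopes(self):
        rng = np.random.default_rng(9)
        cohort = _cohort_from(pgc=rng.gamma(1.0, 50.0, 60), psqi=np.full(60, 7))
        t = assign_tertiles(cohort["pgc_uL"])
        fit = fit_psqi_glm(cohort, t, adjust=False)
        assert fit.terms["tertile_2"].beta == pytest.approx(0.0, abs=1e-10)
        assert fit.terms["tertile_3"].beta == pytest.approx(0.0, abs=1e-10)
        assert fit.terms["intercept"].beta == pytest.approx(7.0, abs=1e-10)

    def test_planted_tertile_effect_recovered_at_large_n(self):
        spec = CohortSpec(
            n=100_000, seed=13,
            pgc=PGCModel(slope_uL_per_year=0.0),
            psqi=PSQIModel(beta_pgc=0.0, beta_age=0.0, beta_female=0.0,
                           intercept=5.3, beta_tertile2=0.48,
                           beta_tertile3=0.43, noise_sd=2.7),
        )
        cohort = make_cohort(spec)
        t = assign_tertiles(cohort["pgc_uL"])
        fit = fit_psqi_glm(cohort, t, adjust=False)
        assert fit.terms["tertile_2"].beta == pytest.approx(0.48, abs=0.03)
        assert fit.terms["tertile_3"].beta == pytest.approx(0.43, abs=0.03)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(10)
        cohort = _cohort_from(
            pgc=rng.gamma(1.0, 50.0, 40),
            psqi=rng.integers(0, 21, 40),
            age=np.full(40, 60.0),  # constant age duplicates the intercept
        )
        t = assign_tertiles(cohort["pgc_uL"])
        with pytest.raises(ValueError, match="collinear"):
            fit_psqi_glm(cohort, t, adjust=True)


class TestLogit:
    def test_saturated_fit_equals_contingency_log_odds(self):
        # categorical-exposure-only logit is saturated: each tertile
        # coefficient equals the log odds ratio of its 2x2 subtable
        counts = {1: (30, 70), 2: (45, 55), 3: (60, 40)}  # (poor, good)
        pgc, psqi = [], []
        for tert, (poor, good) in counts.items():
            level = {1: 0.0, 2: 50.0, 3: 120.0}[tert]
            pgc += [level] * (poor + good)
            psqi += [10] * poor + [2] * good
        cohort = _cohort_from(np.array(pgc), np.array(psqi))
        t = assign_tertiles(cohort["pgc_uL"])
        assert t.counts == (100, 100, 100)
        fit = fit_poor_sleep_logit(cohort, t, adjust=False)
        for tert, term in ((2, "tertile_2"), (3, "tertile_3")):
            poor, good = counts[tert]
            log_or = math.log((poor / good) / (counts[1][0] / counts[1][1]))
            assert fit.terms[term].beta == pytest.approx(log_or, abs=1e-6)
        ors = fit.odds_ratios()
        assert ors.loc[ors["term"] == "tertile_3", "or"].iloc[0] == pytest.approx(
            math.exp(fit.terms["tertile_3"].beta))

    def test_single_class_outcome_rejected(self):
        rng = np.random.default_rng(11)
        cohort = _cohort_from(pgc=rng.gamma(1.0, 50.0, 60), psqi=np.full(60, 2))
        t = assign_tertiles(cohort["pgc_uL"])
        with pytest.raises(ValueError, match="single class"):
            fit_poor_sleep_logit(cohort, t, adjust=False)

    def test_complete_separation_is_an_error(self):
        pgc = np.repeat([5.0, 50.0, 120.0], 30)
        psqi = np.where(pgc > 10, 10, 2)  # poor iff tertile >= 2
        cohort = _cohort_from(pgc, psqi)
        t = assign_tertiles(cohort["pgc_uL"])
        with pytest.raises(ValueError, match="(?i)separation"):
            fit_poor_sleep_logit(cohort, t, adjust=False)


def _lowess_oracle(x, y, fraction, iterations):
    """Naive per-point weighted polyfit, the independent smoother oracle."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(2, math.ceil(fraction * n))
    rw = np.ones(n)
    for it in range(iterations + 1):
        fitted = np.empty(n)
        for i, x0 in enumerate(xs):
            d = np.sort(np.abs(xs - x0))
            h = d[k - 1]
            w = np.clip(1 - (np.abs(xs - x0) / h) ** 3, 0, None) ** 3 * rw
            coeffs = np.polyfit(xs, ys, 1, w=np.sqrt(w))
            fitted[i] = np.polyval(coeffs, x0)
        if it == iterations:
            return fitted
        resid = ys - fitted
        s = np.median(np.abs(resid))
        rw = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return fitted


class TestLowess:
    def test_reproduces_exact_line(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 100, 40)
        y = 1.5 + 0.03 * x
        curve = lowess_curve(x, y, fraction=0.5, iterations=0)
        np.testing.assert_allclose(curve.y_hat, 1.5 + 0.03 * curve.x_grid,
                                   atol=1e-6)

    def test_constant_y_gives_constant_curve(self):
        rng = np.random.default_rng(13)
        curve = lowess_curve(rng.uniform(0, 10, 25), np.full(25, 4.0))
        np.testing.assert_allclose(curve.y_hat, 4.0, atol=1e-9)

    @pytest.mark.parametrize("iterations", [0, 2])
    def test_matches_brute_force_oracle(self, iterations):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 50, 30)
        y = 3 + 0.1 * x + rng.normal(0, 1.5, 30)
        curve = lowess_curve(x, y, fraction=0.6, iterations=iterations)
        oracle = _lowess_oracle(x, y, 0.6, iterations)
        np.testing.assert_allclose(curve.y_hat, oracle, atol=1e-8)

    def test_full_span_zero_iterations_equals_global_ols(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 10, 60)
        y = 2.0 - 0.4 * x
        curve = lowess_curve(x, y, fraction=1.0, iterations=0)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(curve.y_hat,
                                   intercept + slope * curve.x_grid, atol=1e-6)

    def test_agrees_with_statsmodels_reference(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
        rng = np.random.default_rng(16)
        x = rng.uniform(0, 10, 50)
        y = 2 + 0.5 * x + rng.normal(0, 1, 50)
        # frac * n integral so both implementations use the same window
        curve = lowess_curve(x, y, fraction=0.5, iterations=3)
        ref = sm_lowess(y, x, frac=0.5, it=3, delta=0.0, return_sorted=True)
        np.testing.assert_allclose(curve.y_hat, ref[:, 1], atol=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate x"):
            lowess_curve(np.full(20, 3.0), np.arange(20.0))
        with pytest.raises(ValueError, match="at least 10"):
            lowess_curve(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="fraction"):
            lowess_curve(np.arange(20.0), np.arange(20.0), fraction=1.5)


class TestInteractionMediation:
    def test_difference_of_coefficients_matches_ovb_identity(self):
        # exact finite-sample omitted-variable algebra: the attenuation of
        # each tertile term equals the adjusted covariate effects weighted
        # by auxiliary regressions of the covariates on the tertile dummies
        cohort = make_cohort(CohortSpec(n=2000, seed=17))
        t = assign_tertiles(cohort["pgc_uL"])
        rep = interaction_and_mediation(cohort, t)
        n = len(cohort)
        D = np.column_stack([np.ones(n), (t.labels == 2), (t.labels == 3)]).astype(float)
        gamma_age = rep.adjusted.terms["age"].beta
        gamma_fem = rep.adjusted.terms["female"].beta
        a = np.linalg.lstsq(D, cohort["age"].to_numpy(), rcond=None)[0]
        f = np.linalg.lstsq(D, cohort["sex"].to_numpy(dtype=float), rcond=None)[0]
        for j, term in ((1, "tertile_2"), (2, "tertile_3")):
            expected_delta = gamma_age * a[j] + gamma_fem * f[j]
            _, _, delta = rep.mediation[term]
            assert delta == pytest.approx(expected_delta, abs=1e-8)

    def test_no_confounding_means_no_attenuation(self):
        # age-independent volumes: adjustment should not move the betas
        spec = CohortSpec(n=4000, seed=18, pgc=PGCModel(slope_uL_per_year=0.0),
                          psqi=PSQIModel(beta_pgc=0.004))
        cohort = make_cohort(spec)
        t = assign_tertiles(cohort["pgc_uL"])
        rep = interaction_and_mediation(cohort, t)
        for term in ("tertile_2", "tertile_3"):
            se = (rep.unadjusted.terms[term].ci_high
                  - rep.unadjusted.terms[term].ci_low) / (2 * 1.96)
            assert abs(rep.mediation[term][2]) < 2 * se

    def test_confounded_generator_attenuates_toward_direct_effect(self):
        cohort = make_cohort(CohortSpec(n=20000, seed=19))
        t = assign_tertiles(cohort["pgc_uL"])
        rep = interaction_and_mediation(cohort, t)
        for term in ("tertile_2", "tertile_3"):
            unadj, adj, delta = rep.mediation[term]
            assert delta > 0  # age confounding inflates the crude estimate
            assert adj < unadj

    def test_interaction_null_type_i_error_near_nominal(self):
        rejections = 0
        runs = 200
        for i in range(runs):
            cohort = make_cohort(CohortSpec(n=400, seed=3000 + i))
            t = assign_tertiles(cohort["pgc_uL"])
            rep = interaction_and_mediation(cohort, t)
            rejections += rep.interaction_p < 0.05
        # binomial(200, 0.05): 3 sigma around 10 expected rejections
        assert 0.005 <= rejections / runs <= 0.10


class TestGroupCompare:
    def test_identical_strata_give_zero_difference(self):
        pattern = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        cohort = _cohort_from(
            pgc=np.tile(pattern, 2),
            psqi=np.tile([2.0, 4, 6, 8, 10], 2),
            age=np.repeat([40.0, 70.0], 5),
        )
        rep = group_compare(cohort)
        row = rep.continuous[rep.continuous["variable"] == "pgc_uL"].iloc[0]
        assert row["mean_low"] == row["mean_high"]
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_fisher_path_matches_hypergeometric_enumeration(self):
        # 9/9 vs 0/9 split: expected cells < 5 forces Fisher's exact test
        cohort = _cohort_from(
            pgc=np.arange(18, dtype=float) * 10,
            psqi=np.r_[np.full(9, 10.0), np.full(9, 2.0)],
            age=np.r_[np.full(9, 40.0), np.full(9, 70.0)],
        )
        rep = group_compare(cohort)
        row = rep.categorical[rep.categorical["variable"] == "psqi_poor"].iloc[0]
        assert row["test"] == "fisher"
        # exhaustive hypergeometric two-sided enumeration
        N, K, n = 18, 9, 9
        pmf = [math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
               for k in range(10)]
        observed = pmf[9]
        expected_p = sum(p for p in pmf if p <= observed * (1 + 1e-12))
        assert row["p"] == pytest.approx(expected_p, rel=1e-9)

    def test_planted_age_shift_recovered(self):
        spec = CohortSpec(n=1009, seed=20)
        cohort = make_cohort(spec)
        rep = group_compare(cohort)
        row = rep.continuous[rep.continuous["variable"] == "pgc_uL"].iloc[0]
        shift = row["mean_high"] - row["mean_low"]
        age = cohort["age"]
        low = age <= rep.split_value
        planted = spec.pgc.slope_uL_per_year * (age[~low].mean() - age[low].mean())
        se = math.sqrt(row["sd_low"] ** 2 / rep.n_low
                       + row["sd_high"] ** 2 / rep.n_high)
        assert abs(shift - planted) < 3 * se

    def test_empty_stratum_rejected(self):
        cohort = _cohort_from(pgc=[1.0, 2.0, 3.0], psqi=[1, 2, 3],
                              age=[50.0, 50.0, 50.0])
        with pytest.raises(ValueError, match="empty stratum"):
            group_compare(cohort)


def test_joint_tertile_test_detects_planted_effect():
    spec = CohortSpec(n=5000, seed=22,
                      psqi=PSQIModel(beta_pgc=0.0, beta_tertile2=0.5,
                                     beta_tertile3=1.0))
    cohort = make_cohort(spec)
    t = assign_tertiles(cohort["pgc_uL"])
    stat, p = joint_tertile_test(cohort, t)
    assert p < 1e-6 and stat > 0
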