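"""Statistical core: Welch, chi-squared, ANCOVA, Cohen's d, BH-FDR, and the
random-intercept mixed model with its per-level contrasts."""

import numpy as np
import pandas as pd
import pytest
from cordlevel.stats import (
    ancova,
    bh_fdr,
    chi_squared_2x2,
    cohens_d,
    fit_lme_random_intercept,
    fit_lme_reml,
    group_level_curves,
    per_level_group_contrast,
    standardized_regression,
    welch_t_test,
)


class TestWelch:
    def test_hand_computed_example(self):
        # x=(1,2,3), y=(2,3,4): t = -1/sqrt(2/3), Satterthwaite df = 4
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0, abs=1e-9)
        assert res.p == pytest.approx(0.288, abs=2e-3)

    def test_identical_samples_null(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0 and res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.3, 2, 25)
        a, b = welch_t_test(x, y), welch_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)
        assert a.df == pytest.approx(b.df)

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 3, 30)
        res = welch_t_test(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestChiSquared:
    def test_cohort_sex_table(self):
        # 29F/17M vs 36F/18M: expected counts give X^2 ~ 0.143, not significant
        stat, p = chi_squared_2x2([[29, 17], [36, 18]])
        assert stat == pytest.approx(0.1433, abs=2e-3)
        assert p > 0.05

    def test_equal_proportions_zero(self):
        stat, _ = chi_squared_2x2([[20, 10], [40, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_doubling_counts_doubles_statistic(self):
        s1, _ = chi_squared_2x2([[25, 15], [30, 30]])
        s2, _ = chi_squared_2x2([[50, 30], [60, 60]])
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [3, 4]])


class TestAncova:
    def test_exact_recovery_of_shift(self):
        rng = np.random.default_rng(1)
        n = 60
        group = (np.arange(n) % 2).astype(float)
        age = rng.normal(35, 7, n)
        sex = rng.integers(0, 2, n).astype(float)
        y = 2.0 * group + 0.1 * age - 0.5 * sex + 3.0  # zero noise
        eff, p = ancova(y, group, age, sex)
        assert eff == pytest.approx(2.0, abs=1e-10)

    def test_mirrored_groups_give_zero_effect(self):
        rng = np.random.default_rng(2)
        age = rng.normal(35, 7, 30)
        sex = rng.integers(0, 2, 30).astype(float)
        y = rng.normal(0, 1, 30)
        eff, p = ancova(np.r_[y, y], np.r_[np.zeros(30), np.ones(30)],
                        np.r_[age, age], np.r_[sex, sex])
        assert eff == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_confounded_covariate_absorbs_difference(self):
        # group difference fully mediated by age: adjusted effect ~ 0
        rng = np.random.default_rng(3)
        n = 10_000
        group = rng.integers(0, 2, n).astype(float)
        age = 30 + 5 * group + rng.normal(0, 2, n)
        y = 0.5 * age + rng.normal(0, 0.5, n)
        sex = rng.integers(0, 2, n).astype(float)
        eff, _ = ancova(y, group, age, sex)
        assert abs(eff) < 0.05


class TestCohensD:
    def test_unit_effect(self):
        # construct samples with sample means 1/0 and sample sds exactly 1
        x = np.array([0.0, 1.0, 2.0]) / np.std([0.0, 1.0, 2.0], ddof=1)
        x = x - x.mean() + 1.0
        y = np.array([0.0, 1.0, 2.0]) / np.std([0.0, 1.0, 2.0], ddof=1)
        y = y - y.mean()
        assert cohens_d(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_identical_samples_zero(self):
        assert cohens_d([1.0, 2.0, 5.0], [1.0, 2.0, 5.0]) == 0

    def test_hand_pooled_formula(self):
        x, y = np.array([0.0, 2.0]), np.array([-1.0, 1.0])
        sp = np.sqrt(((1) * 2.0 + (1) * 2.0) / 2)  # both s^2 = 2
        assert cohens_d(x, y) == pytest.approx((1.0 - 0.0) / sp)

    def test_zero_pooled_sd_flagged(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


def brute_force_bh(p):
    """Independent step-up implementation from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


class TestBHFDR:
    def test_step_up_collapse_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_single_p(self):
        assert bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(8)
        p = rng.random(200)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-15)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestLME:
    def _simulate(self, rng, n_sub=30, n_lev=5, sigma_b=0.5, sigma_e=0.3,
                  group_effect=0.0, level_effects=None):
        rows = []
        for i in range(n_sub):
            g = 1.0 if i >= n_sub // 2 else 0.0
            b = rng.normal(0, sigma_b)
            for j in range(n_lev):
                mu = 1.0 + group_effect * g + (
                    level_effects[j] if level_effects is not None else 0.0)
                rows.append((f"s{i:02d}", g, f"L{j}",
                             mu + b + rng.normal(0, sigma_e)))
        df = pd.DataFrame(rows, columns=["subject", "group", "level", "y"])
        return df

    def test_reduces_to_ols_when_no_subject_variance(self):
        rng = np.random.default_rng(10)
        df = self._simulate(rng, sigma_b=0.0, sigma_e=0.4)
        fit = fit_lme_random_intercept(df.y, df.group, df.level, df.subject)
        import statsmodels.api as sm
        from cordlevel.stats import _lme_design
        X, _ = _lme_design(df.group.to_numpy(), df.level.to_numpy(),
                           sorted(df.level.unique()))
        ols = sm.OLS(df.y.to_numpy(), X).fit()
        # REML picks gamma ~ 0, so GLS == OLS
        if fit.sigma_b2 == 0:
            assert np.allclose(fit.beta, ols.params, atol=1e-6)
        else:  # tiny positive gamma can win by chance; estimates still agree
            assert np.allclose(fit.beta, ols.params, atol=1e-3)

    def test_balanced_anova_closed_form(self):
        # balanced one-way random-effects layout: REML variance components
        # equal the expected-mean-squares estimators when MSB > MSE
        rng = np.random.default_rng(12)
        m, k = 40, 6
        b = rng.normal(0, 0.8, m)
        y = 2.0 + np.repeat(b, k) + rng.normal(0, 0.4, m * k)
        subject = np.repeat(np.arange(m), k)
        X = np.ones((m * k, 1))
        fit = fit_lme_reml(y, X, subject)
        ybar_i = y.reshape(m, k).mean(axis=1)
        msb = k * ybar_i.var(ddof=1)
        mse = (y.reshape(m, k) - ybar_i[:, None]).var() * (m * k) / (m * (k - 1))
        assert fit.sigma_e2 == pytest.approx(mse, abs=1e-6)
        assert fit.sigma_b2 == pytest.approx((msb - mse) / k, abs=1e-6)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(13)
        df = self._simulate(rng)
        f1 = fit_lme_random_intercept(df.y, df.group, df.level, df.subject)
        f2 = fit_lme_random_intercept(df.y + 10.0, df.group, df.level,
                                      df.subject)
        assert f2.beta[0] == pytest.approx(f1.beta[0] + 10.0, abs=1e-6)
        assert np.allclose(f2.beta[1:], f1.beta[1:], atol=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        # independent REML implementation as oracle on unbalanced data
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(14)
        df = self._simulate(rng, n_sub=24, n_lev=4, sigma_b=0.6, sigma_e=0.3,
                            group_effect=0.5)
        df = df.drop(index=df.sample(10, random_state=1).index)  # unbalance
        fit = fit_lme_random_intercept(df.y, df.group, df.level, df.subject)
        ref = smf.mixedlm("y ~ group * level", df, groups=df.subject,
                          ).fit(reml=True)
        assert fit.sigma_e2 == pytest.approx(ref.scale, rel=1e-4)
        assert fit.sigma_b2 == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6)
        assert fit.beta[fit.names.index("group")] == pytest.approx(
            ref.params["group"], abs=1e-5)

    def test_contrast_at_reference_level_is_group_beta(self):
        rng = np.random.default_rng(15)
        df = self._simulate(rng, group_effect=0.4)
        fit = fit_lme_random_intercept(df.y, df.group, df.level, df.subject)
        c = per_level_group_contrast(fit, fit.reference_level)
        assert c.estimate == pytest.approx(
            fit.beta[fit.names.index("group")], abs=1e-12)

    def test_localized_effect_flagged_only_where_inserted(self):
        rng = np.random.default_rng(16)
        hits, false = [], []
        for _ in range(10):
            effects = [0.0] * 8
            for j in (3, 4, 5):
                effects[j] = 1.0  # large, localized group x level effect
            df = self._simulate(rng, n_sub=50, n_lev=8, sigma_b=0.4,
                                sigma_e=0.25, group_effect=0.0,
                                level_effects=None)
            # add the interaction by hand
            sel = df.level.isin(["L3", "L4", "L5"]) & (df.group == 1.0)
            df.loc[sel, "y"] += 0.6
            fit = fit_lme_random_intercept(df.y, df.group, df.level,
                                           df.subject)
            for lv in fit.levels:
                c = per_level_group_contrast(fit, lv)
                (hits if lv in ("L3", "L4", "L5") else false).append(
                    c.significant)
        assert np.mean(hits) >= 0.9
        assert np.mean(false) <= 0.1

    def test_single_observation_per_subject_boundary(self):
        rng = np.random.default_rng(17)
        n = 40
        y = rng.normal(0, 1, n)
        group = (np.arange(n) % 2).astype(float)
        level = np.array(["L0"] * n)
        fit = fit_lme_random_intercept(y, group, level,
                                       np.arange(n).astype(str))
        assert fit.sigma_b2 == 0.0


class TestStandardizedRegression:
    def test_perfect_association_gives_unit_b1(self):
        rng = np.random.default_rng(18)
        imaging = rng.normal(10, 2, 50)
        age = rng.normal(35, 5, 50)
        sex = rng.integers(0, 2, 50).astype(float)
        dx = rng.integers(0, 2, 50).astype(float)
        b1, p = standardized_regression(imaging, imaging, age, sex, dx)
        assert b1 == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(19)
        n = 4000
        b1, p = standardized_regression(
            rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(35, 5, n),
            rng.integers(0, 2, n).astype(float),
            rng.integers(0, 2, n).astype(float))
        assert abs(b1) < 0.05

    def test_zero_variance_imaging_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardized_regression(np.arange(10.0), np.ones(10),
                                    np.arange(10.0), np.zeros(10),
                                    np.zeros(10))


class TestCurves:
    def _profile(self, values_by_subject):
        rows = []
        for sid, v in values_by_subject.items():
            rows.append(dict(subject_id=sid, region="cord", sublevel="C2.0",
                             metric="FA", value=v, n_voxels=10))
        return pd.DataFrame(rows)

    def _records(self, sids):
        return pd.DataFrame([dict(id=s, group="HC", age=30.0, sex="F",
                                  edss=None, tug_s=6.0, t25_s=4.0)
                             for s in sids])

    def test_identical_subjects_zero_width(self):
        prof = self._profile({f"s{i}": 0.6 for i in range(8)})
        out = group_level_curves(prof, self._records(prof.subject_id))
        assert out.ci95.iloc[0] == 0

    def test_ci_shrinks_with_sqrt_n(self):
        vals = {f"s{i}": v for i, v in enumerate([0.5, 0.7] * 4)}
        out1 = group_level_curves(self._profile(vals),
                                  self._records(list(vals)))
        vals2 = {f"t{i}": v for i, v in enumerate([0.5, 0.7] * 8)}
        out2 = group_level_curves(self._profile(vals2),
                                  self._records(list(vals2)))
        # exact half-width formula, and ~1/sqrt(2) shrinkage on doubling
        assert out2.ci95.iloc[0] == pytest.approx(
            1.96 * np.std(list(vals2.values()), ddof=1) / 4, rel=1e-9)
        assert out2.ci95.iloc[0] == pytest.approx(
            out1.ci95.iloc[0] / np.sqrt(2), rel=0.05)
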