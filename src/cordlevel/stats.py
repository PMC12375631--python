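"""Group-comparison and clinical-association statistics over level profiles.

Implements the battery applied to the along-level tables: Welch's t-test on
per-subject region means, chi-squared for sex composition, ANCOVA for
clinical scores, Cohen's d effect sizes, a per-(region, metric)
random-intercept linear mixed model ``value ~ group * sublevel + (1 |
subject)`` with per-sub-level group contrasts, standardized multivariable
regressions of clinical scores on imaging features, and Benjamini-Hochberg
FDR control.

The mixed model is fitted by REML with the variance ratio
gamma = sigma_b^2 / sigma_eps^2 profiled out: for fixed gamma the GLS
solution is closed-form (V = I + gamma Z Z', block-diagonal by subject), and
gamma is maximized by bounded one-dimensional search. Contrast p-values use
the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_GROUP = 0.05
ALPHA_LEVEL = 0.01
ALPHA_FDR = 0.05


# ---------------------------------------------------------------------------
# Elementary tests


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float


def welch_t_test(x, y) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t-test requires n >= 2 in each sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        return WelchResult(0.0, float(nx + ny - 2), 1.0,
                           float(x.mean()), float(y.mean()))
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p),
                       float(x.mean()), float(y.mean()))


def chi_squared_2x2(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("counts must be a nonnegative 2x2 table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("chi-squared requires all margins > 0")
    stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def ancova(outcome, group, age, sex) -> tuple[float, float]:
    """Adjusted group effect: OLS of outcome ~ group + age + sex.

    ``group`` and ``sex`` are 0/1 indicators. Returns (group coefficient,
    two-sided p from its t-test).
    """
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.asarray(group, dtype=float),
                         np.asarray(age, dtype=float),
                         np.asarray(sex, dtype=float)])
    X = sm.add_constant(X)
    if len(y) <= X.shape[1]:
        raise ValueError("ANCOVA needs more observations than parameters")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def cohens_d(x, y) -> float:
    """Difference in means over the pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Cohen's d requires n >= 2 in each sample")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (REML, profiled variance ratio)


@dataclass
class LMEFit:
    beta: np.ndarray
    names: list[str]
    cov_beta: np.ndarray
    sigma_b2: float
    sigma_e2: float
    loglik_reml: float
    converged: bool
    levels: list[str]
    reference_level: str

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components out of range")


def _lme_design(group: np.ndarray, level: np.ndarray,
                levels_order: list[str]) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design: intercept, group, level dummies (first level is
    the reference), group x level dummies."""
    n = len(group)
    k = len(levels_order)
    cols = [np.ones(n), group.astype(float)]
    names = ["intercept", "group"]
    for lv in levels_order[1:]:
        cols.append((level == lv).astype(float))
        names.append(f"level[{lv}]")
    for lv in levels_order[1:]:
        cols.append(group.astype(float) * (level == lv))
        names.append(f"group:level[{lv}]")
    return np.column_stack(cols), names


def fit_lme_reml(y, X, subject, names: list[str] | None = None,
                 gamma_max: float = 1e6) -> LMEFit:
    """REML fit of ``y = X beta + b_subject + eps`` with a random intercept.

    The variance ratio gamma = sigma_b^2 / sigma_eps^2 is profiled: for
    each gamma the GLS estimate and the residual variance are closed-form
    (V = I + gamma Z Z' is block diagonal by subject), and the restricted
    log-likelihood is maximized over gamma in [0, gamma_max] by bounded
    scalar minimization. With one observation per subject sigma_b^2 is not
    identifiable and is returned at the boundary 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    subject = np.asarray(subject)
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effects design is rank deficient")

    subj_ids, subj_inv = np.unique(subject, return_inverse=True)
    m = len(subj_ids)
    n_i = np.bincount(subj_inv)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-subject row sums of X and y
    Sx = np.zeros((m, p))
    np.add.at(Sx, subj_inv, X)
    Sy = np.bincount(subj_inv, weights=y)

    def gls(gamma: float):
        w = gamma / (1.0 + gamma * n_i)  # (m,)
        A = XtX - (Sx * w[:, None]).T @ Sx
        b = Xty - Sx.T @ (w * Sy)
        yVy = yty - float(w @ Sy**2)
        beta = np.linalg.solve(A, b)
        rss = yVy - float(beta @ b)
        logdetV = float(np.sum(np.log1p(gamma * n_i)))
        _, logdetA = np.linalg.slogdet(A)
        return beta, A, max(rss, 1e-300), logdetV, logdetA

    def neg2_reml(gamma: float) -> float:
        _, _, rss, logdetV, logdetA = gls(gamma)
        s2 = rss / (n - p)
        return (n - p) * np.log(s2) + logdetV + logdetA

    converged = True
    if m == n:  # one observation per subject: gamma not identifiable
        gamma_hat = 0.0
    else:
        res = optimize.minimize_scalar(
            neg2_reml, bounds=(0.0, gamma_max), method="bounded",
            options={"xatol": 1e-10})
        gamma_hat = float(res.x)
        converged = bool(res.success)
        # the boundary gamma = 0 is admissible; prefer it when it is as good
        if neg2_reml(0.0) <= res.fun + 1e-10:
            gamma_hat = 0.0
        if gamma_hat > 0.999 * gamma_max:
            converged = False  # boundary solution reported, flagged

    beta, A, rss, logdetV, logdetA = gls(gamma_hat)
    sigma_e2 = rss / (n - p)
    sigma_b2 = gamma_hat * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(A)
    loglik = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma_e2) + 1)
                     + logdetV + logdetA)
    return LMEFit(beta=beta, names=names, cov_beta=cov_beta,
                  sigma_b2=float(sigma_b2), sigma_e2=float(sigma_e2),
                  loglik_reml=float(loglik), converged=converged,
                  levels=[], reference_level="")


def fit_lme_random_intercept(y, group, level, subject,
                             gamma_max: float = 1e6) -> LMEFit:
    """REML fit of ``y ~ group * level + (1 | subject)``.

    ``group``: 0/1 per observation; ``level``: categorical labels (the
    first in sorted order is the reference); ``subject``: hashable ids.
    """
    group = np.asarray(group)
    level = np.asarray(level)
    levels_order = sorted(pd.unique(level).tolist())
    X, names = _lme_design(group, level, levels_order)
    try:
        fit = fit_lme_reml(y, X, subject, names=names, gamma_max=gamma_max)
    except ValueError as exc:
        raise ValueError(f"{exc} (empty group x level cells?)") from exc
    fit.levels = levels_order
    fit.reference_level = levels_order[0]
    return fit


@dataclass(frozen=True)
class LevelContrast:
    sublevel: str
    estimate: float
    se: float
    p: float
    significant: bool


def per_level_group_contrast(fit: LMEFit, sublevel: str,
                             alpha: float = ALPHA_LEVEL) -> LevelContrast:
    """Group difference at one sub-level: beta_group (+ interaction term)."""
    if sublevel not in fit.levels:
        raise ValueError(f"sub-level {sublevel!r} absent from the fitted design")
    c = np.zeros(len(fit.beta))
    c[fit.names.index("group")] = 1.0
    if sublevel != fit.reference_level:
        c[fit.names.index(f"group:level[{sublevel}]")] = 1.0
    est = float(c @ fit.beta)
    se = float(np.sqrt(c @ fit.cov_beta @ c))
    z = est / se if se > 0 else 0.0
    p = float(2 * sps.norm.sf(abs(z)))
    return LevelContrast(sublevel, est, se, p, p < alpha)


# ---------------------------------------------------------------------------
# Standardized clinical association


@dataclass(frozen=True)
class AssociationResult:
    clinical: str
    region: str
    sublevel: str
    metric: str
    b1: float
    p: float
    q: float = np.nan
    significant: bool = False


def standardized_regression(clinical, imaging, age, sex, diagnosis
                            ) -> tuple[float, float]:
    """Standardized coefficient of the imaging feature.

    Fits ``clinical ~ imaging + age + sex + diagnosis`` with continuous
    variables centered/scaled over the analysis sample and sex/diagnosis as
    0/1 indicators. Returns (B1, two-sided p).
    """
    def z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance variable in standardized regression")
        return (v - v.mean()) / sd

    cl = np.asarray(clinical, dtype=float)
    im = np.asarray(imaging, dtype=float)
    ok = np.isfinite(cl) & np.isfinite(im)
    cl, im = cl[ok], im[ok]
    age = np.asarray(age, dtype=float)[ok]
    sex = np.asarray(sex, dtype=float)[ok]
    dx = np.asarray(diagnosis, dtype=float)[ok]
    if len(cl) <= 5:
        raise ValueError("standardized regression needs more than 5 complete cases")
    X = sm.add_constant(np.column_stack([z(im), z(age), sex, dx]))
    fit = sm.OLS(z(cl), X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Profile-table drivers


def subject_region_means(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean of each (region, metric) over its sub-levels
    (C2.0-C5.8, unweighted; pooled 'all' lesion rows are excluded)."""
    df = profile[profile.sublevel != "all"]
    return (df.groupby(["subject_id", "region", "metric"], as_index=False)
              .value.mean())


def group_comparison_table(profile: pd.DataFrame, records: pd.DataFrame,
                           alpha: float = ALPHA_GROUP) -> pd.DataFrame:
    """Welch's t-test on per-subject region means, HC vs patients.

    Sign convention: statistics are (pwRRMS - HC), so a deficit in patients
    is negative.
    """
    means = subject_region_means(profile)
    merged = means.merge(records[["id", "group"]],
                         left_on="subject_id", right_on="id")
    rows = []
    for (region, metric), sub in merged.groupby(["region", "metric"]):
        hc = sub.loc[sub.group == "HC", "value"].to_numpy()
        ms = sub.loc[sub.group == "pwRRMS", "value"].to_numpy()
        if len(hc) < 2 or len(ms) < 2:
            continue
        res = welch_t_test(ms, hc)
        rows.append(dict(region=region, metric=metric,
                         mean_hc=res.mean_y, mean_ms=res.mean_x,
                         t=res.t, df=res.df, p=res.p,
                         significant=res.p < alpha))
    return pd.DataFrame(rows).sort_values(["region", "metric"]).reset_index(drop=True)


def effect_size_table(profile: pd.DataFrame, records: pd.DataFrame,
                      alpha: float = ALPHA_LEVEL) -> pd.DataFrame:
    """Cohen's d (pwRRMS - HC) per (region, metric) at every sub-level and
    for the per-subject region mean ('mean' row); significance flag from
    Welch's test at the pathway-analysis threshold."""
    df = profile[profile.sublevel != "all"].merge(
        records[["id", "group"]], left_on="subject_id", right_on="id")
    rows = []
    group_cells = [*df.groupby(["region", "metric", "sublevel"])]
    means = subject_region_means(profile).merge(
        records[["id", "group"]], left_on="subject_id", right_on="id")
    for (region, metric), sub in means.groupby(["region", "metric"]):
        group_cells.append(((region, metric, "mean"), sub))
    for (region, metric, sublevel), sub in group_cells:
        hc = sub.loc[sub.group == "HC", "value"].to_numpy()
        ms = sub.loc[sub.group == "pwRRMS", "value"].to_numpy()
        if len(hc) < 2 or len(ms) < 2:
            continue
        try:
            d = cohens_d(ms, hc)
        except ValueError:
            continue
        p = welch_t_test(ms, hc).p
        rows.append(dict(region=region, metric=metric, sublevel=sublevel,
                         d=d, p=p, significant=p < alpha))
    return pd.DataFrame(rows).sort_values(
        ["region", "metric", "sublevel"]).reset_index(drop=True)


def level_contrast_table(profile: pd.DataFrame, records: pd.DataFrame,
                         regions: list[str] | None = None,
                         metrics: list[str] | None = None,
                         alpha: float = ALPHA_LEVEL) -> pd.DataFrame:
    """Per-sub-level group contrasts from the random-intercept mixed model,
    one model per (region, metric) across all its sub-levels."""
    df = profile[(profile.sublevel != "all")
                 & (profile.metric != "lesion_load")].merge(
        records[["id", "group"]], left_on="subject_id", right_on="id")
    if regions is not None:
        df = df[df.region.isin(regions)]
    if metrics is not None:
        df = df[df.metric.isin(metrics)]
    rows = []
    for (region, metric), sub in df.groupby(["region", "metric"]):
        g = (sub.group == "pwRRMS").to_numpy().astype(float)
        fit = fit_lme_random_intercept(sub.value.to_numpy(), g,
                                       sub.sublevel.to_numpy(),
                                       sub.subject_id.to_numpy())
        for lv in fit.levels:
            c = per_level_group_contrast(fit, lv, alpha=alpha)
            rows.append(dict(region=region, metric=metric, sublevel=lv,
                             estimate=c.estimate, se=c.se, p=c.p,
                             significant=c.significant,
                             sigma_b2=fit.sigma_b2, sigma_e2=fit.sigma_e2,
                             converged=fit.converged))
    return pd.DataFrame(rows).sort_values(
        ["region", "metric", "sublevel"]).reset_index(drop=True)


def association_scan(profile: pd.DataFrame, records: pd.DataFrame,
                     clinical_measures: tuple[str, ...] = ("TUG", "T25", "EDSS"),
                     regions: list[str] | None = None,
                     metrics: list[str] | None = None,
                     alpha_fdr: float = ALPHA_FDR) -> pd.DataFrame:
    """Standardized association of each imaging cell with each clinical
    measure, BH-FDR adjusted within one family per (clinical, metric)."""
    col_map = {"TUG": "tug_s", "T25": "t25_s", "EDSS": "edss"}
    df = profile[(profile.sublevel != "all")
                 & (profile.metric != "lesion_load")]
    if regions is not None:
        df = df[df.region.isin(regions)]
    if metrics is not None:
        df = df[df.metric.isin(metrics)]
    wide = df.merge(records, left_on="subject_id", right_on="id")
    wide["dx"] = (wide.group == "pwRRMS").astype(float)
    wide["male"] = (wide.sex == "M").astype(float)
    rows = []
    for clinical in clinical_measures:
        ccol = col_map[clinical]
        for (region, metric, sublevel), sub in wide.groupby(
                ["region", "metric", "sublevel"]):
            try:
                b1, p = standardized_regression(
                    sub[ccol], sub.value, sub.age, sub.male, sub.dx)
            except ValueError:
                continue
            rows.append(dict(clinical=clinical, region=region, metric=metric,
                             sublevel=sublevel, b1=b1, p=p))
    out = pd.DataFrame(rows, columns=["clinical", "region", "metric",
                                      "sublevel", "b1", "p"])
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["clinical", "metric"]).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    out["significant"] = out.q < alpha_fdr
    return out.sort_values(["clinical", "metric", "region",
                            "sublevel"]).reset_index(drop=True)


def group_level_curves(profile: pd.DataFrame, records: pd.DataFrame
                       ) -> pd.DataFrame:
    """Per-(region, metric, sublevel, group) mean and 95% CI half-width;
    cells with fewer than two subjects are absent."""
    df = profile[profile.sublevel != "all"].merge(
        records[["id", "group"]], left_on="subject_id", right_on="id")
    rows = []
    for (region, metric, sublevel, group), sub in df.groupby(
            ["region", "metric", "sublevel", "group"]):
        n = len(sub)
        if n < 2:
            continue
        se = sub.value.std(ddof=1) / np.sqrt(n)
        rows.append(dict(region=region, metric=metric, sublevel=sublevel,
                         group=group, mean=sub.value.mean(),
                         ci95=1.96 * se, n=n))
    return pd.DataFrame(rows).sort_values(
        ["region", "metric", "sublevel", "group"]).reset_index(drop=True)


def demographics_table(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort-composition comparisons: Welch on age, chi-squared on sex,
    ANCOVA (age- and sex-adjusted) on TUG and T25."""
    hc = records[records.group == "HC"]
    ms = records[records.group == "pwRRMS"]
    rows = []
    age = welch_t_test(ms.age, hc.age)
    rows.append(dict(variable="age", test="welch", statistic=age.t, p=age.p,
                     hc=age.mean_y, ms=age.mean_x))
    tab = [[int((hc.sex == "F").sum()), int((hc.sex == "M").sum())],
           [int((ms.sex == "F").sum()), int((ms.sex == "M").sum())]]
    try:
        stat, p = chi_squared_2x2(tab)
    except ValueError:  # a sex absent entirely (tiny cohorts)
        stat, p = np.nan, np.nan
    rows.append(dict(variable="sex", test="chi2", statistic=stat, p=p,
                     hc=tab[0][0] / len(hc), ms=tab[1][0] / len(ms)))
    dx = (records.group == "pwRRMS").astype(float)
    male = (records.sex == "M").astype(float)
    for var in ("tug_s", "t25_s"):
        if records[var].notna().all():
            try:
                eff, p = ancova(records[var], dx, records.age, male)
            except ValueError:  # too few subjects or degenerate design
                eff, p = np.nan, np.nan
            rows.append(dict(variable=var, test="ancova", statistic=eff, p=p,
                             hc=hc[var].mean(), ms=ms[var].mean()))
    return pd.DataFrame(rows)


def normalize_for_display(values: np.ndarray, half_range: float = 1.0
                          ) -> np.ndarray:
    """Scale by the max absolute value into [-half_range, half_range];
    render-time only, never stored in results tables."""
    v = np.asarray(values, dtype=float)
    peak = np.nanmax(np.abs(v))
    return v if peak == 0 else v * (half_range / peak)
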