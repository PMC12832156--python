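"""Cohort association analysis for calcification volume and sleep quality.

Reproduces a standard epidemiological workflow: the exposure (calcified
volume in microlitres) is rounded to integer microlitres and split into
tertiles; the continuous PSQI total is modelled with a Gaussian
identity-link GLM and the binary poor-sleep class with a logistic model,
each unadjusted and adjusted for age and sex; a Cleveland LOWESS smoother
shows the continuous dose-response; median-age stratification, an
age-by-tertile interaction test, and a descriptive difference-of-
coefficients mediation summary complete the picture.

Model fitting is delegated to statsmodels; confidence intervals are Wald
intervals and p-values are two-sided.  The LOWESS smoother is implemented
here so its neighbour-count and weighting conventions are exactly the
documented ones (tricube weights over the nearest ``ceil(fraction * n)``
points, optional bisquare robustness passes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools import sm_exceptions

__all__ = [
    "TertileAssignment",
    "ModelTerm",
    "ModelFit",
    "LowessCurve",
    "assign_tertiles",
    "fit_psqi_glm",
    "fit_poor_sleep_logit",
    "lowess_curve",
    "joint_tertile_test",
    "interaction_and_mediation",
    "group_compare",
    "InteractionMediationReport",
    "GroupCompareReport",
]


# ---------------------------------------------------------------------------
# tertiles
# ---------------------------------------------------------------------------

@dataclass
class TertileAssignment:
    """Tertile split of rounded exposure values.

    ``cutpoints`` are the two boundary values in integer microlitres; every
    row whose rounded value is <= the first boundary is tertile 1, <= the
    second is tertile 2, else tertile 3.  All rows sharing a boundary value
    land in the same (lower) tertile, so counts may be unequal.
    """

    cutpoints: tuple[int, int]
    labels: np.ndarray
    counts: tuple[int, int, int]

    @property
    def n(self) -> int:
        return int(self.labels.size)


def assign_tertiles(values) -> TertileAssignment:
    """Split exposure values into tertiles at the empirical 1/3 and 2/3 points.

    Values are rounded to integer microlitres first; ties at a boundary are
    grouped into the lower tertile.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be 1-D")
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 values to form tertiles")
    if np.any(~np.isfinite(v)):
        raise ValueError("values must be finite")
    vi = np.rint(v).astype(int)
    if np.unique(vi).size < 3:
        raise ValueError("fewer than 3 distinct rounded values; tertiles undefined")
    s = np.sort(vi)
    c1 = int(s[math.ceil(n / 3) - 1])
    c2 = int(s[math.ceil(2 * n / 3) - 1])
    labels = np.where(vi <= c1, 1, np.where(vi <= c2, 2, 3))
    counts = tuple(int((labels == t).sum()) for t in (1, 2, 3))
    return TertileAssignment(cutpoints=(c1, c2), labels=labels, counts=counts)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

@dataclass
class ModelTerm:
    name: str
    beta: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelFit:
    """Named coefficients of one fitted regression model."""

    family: str  # "gaussian-identity" or "binomial-logit"
    n: int
    terms: dict[str, ModelTerm]

    def table(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "beta": t.beta, "ci_low": t.ci_low,
             "ci_high": t.ci_high, "p": t.p}
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows)

    def odds_ratios(self) -> pd.DataFrame:
        if self.family != "binomial-logit":
            raise ValueError("odds ratios are defined for logistic fits only")
        rows = [
            {"term": t.name, "or": math.exp(t.beta),
             "ci_low": math.exp(t.ci_low), "ci_high": math.exp(t.ci_high),
             "p": t.p}
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows)


_TERM_MAP = {
    "Intercept": "intercept",
    "C(tertile)[T.2]": "tertile_2",
    "C(tertile)[T.3]": "tertile_3",
    "age": "age",
    "female": "female",
    "C(tertile)[T.2]:age": "tertile_2:age",
    "C(tertile)[T.3]:age": "tertile_3:age",
}


def _model_frame(cohort: pd.DataFrame, tertiles: TertileAssignment) -> pd.DataFrame:
    if len(cohort) != tertiles.n:
        raise ValueError(
            f"cohort has {len(cohort)} rows but tertile assignment has {tertiles.n}"
        )
    df = cohort.reset_index(drop=True).copy()
    df["tertile"] = tertiles.labels
    if "female" not in df.columns:
        df["female"] = df["sex"].astype(int)
    return df


def _check_full_rank(res) -> None:
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name one offending column for the error message
        names = res.model.exog_names
        for j in range(exog.shape[1]):
            others = np.delete(exog, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(f"rank-deficient design: column '{names[j]}' "
                                 "is collinear with the others")
        raise ValueError("rank-deficient design matrix")


def _extract_fit(res, family: str) -> ModelFit:
    ci = res.conf_int()
    terms: dict[str, ModelTerm] = {}
    for raw in res.params.index:
        name = _TERM_MAP.get(raw, raw)
        terms[name] = ModelTerm(
            name=name,
            beta=float(res.params[raw]),
            ci_low=float(ci.loc[raw, 0]),
            ci_high=float(ci.loc[raw, 1]),
            p=float(res.pvalues[raw]),
        )
    return ModelFit(family=family, n=int(res.nobs), terms=terms)


def fit_psqi_glm(cohort: pd.DataFrame, tertiles: TertileAssignment,
                 adjust: bool = False) -> ModelFit:
    """Gaussian identity-link GLM of the PSQI total on exposure tertiles.

    Tertile 1 is the referent; with ``adjust`` the model also includes age
    (years) and a female indicator.  Reports beta, Wald 95% CI and
    two-sided p per term.
    """
    df = _model_frame(cohort, tertiles)
    formula = "psqi_total ~ C(tertile)"
    if adjust:
        formula += " + age + female"
    model = smf.glm(formula, data=df, family=sm.families.Gaussian())
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("not enough rows to fit the requested model")
    if np.ptp(model.endog) == 0:
        # degenerate outcome: the IRLS scale estimate is 0, so fit the
        # identical least-squares problem directly (slopes come out 0)
        res = smf.ols(formula, data=df).fit()
    else:
        res = model.fit()
    _check_full_rank(res)
    return _extract_fit(res, "gaussian-identity")


def fit_poor_sleep_logit(cohort: pd.DataFrame, tertiles: TertileAssignment,
                         adjust: bool = False) -> ModelFit:
    """Logistic model of the binary poor-sleep class on exposure tertiles.

    Coefficients are log odds; ``ModelFit.odds_ratios`` exponentiates them.
    Complete separation raises a ``ValueError`` rather than diverging
    silently.
    """
    df = _model_frame(cohort, tertiles)
    y = df["psqi_poor"].astype(int)
    if y.nunique() < 2:
        raise ValueError("poor-sleep outcome has a single class; cannot fit logit")
    df["psqi_poor_int"] = y
    formula = "psqi_poor_int ~ C(tertile)"
    if adjust:
        formula += " + age + female"
    model = smf.logit(formula, data=df)
    try:
        with warnings.catch_warnings():
            # statsmodels only warns on separation; an unidentified MLE is
            # an error here, not a result
            warnings.simplefilter("error",
                                  sm_exceptions.PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(disp=0)
    except (sm_exceptions.PerfectSeparationError,
            sm_exceptions.PerfectSeparationWarning) as exc:
        raise ValueError(f"complete separation in logistic fit: {exc}") from exc
    _check_full_rank(res)
    return _extract_fit(res, "binomial-logit")


def joint_tertile_test(cohort: pd.DataFrame, tertiles: TertileAssignment,
                       adjust: bool = False) -> tuple[float, float]:
    """Joint Wald test that both tertile coefficients are zero.

    Returns ``(chi2 statistic, p-value)`` from the Gaussian PSQI model.
    """
    df = _model_frame(cohort, tertiles)
    formula = "psqi_total ~ C(tertile)"
    if adjust:
        formula += " + age + female"
    res = smf.glm(formula, data=df, family=sm.families.Gaussian()).fit()
    _check_full_rank(res)
    wald = res.wald_test(
        ["C(tertile)[T.2] = 0", "C(tertile)[T.3] = 0"], scalar=True
    )
    return float(wald.statistic), float(wald.pvalue)


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------

@dataclass
class LowessCurve:
    """Smoothed dose-response curve evaluated at the sorted x values."""

    x_grid: np.ndarray
    y_hat: np.ndarray
    fraction: float
    iterations: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x_grid, "y_hat": self.y_hat})


def _local_fit(x: np.ndarray, y: np.ndarray, x0: float, k: int,
               robust_w: np.ndarray) -> float:
    """Tricube-weighted linear fit over the k nearest points, value at x0."""
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1]
    if h <= 0:
        # >= k points share this x; fall back to their (robust) mean
        sel = d == 0
        w = robust_w[sel]
        if w.sum() <= 0:
            return float(np.mean(y[sel]))
        return float(np.sum(w * y[sel]) / w.sum())
    u = np.clip(d / h, 0.0, 1.0)
    w = (1.0 - u ** 3) ** 3
    w *= robust_w
    sw = w.sum()
    if sw <= 0:
        return float(np.nan)
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return float(ym)
    b = np.sum(w * (x - xm) * (y - ym)) / sxx
    return float(ym + b * (x0 - xm))


def lowess_curve(x, y, fraction: float = 2.0 / 3.0,
                 iterations: int = 3) -> LowessCurve:
    """Cleveland-style locally weighted scatterplot smoother.

    For each point of the sorted x grid, fits a weighted local line over
    the nearest ``ceil(fraction * n)`` points with tricube distance
    weights; ``iterations`` robustness passes down-weight large residuals
    by the bisquare function of r / (6 * median|r|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    k = max(2, math.ceil(fraction * n))
    k = min(k, n)

    robust_w = np.ones(n)
    y_hat = np.empty(n)
    for it in range(iterations + 1):
        for i in range(n):
            y_hat[i] = _local_fit(xs, ys, xs[i], k, robust_w)
        if it == iterations:
            break
        resid = ys - y_hat
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        robust_w = (1.0 - u ** 2) ** 2
    return LowessCurve(x_grid=xs, y_hat=y_hat, fraction=fraction,
                       iterations=iterations)


# ---------------------------------------------------------------------------
# interaction, mediation, group comparison
# ---------------------------------------------------------------------------

@dataclass
class InteractionMediationReport:
    """Age-by-tertile interaction test plus a descriptive mediation summary.

    ``mediation`` maps each tertile term to (unadjusted beta, age/sex-
    adjusted beta, difference).  The difference of coefficients is
    descriptive — the share of the crude association accounted for by the
    covariates — not a formal causal-mediation estimand.
    """

    interaction_p: float
    unadjusted: ModelFit
    adjusted: ModelFit
    mediation: dict[str, tuple[float, float, float]]

    def summary(self) -> str:
        lines = [f"joint Wald p for age x tertile interaction: "
                 f"{self.interaction_p:.4f}"]
        for term, (b0, b1, d) in self.mediation.items():
            lines.append(
                f"{term}: unadjusted beta {b0:.3f}, adjusted {b1:.3f}, "
                f"difference {d:.3f} (descriptive)"
            )
        return "\n".join(lines)


def interaction_and_mediation(cohort: pd.DataFrame,
                              tertiles: TertileAssignment) -> InteractionMediationReport:
    """Test for age-by-tertile interaction and summarise age mediation.

    The interaction model adds age x tertile product terms to the adjusted
    Gaussian GLM and reports their joint Wald p-value; the mediation
    summary is the unadjusted-minus-adjusted coefficient difference for
    each tertile term.
    """
    unadj = fit_psqi_glm(cohort, tertiles, adjust=False)
    adj = fit_psqi_glm(cohort, tertiles, adjust=True)

    df = _model_frame(cohort, tertiles)
    model = smf.glm("psqi_total ~ C(tertile) + age + female + C(tertile):age",
                    data=df, family=sm.families.Gaussian())
    res = model.fit()
    _check_full_rank(res)
    inter_names = [nm for nm in res.model.exog_names if ":age" in nm]
    wald = res.wald_test([f"{nm} = 0" for nm in inter_names], scalar=True)
    mediation = {
        term: (
            unadj.terms[term].beta,
            adj.terms[term].beta,
            unadj.terms[term].beta - adj.terms[term].beta,
        )
        for term in ("tertile_2", "tertile_3")
    }
    return InteractionMediationReport(
        interaction_p=float(wald.pvalue),
        unadjusted=unadj,
        adjusted=adj,
        mediation=mediation,
    )


@dataclass
class GroupCompareReport:
    """Median-age stratified comparison of cohort variables."""

    split_value: float
    n_low: int
    n_high: int
    continuous: pd.DataFrame  # variable, mean/sd per stratum, p (linear model)
    categorical: pd.DataFrame  # variable, counts per stratum, test, p

    def summary(self) -> str:
        lines = [f"strata: age <= {self.split_value:g} (n={self.n_low}) vs "
                 f"age > {self.split_value:g} (n={self.n_high})"]
        for _, r in self.continuous.iterrows():
            lines.append(
                f"{r['variable']}: {r['mean_low']:.1f} +/- {r['sd_low']:.1f} vs "
                f"{r['mean_high']:.1f} +/- {r['sd_high']:.1f}, p={r['p']:.4g}"
            )
        for _, r in self.categorical.iterrows():
            lines.append(
                f"{r['variable']}: {int(r['count_low'])}/{self.n_low} vs "
                f"{int(r['count_high'])}/{self.n_high}, {r['test']} p={r['p']:.4g}"
            )
        return "\n".join(lines)


def group_compare(cohort: pd.DataFrame,
                  continuous: tuple[str, ...] = ("pgc_uL", "psqi_total"),
                  categorical: tuple[str, ...] = ("psqi_poor", "sex"),
                  ) -> GroupCompareReport:
    """Compare cohort variables between median-age strata.

    Continuous variables get per-stratum mean +/- SD and a two-group
    linear-model p-value; categorical variables get a chi-squared test, or
    Fisher's exact test when any expected cell count is below 5.
    """
    age = cohort["age"].to_numpy(dtype=float)
    split = float(np.median(age))
    low = age <= split
    high = ~low
    if low.sum() == 0 or high.sum() == 0:
        raise ValueError("empty stratum after median-age split")

    cont_rows = []
    for var in continuous:
        v = cohort[var].to_numpy(dtype=float)
        X = sm.add_constant(high.astype(float))
        p = float(sm.OLS(v, X).fit().pvalues[1])
        cont_rows.append({
            "variable": var,
            "mean_low": float(v[low].mean()), "sd_low": float(v[low].std(ddof=1)),
            "mean_high": float(v[high].mean()), "sd_high": float(v[high].std(ddof=1)),
            "p": p,
        })

    cat_rows = []
    for var in categorical:
        v = cohort[var].astype(int).to_numpy()
        table = np.array([
            [int((v[low] == 1).sum()), int((v[low] == 0).sum())],
            [int((v[high] == 1).sum()), int((v[high] == 0).sum())],
        ])
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            test = "fisher"
            p = float(stats.fisher_exact(table)[1])
        else:
            test = "chi2"
            p = float(stats.chi2_contingency(table, correction=False)[1])
        cat_rows.append({
            "variable": var,
            "count_low": int(table[0, 0]), "count_high": int(table[1, 0]),
            "test": test, "p": p,
        })

    return GroupCompareReport(
        split_value=split,
        n_low=int(low.sum()),
        n_high=int(high.sum()),
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
    )
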