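"""Mixed-effects model ladder, standardization and demographic statistics.

The analysis treats each of the nine outcome features with a ladder of linear
mixed-effects models with a random intercept per subject:

    feature = b0 + b_S Speed + b_A AgeGroup + b_SA Speed x AgeGroup
              + (1 | Subject) + eps

Speed is continuous and standardized; AgeGroup is categorical (Young = 0,
Older = 1); the outcome is standardized so the fixed-effect slopes read as
effect sizes.  Fitting is two-step: maximum likelihood supplies the
log-likelihood and AIC used for model comparison, and a REML refit supplies
the (unbiased) coefficient estimates, their normal-approximation 95% CIs and
z-test p-values.  R^2 is the squared Pearson correlation between the observed
feature and the fixed-effects-only prediction; residual normality is
quantified with the Jarque-Bera test on conditional residuals.

Conventions pinned here (the source analysis leaves them open): sample SD
(n - 1 denominator) for standardization; Wald/normal CIs and p-values from the
REML fit; no multiple-testing correction across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import DegenerateDataError, UsageError

#: The four model specifications of the ladder, in reporting order.
MODEL_LADDER = (
    ("speed",),
    ("age",),
    ("speed", "age"),
    ("speed", "age", "speed:age"),
)

_PRED_LABELS = {"speed": "beta_S", "age": "beta_A", "speed:age": "beta_SA"}


def standardize(x) -> tuple[np.ndarray, float, float]:
    """z-scores with the (mean, sd) used, sample SD convention (ddof=1)."""
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateDataError("cannot standardize a constant column")
    return (x - mean) / sd, mean, sd


def jarque_bera(residuals) -> tuple[float, float]:
    """Jarque-Bera normality statistic and chi2(2) p-value."""
    res = sps.jarque_bera(np.asarray(residuals, dtype=float))
    return float(res.statistic), float(res.pvalue)


@dataclass
class LmmResult:
    """One fitted entry of the model ladder."""

    feature: str
    predictors: tuple                 # subset of ("speed", "age", "speed:age")
    beta: dict                        # coefficient name -> REML estimate
    se: dict
    ci95: dict                        # name -> (lo, hi)
    p_values: dict
    llf: float                        # ML log-likelihood
    aic: float                        # 2k - 2 llf, k = n_fixed + 2
    k_params: int
    r2_fixed: float
    random_intercept_var: float
    residual_var: float
    jb_stat: float
    jb_p: float
    nobs: int
    converged: bool = True
    boundary: bool = False            # random-intercept variance at ~0
    degenerate: bool = False          # noiseless limit, OLS fallback


def _design(table: pd.DataFrame, predictors, speed_col: str) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    s = table[speed_col].to_numpy(dtype=float)
    g = table["age_group"].to_numpy(dtype=float)
    for p in predictors:
        if p == "speed":
            cols.append(s)
        elif p == "age":
            cols.append(g)
        elif p == "speed:age":
            cols.append(s * g)
        else:
            raise UsageError(f"unknown predictor {p!r}")
        names.append(_PRED_LABELS[p])
    return np.column_stack(cols), names


def r2_fixed(y, X, beta) -> float:
    """Squared Pearson correlation between y and the fixed-effect prediction."""
    yhat = np.asarray(X) @ np.asarray(beta)
    if np.std(yhat) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(np.asarray(y), yhat)[0, 1] ** 2)


_OPTIMIZERS = ("bfgs", "powell", "lbfgs")


def _fit_best(model, reml: bool):
    """Fit the random-intercept model, falling back across optimizers.

    A single optimizer occasionally stalls or errors on this likelihood,
    which would break the LLF ordering of nested ML fits; BFGS is tried
    first (empirically it reaches the same optimum as Powell to ~1e-7) and
    the remaining optimizers serve as fallbacks.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _OPTIMIZERS:
            try:
                res = model.fit(reml=reml, method=method)
            except Exception:
                continue
            if np.isfinite(res.llf):
                return res
    raise DegenerateDataError("mixed-model fit failed with all optimizers")


def fit_lmm(table: pd.DataFrame, feature: str, predictors,
            standardize_feature: bool = True,
            standardize_speed: bool = True,
            group_col: str = "subject_id",
            ml_metrics: bool = True) -> LmmResult:
    """Fit one random-intercept model of the ladder.

    ``predictors`` is an ordered subset of ``("speed", "age", "speed:age")``.
    The two-step procedure fits by maximum likelihood for the LLF/AIC metrics
    and refits by REML for the coefficient estimates; ``ml_metrics=False``
    skips the ML step (LLF/AIC become NaN) for Monte-Carlo loops that only
    need coefficients.  When both noise sources vanish (a noiseless synthetic
    table) the mixed-model likelihood degenerates; the fit then falls back to
    the exact OLS limit with the ``degenerate`` flag set.
    """
    predictors = tuple(predictors)
    df = table.reset_index(drop=True)
    y = df[feature].to_numpy(dtype=float)
    if standardize_feature:
        y, _, _ = standardize(y)
    speed_col = "speed"
    if standardize_speed:
        z, _, _ = standardize(df["speed"])
        df = df.assign(_speed_z=z)
        speed_col = "_speed_z"
    X, names = _design(df, predictors, speed_col)
    groups = df[group_col].to_numpy()
    k = X.shape[1] + 2    # fixed effects + random-intercept var + residual var

    # degenerate (noiseless) limit: exact linear fit
    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta

    def _ols_limit() -> LmmResult:
        beta = dict(zip(names, ols_beta))
        zero = {n: 0.0 for n in names}
        return LmmResult(
            feature=feature, predictors=predictors, beta=beta, se=zero,
            ci95={n: (b, b) for n, b in beta.items()},
            p_values={n: (0.0 if n != "intercept" else 1.0) for n in names},
            llf=np.nan, aic=np.nan, k_params=k,
            r2_fixed=r2_fixed(y, X, ols_beta),
            random_intercept_var=0.0, residual_var=float(np.var(ols_resid)),
            jb_stat=np.nan, jb_p=np.nan, nobs=len(y),
            converged=True, boundary=True, degenerate=True,
        )

    if float(np.var(ols_resid)) < 1e-18:
        return _ols_limit()

    model = sm.MixedLM(y, X, groups=groups)
    try:
        reml = _fit_best(model, reml=True)
    except DegenerateDataError:
        # near-noiseless data: the mixed likelihood is numerically singular
        return _ols_limit()
    if ml_metrics:
        try:
            ml = _fit_best(model, reml=False)
            llf = float(ml.llf)
            aic = 2.0 * k - 2.0 * llf
            ml_converged = bool(ml.converged)
        except DegenerateDataError:
            llf = aic = np.nan
            ml_converged = False
    else:
        llf = aic = np.nan
        ml_converged = True
    fe = np.asarray(reml.fe_params, dtype=float)
    se = np.asarray(reml.bse_fe, dtype=float)
    zcrit = sps.norm.ppf(0.975)
    beta = dict(zip(names, fe))
    se_d = dict(zip(names, se))
    ci = {n: (b - zcrit * s, b + zcrit * s)
          for (n, b), s in zip(beta.items(), se)}
    pvals = {n: float(2.0 * sps.norm.sf(abs(b / s))) if s > 0 else np.nan
             for (n, b), s in zip(beta.items(), se)}

    # conditional residuals: y - X beta - u_subject
    ranef = reml.random_effects
    u = np.array([float(np.asarray(ranef[gr])[0]) for gr in groups])
    resid = y - X @ fe - u
    jb_stat, jb_p = jarque_bera(resid)

    re_var = float(np.asarray(reml.cov_re)[0, 0])
    return LmmResult(
        feature=feature, predictors=predictors, beta=beta, se=se_d, ci95=ci,
        p_values=pvals, llf=llf, aic=aic, k_params=k,
        r2_fixed=r2_fixed(y, X, fe),
        random_intercept_var=re_var, residual_var=float(reml.scale),
        jb_stat=jb_stat, jb_p=jb_p, nobs=len(y),
        converged=bool(ml_converged and reml.converged),
        boundary=re_var < 1e-8 * max(float(reml.scale), 1e-12),
    )


def fit_ladder(table: pd.DataFrame, feature: str,
               standardize_feature: bool = True) -> dict:
    """Fit the four-model ladder for one feature; keys are predictor tuples."""
    return {
        spec: fit_lmm(table, feature, spec,
                      standardize_feature=standardize_feature)
        for spec in MODEL_LADDER
    }


def likelihood_ratio_test(nested: LmmResult, full: LmmResult) -> tuple[float, int, float]:
    """LRT for the additional fixed term(s): 2 dLLF ~ chi2(d k)."""
    if not set(nested.predictors) < set(full.predictors):
        raise UsageError(
            f"models are not nested: {nested.predictors} vs {full.predictors}"
        )
    if nested.nobs != full.nobs or nested.feature != full.feature:
        raise UsageError("LRT requires both fits on identical data")
    df = full.k_params - nested.k_params
    stat = 2.0 * (full.llf - nested.llf)
    if -1e-8 < stat < 0.0:       # optimizer noise on equal fits
        stat = 0.0
    return float(stat), int(df), float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# demographic comparisons


def cohens_d(mean1, sd1, n1, mean2, sd2, n2) -> float:
    """|standardized mean difference| with pooled, df-weighted SD."""
    sp = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    return float(abs(mean1 - mean2) / sp)


def group_compare_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float, float]:
    """Independent two-tailed t-test and Cohen's d from printed summaries.

    The t statistic is signed as (group2 - group1); d is reported as a
    magnitude, matching how cohort tables conventionally print effect sizes.
    """
    sp = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    t = (mean2 - mean1) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = float(2.0 * sps.t.sf(abs(t), n1 + n2 - 2))
    return float(t), p, cohens_d(mean1, sd1, n1, mean2, sd2, n2)


def group_compare(group1, group2) -> tuple[float, float, float]:
    """Independent two-tailed t-test (t, p) plus Cohen's d for two samples."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    return group_compare_summary(x.mean(), x.std(ddof=1), x.size,
                                 y.mean(), y.std(ddof=1), y.size)


# ---------------------------------------------------------------------------
# speed-confounding subset analysis


@dataclass
class SubsetConfoundResult:
    young_ids: list
    older_ids: list
    speed_t: float
    speed_p: float
    speed_d: float
    ladders: dict = field(default_factory=dict)  # feature -> {"A": ..., "A+S": ...}


def subset_confound_analysis(table: pd.DataFrame, features=None,
                             condition: str = "comfortable") -> SubsetConfoundResult:
    """Contrast the slower half of older vs. the faster half of young subjects.

    Subjects are ranked by their comfortable-condition speed within each age
    group; the subset keeps the ceil(N/2) slowest older and ceil(N/2) fastest
    young subjects (all their speed conditions).  For every feature the
    age-only model and the age+speed model are fitted, standardizing within
    the analyzed subset, exposing how a group speed difference masquerades as
    an age effect until speed enters the model.
    """
    comfort = table[table["condition"] == condition]
    if comfort.empty:
        raise UsageError(f"no rows with condition {condition!r}")
    speeds = comfort.set_index("subject_id")["speed"]
    groups = comfort.set_index("subject_id")["age_group"]

    young = speeds[groups == 0].sort_values()
    older = speeds[groups == 1].sort_values()
    n_y, n_o = len(young), len(older)
    if n_y < 2 or n_o < 2:
        raise DegenerateDataError("each age group needs at least 2 subjects")
    k_y = int(np.ceil(n_y / 2))
    k_o = int(np.ceil(n_o / 2))
    young_ids = list(young.index[-k_y:])   # faster half of young
    older_ids = list(older.index[:k_o])    # slower half of older

    if min(k_y, k_o) >= 2:
        t, p, d = group_compare(young.loc[young_ids].to_numpy(),
                                older.loc[older_ids].to_numpy())
    else:                       # a single-subject subgroup has no spread
        t = p = d = float("nan")

    sub = table[table["subject_id"].isin(young_ids + older_ids)]
    if features is None:
        features = [c for c in table.columns
                    if c not in ("subject_id", "age_group", "age", "condition",
                                 "speed")]
    ladders = {}
    for feat in features:
        ladders[feat] = {
            "A": fit_lmm(sub, feat, ("age",)),
            "A+S": fit_lmm(sub, feat, ("age", "speed")),
        }
    return SubsetConfoundResult(young_ids=young_ids, older_ids=older_ids,
                                speed_t=t, speed_p=p, speed_d=d,
                                ladders=ladders)
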