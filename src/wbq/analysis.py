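"""The study's statistical pipeline on a scored respondent table.

Stages: descriptive gender comparisons (test chosen by variable type and a
Shapiro–Wilk normality verdict), univariate water-balance screens, a
missing-at-random screening of missingness indicators, chained-equation
multiple imputation, and the three multivariable models — the full
DAG-selected model (Model 1), its backward-AIC reduction (Model 2), and the
refit on Model 2's significant terms (Model 3) — pooled across imputations
by Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .config import BEVERAGE_CATEGORIES, ScoringConfig
from .stats import (
    LinearFit,
    PooledFit,
    backward_aic,
    design_matrix,
    linear_fit,
    logistic_irls,
    pool_fits,
    required_sample_size,  # noqa: F401  (re-exported pipeline operation)
)

__all__ = [
    "MODEL1_GROUPS",
    "UNIVARIATE_PREDICTORS",
    "build_design",
    "assess_normality",
    "NormalityResult",
    "compare_by_gender",
    "ComparisonResult",
    "univariate_screen",
    "assess_mar",
    "MARReport",
    "ChainedImputer",
    "ImputationSet",
    "impute_chained",
    "fit_models",
    "pooled_ols",
    "ModelSet",
    "diagnostics",
    "DiagnosticsReport",
    "required_sample_size",
]

ALPHA = 0.05

#: Yes/no questionnaire items entered as 0/1 indicators (reference "no").
_YESNO = ("bottle_at_work", "glass_during_day", "bottle_during_day",
          "water_without_thirst", "water_for_pleasure")

#: Likert 1–5 items entered as continuous scores.
_LIKERT = ("labor_intensity", "physical_strain", "mental_strain",
           "wc_access", "weather_exposure", "water_access")

#: Model 1 term groups (the DAG-selected set), in reporting order.  A
#: multi-level factor is one group spanning its dummy columns; reference
#: levels: female, profession "other", limited variety, "no".
MODEL1_GROUPS: dict[str, list[str]] = {
    "beverage_variety_binary": ["beverage_variety_binary"],
    "gender_male": ["gender_male"],
    "age": ["age"],
    "bmi": ["bmi"],
    "education_years": ["education_years"],
    "profession": ["profession_self_employed", "profession_private",
                   "profession_public"],
    "work_hours_week": ["work_hours_week"],
    **{k: [k] for k in _LIKERT},
    **{k: [k] for k in _YESNO},
}

#: Default univariate screen: the Model 1 covariates plus the per-category
#: beverage frequencies (times/day).
UNIVARIATE_PREDICTORS: list[str] = (
    ["gender_male", "age", "bmi", "education_years", "profession",
     "work_hours_week", *_LIKERT, "bottle_at_work"]
    + [f"bev_{c}_times" for c in BEVERAGE_CATEGORIES]
    + ["beverage_variety_binary", "glass_during_day", "bottle_during_day",
       "water_without_thirst", "water_for_pleasure"]
)


def _to01(col: pd.Series) -> pd.Series:
    """'yes'/'no' (or 0/1) to float 0/1, preserving missing."""
    if col.dtype == object or pd.api.types.is_string_dtype(col):
        s = col.astype("string").str.lower()
        out = s.map({"yes": 1.0, "no": 0.0})
        return out.astype(float)
    return pd.to_numeric(col, errors="coerce")


def build_design(scored: pd.DataFrame,
                 config: ScoringConfig | None = None) -> pd.DataFrame:
    """Numeric modelling table from a scored respondent table.

    Produces the Model 1 design columns (dummy-coded against the reference
    levels above), the recoded per-beverage times/day, and the ``balance``
    outcome.  Missing values stay missing.
    """
    config = config or ScoringConfig()
    out = pd.DataFrame(index=scored.index)
    gender = scored["gender"].astype("string").str.lower()
    out["gender_male"] = gender.map({"male": 1.0, "female": 0.0}).astype(float)
    for col in ("age", "bmi", "education_years", "work_hours_week", *_LIKERT):
        out[col] = pd.to_numeric(scored[col], errors="coerce")
    prof = scored["profession"].astype("string").str.lower()
    for level in ("self_employed", "private", "public"):
        out[f"profession_{level}"] = (prof == level).astype(float).where(prof.notna())
    for col in _YESNO:
        out[col] = _to01(scored[col])
    out["beverage_variety_binary"] = pd.to_numeric(
        scored["beverage_variety_binary"], errors="coerce")
    values = np.asarray(config.frequency_recode.values)
    for cat in BEVERAGE_CATEGORIES:
        codes = pd.to_numeric(scored[f"bev_{cat}"], errors="coerce")
        mapped = codes.map(lambda c: values[int(c) - 1] if pd.notna(c) else np.nan)
        out[f"bev_{cat}_times"] = mapped.astype(float)
    out["balance"] = pd.to_numeric(scored["balance"], errors="coerce")
    return out


# ---------------------------------------------------------------------------
# descriptives


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    pvalue: float
    normal: bool


def assess_normality(values, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro–Wilk normality verdict (normal iff p >= alpha)."""
    x = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 non-missing values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: normality test undefined")
    stat, p = sps.shapiro(x)
    return NormalityResult(float(stat), float(p), bool(p >= alpha))


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str                    # chi-square | t | Wilcoxon
    statistic: float
    pvalue: float
    summaries: dict[str, str]


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{np.mean(x):.2f} ({np.std(x, ddof=1):.2f})"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def compare_by_gender(df: pd.DataFrame, variable: str,
                      gender_col: str = "gender",
                      kind: str | None = None) -> ComparisonResult:
    """Two-group comparison by gender with the study's test-selection rule.

    Categorical variables get a chi-square test on the contingency table
    (continuity-corrected only for 2x2); continuous variables get Student's
    t when both groups pass Shapiro–Wilk, otherwise the Wilcoxon rank-sum
    (normal approximation with tie correction).
    """
    sub = df[[gender_col, variable]].dropna(subset=[gender_col])
    groups = sub[gender_col].unique().tolist()
    counts = sub.groupby(gender_col, observed=True)[variable].count()
    if (counts == 0).any() or len(groups) < 2:
        raise ValueError("both gender groups must be non-empty")
    if kind is None:
        numeric = pd.to_numeric(sub[variable], errors="coerce")
        parses = numeric.notna().sum() == sub[variable].notna().sum()
        kind = ("continuous"
                if parses and sub[variable].dropna().nunique() > 2
                else "categorical")
    if kind == "categorical":
        table = pd.crosstab(sub[variable], sub[gender_col])
        stat, p, *_ = sps.chi2_contingency(table.to_numpy(),
                                           correction=table.shape == (2, 2))
        summaries = {}
        for g in table.columns:
            n = table[g].sum()
            summaries[str(g)] = "; ".join(
                f"{lvl}: {cnt} ({100 * cnt / n:.1f}%)"
                for lvl, cnt in table[g].items())
        return ComparisonResult(variable, "chi-square", float(stat), float(p),
                                summaries)
    vals = {g: pd.to_numeric(sub.loc[sub[gender_col] == g, variable],
                             errors="coerce").dropna().to_numpy(float)
            for g in groups}
    normal = all(assess_normality(v).normal for v in vals.values())
    a, b = (vals[g] for g in groups[:2])
    if normal:
        stat, p = sps.ttest_ind(a, b)
        summaries = {str(g): _fmt_mean_sd(v) for g, v in vals.items()}
        return ComparisonResult(variable, "t", float(stat), float(p), summaries)
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    summaries = {str(g): _fmt_median_iqr(v) for g, v in vals.items()}
    return ComparisonResult(variable, "Wilcoxon", float(stat), float(p), summaries)


# ---------------------------------------------------------------------------
# univariate screen


@dataclass
class UnivariateResult:
    predictor: str
    fit: LinearFit


def univariate_screen(design: pd.DataFrame,
                      predictors: list[str] | None = None,
                      outcome: str = "balance",
                      groups: dict[str, list[str]] | None = None,
                      log: list[str] | None = None) -> list[UnivariateResult]:
    """One simple OLS of the outcome per predictor (factor = one model).

    Constant predictors are skipped with a log entry rather than fitted.
    """
    predictors = predictors if predictors is not None else UNIVARIATE_PREDICTORS
    groups = groups or MODEL1_GROUPS
    results = []
    y_all = pd.to_numeric(design[outcome], errors="coerce")
    for pred in predictors:
        cols = groups.get(pred, [pred])
        sub = design[cols].apply(pd.to_numeric, errors="coerce")
        ok = sub.notna().all(axis=1) & y_all.notna()
        if ok.sum() < len(cols) + 2 or (sub[ok].nunique() <= 1).all():
            if log is not None:
                log.append(f"skipped constant/degenerate predictor {pred!r}")
            continue
        X = design_matrix(design[ok], cols)
        fit = linear_fit(X, y_all[ok].to_numpy(float), ["const"] + cols)
        results.append(UnivariateResult(pred, fit))
    return results


# ---------------------------------------------------------------------------
# missingness screening (MAR assessment)


@dataclass
class MARReport:
    """Per-variable logistic screens of missingness indicators.

    ``screens`` maps each incompletely observed variable to a coefficient
    table over the fully observed covariates; ``systematic`` flags variables
    whose missingness is predicted by any covariate at the 5% level.
    """

    screens: dict[str, pd.DataFrame] = field(default_factory=dict)
    systematic: dict[str, bool] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.screens


def assess_mar(df: pd.DataFrame, covariates: list[str] | None = None,
               alpha: float = ALPHA) -> MARReport:
    """Regress each variable's missingness indicator on observed covariates.

    Covariates default to the fully observed numeric columns.  Separated or
    non-converged covariate effects are reported as non-estimable rather
    than raising.
    """
    numeric = df.apply(pd.to_numeric, errors="coerce")
    incomplete = [c for c in numeric.columns if numeric[c].isna().any()]
    if covariates is None:
        covariates = [c for c in numeric.columns
                      if not numeric[c].isna().any() and numeric[c].nunique() > 1]
    report = MARReport()
    for var in incomplete:
        ind = numeric[var].isna().astype(float).to_numpy()
        X = design_matrix(numeric, covariates)
        beta, cov, converged = logistic_irls(X, ind)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        p = 2 * sps.norm.sf(np.abs(z))
        ok = (converged and bool(np.all(np.isfinite(se)))) & (np.abs(beta) < 15)
        rows = pd.DataFrame({"coef": beta, "se": se, "p": p, "estimable": ok},
                            index=["const"] + covariates)
        rows.loc[~rows["estimable"], ["coef", "se", "p"]] = np.nan
        report.screens[var] = rows
        pvals = rows.loc[covariates, "p"]
        report.systematic[var] = bool((pvals < alpha).any())
    return report


# ---------------------------------------------------------------------------
# chained-equation imputation


@dataclass
class ImputationSet:
    """m completed tables plus the imputation bookkeeping.

    Observed cells are identical across completions; each completion has no
    missing cells in the modelled variables.
    """

    completions: list[pd.DataFrame]
    methods: dict[str, str]
    seed: int
    n_iter: int
    chain_means: pd.DataFrame   # per (chain, iteration, variable) imputed mean

    @property
    def m(self) -> int:
        return len(self.completions)


class ChainedImputer(BaseEstimator):
    """Multiple imputation by chained equations on a numeric table.

    Each incompletely observed variable is imputed conditionally on all other
    modelled variables: continuous variables by a Bayesian linear regression
    draw (posterior draws of coefficients and residual variance, then noise),
    0/1 variables by a Bernoulli draw from a logistic fit with an approximate
    posterior draw of its coefficients.  ``m`` independent chains are run for
    ``n_iter`` cycles each; everything is reproducible under ``seed``.
    """

    def __init__(self, m: int = 20, n_iter: int = 10, seed: int = 20220512):
        self.m = m
        self.n_iter = n_iter
        self.seed = seed

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _is_binary(x: pd.Series) -> bool:
        obs = x.dropna().unique()
        return len(obs) > 0 and set(np.unique(obs)).issubset({0.0, 1.0})

    def _impute_one(self, work: np.ndarray, cols: list[int], miss_masks,
                    methods, rng: np.random.Generator, trace: list) -> None:
        for it in range(self.n_iter):
            for j in cols:
                mis = miss_masks[j]
                obs = ~mis
                others = [k for k in range(work.shape[1]) if k != j]
                Xo = np.column_stack([np.ones(obs.sum()), work[obs][:, others]])
                Xm = np.column_stack([np.ones(mis.sum()), work[mis][:, others]])
                yo = work[obs, j]
                if methods[j] == "logistic":
                    beta, cov, _ = logistic_irls(Xo, yo, ridge=1e-4)
                    try:
                        L = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        L = np.diag(np.sqrt(np.abs(np.diag(cov))))
                    bdraw = beta + L @ rng.standard_normal(len(beta))
                    pr = 1 / (1 + np.exp(-np.clip(Xm @ bdraw, -30, 30)))
                    work[mis, j] = (rng.random(mis.sum()) < pr).astype(float)
                else:
                    n_o, p = Xo.shape
                    xtx = Xo.T @ Xo + 1e-8 * np.eye(p)
                    xtx_inv = np.linalg.inv(xtx)
                    bhat = xtx_inv @ (Xo.T @ yo)
                    resid = yo - Xo @ bhat
                    ssr = float(resid @ resid)
                    dfree = max(n_o - p, 1)
                    sigma2 = ssr / rng.chisquare(dfree)
                    L = np.linalg.cholesky(xtx_inv * sigma2)
                    bdraw = bhat + L @ rng.standard_normal(p)
                    work[mis, j] = Xm @ bdraw + rng.standard_normal(mis.sum()) \
                        * np.sqrt(sigma2)
                trace.append((it, j, float(work[mis, j].mean())))

    # -- public API ---------------------------------------------------------

    def impute(self, df: pd.DataFrame,
               columns: list[str] | None = None) -> ImputationSet:
        """Run the chained equations and return the m completed tables."""
        if self.m < 1:
            raise ValueError("m must be at least 1")
        numeric = df.apply(pd.to_numeric, errors="coerce")
        all_missing = [c for c in numeric.columns if numeric[c].isna().all()]
        if all_missing:
            raise ValueError(f"variable(s) with 100% missingness: {all_missing}")
        if columns is None:
            columns = [c for c in numeric.columns if numeric[c].isna().any()]
        col_idx = [numeric.columns.get_loc(c) for c in columns]
        methods_by_idx = {
            j: ("logistic" if self._is_binary(numeric.iloc[:, j]) else "linear")
            for j in col_idx
        }
        base = numeric.to_numpy(float)
        miss_masks = {j: np.isnan(base[:, j]) for j in col_idx}
        completions: list[pd.DataFrame] = []
        traces = []
        children = np.random.SeedSequence(self.seed).spawn(self.m)
        for chain, ss in enumerate(children):
            rng = np.random.default_rng(ss)
            work = base.copy()
            for j in col_idx:       # initial fill: draws from the observed margin
                mis = miss_masks[j]
                if mis.any():
                    obs_vals = work[~mis, j]
                    work[mis, j] = rng.choice(obs_vals, size=mis.sum())
            trace: list = []
            active = [j for j in col_idx if miss_masks[j].any()]
            if active:
                self._impute_one(work, active, miss_masks, methods_by_idx, rng,
                                 trace)
            completed = pd.DataFrame(work, index=numeric.index,
                                     columns=numeric.columns)
            completions.append(completed)
            traces.extend((chain, it, numeric.columns[j], mean)
                          for it, j, mean in trace)
        chain_means = pd.DataFrame(traces,
                                   columns=["chain", "iteration", "variable",
                                            "imputed_mean"])
        methods = {numeric.columns[j]: methods_by_idx[j] for j in col_idx}
        return ImputationSet(completions, methods, self.seed, self.n_iter,
                             chain_means)


def impute_chained(df: pd.DataFrame, m: int = 20, seed: int = 20220512,
                   n_iter: int = 10,
                   columns: list[str] | None = None) -> ImputationSet:
    """Functional wrapper over :class:`ChainedImputer`."""
    return ChainedImputer(m=m, n_iter=n_iter, seed=seed).impute(df, columns)


# ---------------------------------------------------------------------------
# the three multivariable models


@dataclass
class ModelSet:
    """Models 1–3 with their term groups; terms3 ⊆ terms2 ⊆ terms1."""

    model1: PooledFit
    model2: PooledFit
    model3: PooledFit
    terms1: list[str]
    terms2: list[str]
    terms3: list[str]
    selection_log: list[str] = field(default_factory=list)


def pooled_ols(completions: list[pd.DataFrame], cols: list[str],
                outcome: str) -> PooledFit:
    fits = [linear_fit(design_matrix(c, cols),
                       c[outcome].to_numpy(float), ["const"] + cols)
            for c in completions]
    return pool_fits(fits)


def fit_models(imputations: ImputationSet, outcome: str = "balance",
               groups: dict[str, list[str]] | None = None,
               alpha: float = ALPHA) -> ModelSet:
    """Fit the three-model cascade on an imputation set.

    Model 1 pools the full DAG term set over the m completions by Rubin's
    rules.  Model 2 applies backward AIC elimination on the first completed
    dataset (a deterministic selection), then pools the selected terms over
    all completions.  Model 3 refits the Model 2 terms whose pooled p-value
    is below ``alpha`` (a factor survives if any of its levels does).
    """
    groups = groups or MODEL1_GROUPS
    completions = imputations.completions
    log: list[str] = []
    cols1 = [c for g in groups.values() for c in g]
    model1 = pooled_ols(completions, cols1, outcome)

    first = completions[0]
    y0 = first[outcome].to_numpy(float)
    terms2 = backward_aic(first, y0, groups, log=log)
    cols2 = [c for g in terms2 for c in groups[g]]
    model2 = pooled_ols(completions, cols2, outcome)

    terms3 = []
    for g in terms2:
        idx = [model2.terms.index(c) for c in groups[g]]
        if (model2.pvalues[idx] < alpha).any():
            terms3.append(g)
    if terms3 != terms2:
        log.append(f"model 3 drops {[g for g in terms2 if g not in terms3]}")
    cols3 = [c for g in terms3 for c in groups[g]]
    model3 = pooled_ols(completions, cols3, outcome)
    return ModelSet(model1, model2, model3, list(groups), terms2, terms3, log)


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DiagnosticsReport:
    vif: dict[str, float]
    vif_flags: list[str]
    residual_normality: NormalityResult | None
    heteroscedasticity: dict[str, float]
    residual_vs_fitted: dict[str, float]


def diagnostics(design: pd.DataFrame, columns: list[str],
                outcome: str = "balance",
                vif_cap: float = 5.0) -> DiagnosticsReport:
    """Collinearity (VIF), residual normality and heteroscedasticity checks.

    VIF for a column is 1/(1−R²) of the auxiliary regression of that column
    on the remaining predictors; perfectly collinear columns report an
    infinite VIF.  Heteroscedasticity uses the Breusch–Pagan LM test.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    sub = design[columns + [outcome]].apply(pd.to_numeric, errors="coerce").dropna()
    vif: dict[str, float] = {}
    for col in columns:
        others = [c for c in columns if c != col]
        X = design_matrix(sub, others)
        yv = sub[col].to_numpy(float)
        try:
            fit = linear_fit(X, yv, ["const"] + others)
            sst = float(((yv - yv.mean()) ** 2).sum())
            r2 = 1.0 - fit.ssr / sst if sst > 0 else 0.0
            vif[col] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        except np.linalg.LinAlgError:
            vif[col] = np.inf
    flags = [c for c, v in vif.items() if v > vif_cap]

    resid_norm = None
    het: dict[str, float] = {}
    rvf: dict[str, float] = {}
    try:
        X = design_matrix(sub, columns)
        fit = linear_fit(X, sub[outcome].to_numpy(float), ["const"] + columns)
        resid = sub[outcome].to_numpy(float) - X @ fit.beta
        fitted = X @ fit.beta
        resid_norm = assess_normality(resid)
        lm, lm_p, f, f_p = het_breuschpagan(resid, X)
        het = {"lm": float(lm), "lm_p": float(lm_p), "f": float(f),
               "f_p": float(f_p)}
        slope = (np.cov(fitted, resid)[0, 1] / np.var(fitted)
                 if np.var(fitted) > 0 else 0.0)
        rvf = {"mean_resid": float(resid.mean()), "slope": float(slope)}
    except np.linalg.LinAlgError:
        pass
    return DiagnosticsReport(vif, flags, resid_norm, het, rvf)
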