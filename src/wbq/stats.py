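"""Regression primitives: OLS with exact normal-equation algebra, Rubin's
rules for multiply-imputed fits, greedy backward AIC elimination, a compact
IRLS logistic solver, and the noncentral-F sample-size calculation.

The OLS core is deliberately lean (plain least squares on an explicit design
matrix) because the Monte-Carlo recovery experiments fit hundreds of
thousands of small models; it is cross-checked against statsmodels in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LinearFit",
    "PooledFit",
    "linear_fit",
    "design_matrix",
    "pool_fits",
    "backward_aic",
    "logistic_irls",
    "required_sample_size",
]


@dataclass
class LinearFit:
    """One OLS fit: coefficient table plus model-level summaries."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray
    n: int
    p: int
    sigma2: float           # SSR / (n - p)
    ssr: float
    adj_r2: float
    rmse: float             # sqrt(SSR / n)
    aic: float              # n log(SSR/n) + 2 p  (R's stepwise convention)

    @property
    def df_resid(self) -> int:
        return self.n - self.p


def design_matrix(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Design matrix with a leading intercept column."""
    X = np.column_stack([np.ones(len(df))] +
                        [pd.to_numeric(df[c], errors="coerce").to_numpy(float)
                         for c in columns])
    return X


def linear_fit(X: np.ndarray, y: np.ndarray,
               terms: list[str] | None = None) -> LinearFit:
    """Ordinary least squares on an explicit design (first column intercept).

    Raises ``np.linalg.LinAlgError`` listing aliased columns when the design
    is rank deficient.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    terms = terms or [f"x{i}" for i in range(p)]
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        # identify aliased columns via the QR diagonal
        diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = diag.max() * max(n, p) * np.finfo(float).eps
        aliased = [terms[i] for i in np.flatnonzero(diag < tol)]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; aliased term(s): {aliased or 'unidentified'}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    sigma2 = ssr / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * sps.t.sf(np.abs(tvals), n - p)
    adj_r2 = 1.0 - (ssr / (n - p)) / (sst / (n - 1)) if sst > 0 else np.nan
    aic = n * np.log(ssr / n) + 2 * p
    return LinearFit(list(terms), beta, se, pvals, cov, n, p, sigma2, ssr,
                     adj_r2, float(np.sqrt(ssr / n)), aic)


@dataclass
class PooledFit:
    """Rubin's-rules combination of per-imputation OLS fits.

    ``adj_r2`` and ``rmse`` are the means across completions; ``between`` is
    the between-imputation variance of each coefficient (zero when all
    completions agree).
    """

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    df: np.ndarray
    m: int
    n: int
    adj_r2: float
    rmse: float
    within: np.ndarray
    between: np.ndarray
    fits: list[LinearFit] = field(default_factory=list, repr=False)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "p": self.pvalues},
            index=self.terms,
        )


def pool_fits(fits: list[LinearFit]) -> PooledFit:
    """Combine m per-completion OLS fits by Rubin's rules.

    With identical completions the between-imputation variance is exactly
    zero and the pooled fit reduces to the single-dataset fit (t reference
    with the complete-data residual degrees of freedom).
    """
    m = len(fits)
    if m == 0:
        raise ValueError("no fits to pool")
    terms = fits[0].terms
    betas = np.stack([f.beta for f in fits])
    qbar = betas.mean(axis=0)
    W = np.stack([f.se ** 2 for f in fits]).mean(axis=0)
    B = betas.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1 + 1 / m) * B
    se = np.sqrt(T)
    df_com = fits[0].df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (1 + 1 / m) * B / W
    df = np.where(r > 0, (m - 1) * (1 + 1 / np.where(r > 0, r, 1)) ** 2, np.inf)
    df = np.minimum(df, df_com)
    pvals = 2 * sps.t.sf(np.abs(qbar / se), df)
    return PooledFit(list(terms), qbar, se, pvals, df, m, fits[0].n,
                     float(np.mean([f.adj_r2 for f in fits])),
                     float(np.mean([f.rmse for f in fits])),
                     W, B, fits)


def backward_aic(df: pd.DataFrame, y: np.ndarray,
                 groups: dict[str, list[str]],
                 log: list[str] | None = None) -> list[str]:
    """Greedy backward elimination over term groups, minimising AIC.

    ``groups`` maps a term (e.g. a multi-level factor) to its design columns;
    a group is dropped as a unit.  Returns the retained group names in the
    original order.  Stops when no single drop lowers the AIC.
    """
    current = list(groups)

    def fit_aic(keep: list[str]) -> float:
        cols = [c for g in keep for c in groups[g]]
        return linear_fit(design_matrix(df, cols), y, ["const"] + cols).aic

    best = fit_aic(current)
    while current:
        trial = [(fit_aic([g for g in current if g != cand]), cand)
                 for cand in current]
        aic_min, drop = min(trial, key=lambda t: t[0])
        if aic_min < best - 1e-10:
            current = [g for g in current if g != drop]
            best = aic_min
            if log is not None:
                log.append(f"drop {drop} (AIC {aic_min:.2f})")
        else:
            break
    return current


def logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                  max_iter: int = 50, tol: float = 1e-8
                  ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic regression by iteratively reweighted least squares.

    A tiny ridge keeps the solve defined under (quasi-)separation.  Returns
    ``(beta, covariance, converged)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    eye = np.eye(p) * ridge
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = X.T @ (y - mu) - ridge * beta
        hess = (X.T * w) @ X + eye
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X + eye)
    return beta, cov, converged


def required_sample_size(f2: float, power: float = 0.80, alpha: float = 0.05,
                         k: int = 1, n_max: int = 1_000_000) -> int:
    """Smallest n giving the target power for the k-predictor omnibus F test.

    Cohen's f² enters through the noncentrality λ = f²·n; the test is
    F(k, n−k−1) at level ``alpha``.
    """
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be at least 1")
    for n in range(k + 2, n_max + 1):
        df2 = n - k - 1
        fcrit = sps.f.isf(alpha, k, df2)
        if sps.ncf.sf(fcrit, k, df2, f2 * n) >= power:
            return n
    raise ValueError(f"power {power} unattainable below n={n_max}")
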