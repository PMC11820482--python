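"""Parameter-recovery Monte Carlo: the generator's acceptance surface.

Repeatedly generates cohorts with the default planted effects, pushes each
through the full pipeline (scoring, MAR deletion, chained-equation
imputation, the three-model cascade) and measures how well the pooled
reduced-model coefficients recover the planted values.  The reduced-model
*specification* (the planted nonzero terms) is refit on every replicate so
the recovery estimand is the unconditional pooled estimate; the data-driven
selection path is run as well and summarised as per-term selection
frequencies, since averaging only the replicates where a term survives
selection would measure winner's-curse bias rather than estimation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import MODEL1_GROUPS, fit_models, impute_chained, pooled_ols
from .analysis import build_design
from .scoring import score_table
from .simulate import (
    DEFAULT_TRUE_COEFFICIENTS,
    CohortSpec,
    generate_cohort,
    inject_missingness,
)

__all__ = ["recovery_experiment", "RecoveryResult"]


@dataclass
class RecoveryResult:
    """Per-replicate estimates and their summary against the planted truth."""

    estimates: pd.DataFrame      # one row per replicate, one column per term
    summary: pd.DataFrame        # mean, sd, mc_se, planted, |bias|/mc_se
    selection_frequency: pd.Series
    mean_rmse: float
    noise_sd: float
    n_replicates: int
    n: int

    def within(self, term: str, k: float = 2.0) -> bool:
        """Is the mean estimate within k Monte-Carlo SEs of the planted value?"""
        row = self.summary.loc[term]
        return bool(abs(row["mean"] - row["planted"]) <= k * row["mc_se"])


def recovery_experiment(n_replicates: int = 500, n: int = 208,
                        seed: int = 20220512, m: int = 20, n_iter: int = 10,
                        run_selection: bool = True,
                        progress: bool = False) -> RecoveryResult:
    """Run the planted-effect recovery Monte Carlo.

    Each replicate: generate a cohort of size ``n`` from the default
    :class:`CohortSpec`, delete cells by its MAR mechanism, score, impute
    with ``m`` chains, fit the model cascade, and record the pooled
    coefficients of the planted-term specification together with which terms
    the AIC/significance selection retained.
    """
    master = np.random.default_rng(seed)
    planted = dict(DEFAULT_TRUE_COEFFICIENTS)
    terms = list(planted)
    rows = []
    rmses = []
    selected_counts = pd.Series(0, index=list(MODEL1_GROUPS), dtype=float)
    spec0 = CohortSpec()
    for rep in range(n_replicates):
        s1, s2, s3 = (int(x) for x in master.integers(2 ** 31, size=3))
        spec = CohortSpec(n=n, seed=s1)
        cohort = generate_cohort(spec)
        miss = inject_missingness(cohort.responses, spec.missingness, seed=s2)
        scored = score_table(miss.data)
        design = build_design(scored)
        model_cols = [c for g in MODEL1_GROUPS.values() for c in g]
        imps = impute_chained(design[model_cols + ["balance"]], m=m, seed=s3,
                              n_iter=n_iter)
        fit = pooled_ols(imps.completions, terms, "balance")
        rows.append({t: fit.coef(t) for t in terms})
        rmses.append(fit.rmse)
        if run_selection:
            models = fit_models(imps)
            selected_counts[models.terms3] += 1
        if progress and (rep + 1) % 50 == 0:
            print(f"  replicate {rep + 1}/{n_replicates}")
    est = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "mean": est.mean(),
        "sd": est.std(ddof=1),
        "mc_se": est.std(ddof=1) / np.sqrt(len(est)),
        "planted": pd.Series(planted),
    })
    summary["abs_bias_over_mc_se"] = (
        (summary["mean"] - summary["planted"]).abs() / summary["mc_se"])
    return RecoveryResult(
        estimates=est,
        summary=summary,
        selection_frequency=selected_counts / n_replicates,
        mean_rmse=float(np.mean(rmses)),
        noise_sd=spec0.noise_sd,
        n_replicates=n_replicates,
        n=n,
    )
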