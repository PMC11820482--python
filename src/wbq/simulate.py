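"""Synthetic questionnaire cohorts with a plantable water-balance model.

The generator draws respondent covariates from marginal distributions
anchored to the study population it emulates (gender split, Likert
frequencies, binary prevalences, work hours), draws a latent water balance
``intercept + Σ βx + N(0, noise_sd)`` from planted linear effects, and then
back-solves the plain drinking-water answer — the only continuous free
intake input — so that the scoring module reproduces each respondent's
latent balance essentially exactly while every ordinal answer keeps its
marginal distribution.

When a very negative latent balance would require negative drinking water,
the fluid-loss answers (excretion scales and physical activity) are redrawn
with the latent balance held fixed; as a last resort the loss side is
augmented deterministically (maximal scales plus extra walking time) so the
target is still met with zero drinking water.  Because the latent balance is
never altered, planted coefficients stay exactly recoverable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .codebook import EXCLUSION_FLAGS
from .config import BEVERAGE_CATEGORIES, ScoringConfig, default_composition_table
from .scoring import score_table

__all__ = [
    "CohortSpec",
    "MissingnessSpec",
    "SyntheticCohort",
    "MissingnessResult",
    "default_marginals",
    "generate_cohort",
    "inject_missingness",
    "DEFAULT_TRUE_COEFFICIENTS",
    "DEFAULT_INTERCEPT",
    "DEFAULT_NOISE_SD",
]

#: Planted linear effects on water balance (mL/day per unit), keyed by
#: modelling-design column.  Defaults mirror the reduced multivariable model
#: the generator is meant to emulate.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "education_years": -21.88,
    "work_hours_week": 30.17,
    "glass_during_day": 423.13,
    "bottle_during_day": 873.50,
    "water_for_pleasure": 478.63,
}
DEFAULT_INTERCEPT = -3052.46
DEFAULT_NOISE_SD = 1377.49


def default_marginals() -> dict:
    """Marginal distributions for every questionnaire field.

    Probabilities follow the printed cohort tables where available (gender
    split, residence, family status, profession, the six Likert items, the
    three container-use prevalences, mean weekly work hours); the remaining
    distributions are realistic choices for a working adult population.
    """
    return {
        "p_male": 98 / 208,
        "age": {"mean": 38.0, "sd": 11.0, "lo": 18.0, "hi": 65.0},
        "height_m": {"male": (1.77, 0.07), "female": (1.65, 0.06)},
        "bmi": {"male": (25.89, 4.5), "female": (22.37, 3.39),
                "lo": 16.0, "hi": 45.0},
        "education_years": {"mean": 16.0, "sd": 3.0, "lo": 6.0, "hi": 25.0},
        "work_hours_week": {"mean": 38.87, "sd": 10.0, "lo": 5.0, "hi": 80.0},
        "residence": {"capital": 0.606, "other_city": 0.327,
                      "small_town": 0.048, "village": 0.019},
        "family_status": {"unmarried": 0.726, "married": 0.226,
                          "divorced": 0.048},
        "profession": {"self_employed": 29 / 208, "private": 76 / 208,
                       "public": 27 / 208, "other": 76 / 208},
        "likert": {
            "labor_intensity": [0.413, 0.149, 0.197, 0.149, 0.092],
            "physical_strain": [0.269, 0.240, 0.284, 0.144, 0.063],
            "mental_strain": [0.072, 0.087, 0.251, 0.341, 0.249],
            "wc_access": [0.067, 0.053, 0.096, 0.168, 0.616],
            "weather_exposure": [0.620, 0.168, 0.120, 0.038, 0.054],
            "water_access": [0.048, 0.024, 0.135, 0.188, 0.605],
        },
        "binary": {
            "bottle_at_work": 0.553,
            "bottle_during_day": 0.848,
            "glass_during_day": 0.693,
            "water_without_thirst": 0.65,
            "water_for_pleasure": 0.60,
        },
        "beverage_freq": {
            "juices_soda": [0.15, 0.38, 0.25, 0.15, 0.05, 0.02],
            "coffee_milk": [0.05, 0.20, 0.25, 0.30, 0.14, 0.06],
            "milkshake_granita": [0.65, 0.22, 0.08, 0.035, 0.010, 0.005],
            "tea": [0.20, 0.35, 0.25, 0.13, 0.05, 0.02],
            "alcohol": [0.18, 0.40, 0.27, 0.10, 0.04, 0.01],
        },
        "food_freq": {
            "frequent": [0.18, 0.27, 0.28, 0.18, 0.06, 0.03],
            "occasional": [0.32, 0.36, 0.20, 0.09, 0.02, 0.01],
            "frequent_items": ["apple", "banana", "orange", "tomato",
                               "cucumber", "green_salad", "cooked_vegetables",
                               "bread", "yogurt", "potatoes"],
        },
        "urination_scale": [0.03, 0.10, 0.22, 0.34, 0.31],
        "defecation_scale": [0.10, 0.25, 0.32, 0.22, 0.11],
        "sweat_rest_scale": [0.04, 0.06, 0.09, 0.12, 0.15, 0.15, 0.13,
                             0.11, 0.08, 0.07],
        "sweat_exercise_scale": [0.04, 0.07, 0.10, 0.13, 0.16, 0.16, 0.13,
                                 0.10, 0.07, 0.04],
        "ipaq": {
            "vigorous": {"days": [0.40, 0.08, 0.14, 0.14, 0.09, 0.07, 0.04, 0.04],
                         "minutes": (60.0, 25.0)},
            "moderate": {"days": [0.30, 0.10, 0.15, 0.15, 0.10, 0.09, 0.06, 0.05],
                         "minutes": (50.0, 20.0)},
            "walking": {"days": [0.10, 0.06, 0.10, 0.12, 0.12, 0.14, 0.12, 0.24],
                        "minutes": (45.0, 20.0)},
        },
    }


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness mechanism: MCAR or MAR with logistic covariate dependence.

    Under MAR the per-cell deletion probability is ``sigmoid(a + Σ slope·z)``
    over the designated fully observed predictors (continuous predictors
    standardised); the intercept ``a`` is calibrated per variable so the
    expected deletion rate equals ``rate``.
    """

    mechanism: str = "MAR"
    rate: float = 0.10
    variables: tuple[str, ...] = ("education_years", "work_hours_week",
                                  "water_for_pleasure")
    predictors: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.5, "gender": 0.6})

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0 <= self.rate < 1:
            raise ValueError("rate must be in [0, 1)")
        overlap = set(self.variables) & set(self.predictors)
        if self.mechanism == "MAR" and overlap:
            raise ValueError(
                f"MAR predictors cannot also be deleted: {sorted(overlap)}")


@dataclass
class CohortSpec:
    """Generator parameters: size, seed, marginals, planted linear model."""

    n: int = 208
    seed: int = 20220512
    marginals: dict = field(default_factory=default_marginals)
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS))
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for key, probs in [*self.marginals["likert"].items(),
                           *self.marginals["beverage_freq"].items()]:
            p = np.asarray(probs, float)
            if (p < 0).any() or abs(p.sum() - 1) > 1e-6:
                raise ValueError(f"probabilities for {key!r} must sum to 1")
        for key, p in self.marginals["binary"].items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {key!r} outside [0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        kwargs = dict(d)
        marg = default_marginals()
        for k, v in kwargs.pop("marginals", {}).items():
            marg[k] = copy.deepcopy(v)
        if "missingness" in kwargs and isinstance(kwargs["missingness"], Mapping):
            mspec = dict(kwargs["missingness"])
            if "variables" in mspec:
                mspec["variables"] = tuple(mspec["variables"])
            kwargs["missingness"] = MissingnessSpec(**mspec)
        return cls(marginals=marg, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class SyntheticCohort:
    """Generated respondents plus the planted truth and feasibility log."""

    responses: pd.DataFrame
    latent_balance: pd.Series
    resampled: int = 0
    augmented: int = 0


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _categorical(rng, levels, probs, size):
    p = np.asarray(probs, float)
    return rng.choice(np.asarray(levels, dtype=object), size=size, p=p / p.sum())


_LOSS_COLUMNS = ("urination_scale", "defecation_scale", "sweat_rest_scale",
                 "sweat_exercise_scale",
                 "ipaq_vigorous_days", "ipaq_vigorous_min",
                 "ipaq_moderate_days", "ipaq_moderate_min",
                 "ipaq_walking_days", "ipaq_walking_min")


def _draw_loss_side(rng: np.random.Generator, marg: dict, size: int) -> dict:
    cols: dict[str, np.ndarray] = {}
    cols["urination_scale"] = _categorical(rng, range(1, 6),
                                           marg["urination_scale"], size).astype(int)
    cols["defecation_scale"] = _categorical(rng, range(1, 6),
                                            marg["defecation_scale"], size).astype(int)
    cols["sweat_rest_scale"] = _categorical(rng, range(1, 11),
                                            marg["sweat_rest_scale"], size).astype(int)
    cols["sweat_exercise_scale"] = _categorical(
        rng, range(1, 11), marg["sweat_exercise_scale"], size).astype(int)
    for cls, cfg in marg["ipaq"].items():
        days = _categorical(rng, range(len(cfg["days"])), cfg["days"],
                            size).astype(int)
        mean, sd = cfg["minutes"]
        minutes = np.where(days > 0,
                           np.round(_trunc_normal(rng, mean, sd, 5.0, 960.0, size)),
                           0.0)
        cols[f"ipaq_{cls}_days"] = days
        cols[f"ipaq_{cls}_min"] = minutes
    return cols


def generate_cohort(spec: CohortSpec,
                    config: ScoringConfig | None = None,
                    max_resample: int = 30) -> SyntheticCohort:
    """Generate a fully observed cohort whose scored balance equals the
    planted latent balance (to well below 1 mL/day)."""
    config = config or ScoringConfig()
    marg = spec.marginals
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    df = pd.DataFrame({"id": [f"r{i:05d}" for i in range(n)]})
    male = rng.random(n) < marg["p_male"]
    df["gender"] = np.where(male, "male", "female")
    a = marg["age"]
    df["age"] = np.round(_trunc_normal(rng, a["mean"], a["sd"], a["lo"], a["hi"], n))
    h = marg["height_m"]
    height = np.where(male,
                      rng.normal(*h["male"], n), rng.normal(*h["female"], n))
    height = np.clip(height, 1.40, 2.15)
    b = marg["bmi"]
    bmi = np.where(male,
                   _trunc_normal(rng, *b["male"], b["lo"], b["hi"], n),
                   _trunc_normal(rng, *b["female"], b["lo"], b["hi"], n))
    df["height_m"] = np.round(height, 2)
    df["weight_kg"] = np.round(bmi * df["height_m"] ** 2, 1)
    e = marg["education_years"]
    df["education_years"] = np.round(
        _trunc_normal(rng, e["mean"], e["sd"], e["lo"], e["hi"], n))
    df["residence"] = _categorical(rng, list(marg["residence"]),
                                   list(marg["residence"].values()), n)
    df["family_status"] = _categorical(rng, list(marg["family_status"]),
                                       list(marg["family_status"].values()), n)
    df["profession"] = _categorical(rng, list(marg["profession"]),
                                    list(marg["profession"].values()), n)
    w = marg["work_hours_week"]
    df["work_hours_week"] = np.round(
        _trunc_normal(rng, w["mean"], w["sd"], w["lo"], w["hi"], n), 1)
    for item, probs in marg["likert"].items():
        df[item] = _categorical(rng, range(1, 6), probs, n).astype(int)
    for item, p in marg["binary"].items():
        df[item] = np.where(rng.random(n) < p, "yes", "no")
    for cat in BEVERAGE_CATEGORIES:
        df[f"bev_{cat}"] = _categorical(rng, range(1, 7),
                                        marg["beverage_freq"][cat], n).astype(int)
    freq_items = set(marg["food_freq"]["frequent_items"])
    for item in default_composition_table():
        probs = (marg["food_freq"]["frequent"] if item in freq_items
                 else marg["food_freq"]["occasional"])
        df[f"food_{item}"] = _categorical(rng, range(1, 7), probs, n).astype(int)
    for col, arr in _draw_loss_side(rng, marg, n).items():
        df[col] = arr
    for flag in EXCLUSION_FLAGS:
        df[flag] = "no"

    # planted latent balance
    lp = np.full(n, float(spec.intercept))
    for term, beta in spec.true_coefficients.items():
        if term == "gender_male":
            x = male.astype(float)
        elif term in marg["binary"]:
            x = (df[term] == "yes").astype(float).to_numpy()
        elif term == "bmi":
            x = bmi
        else:
            x = pd.to_numeric(df[term]).to_numpy(float)
        lp += beta * x
    target = lp + rng.normal(0.0, spec.noise_sd, n)

    def water_needed(frame: pd.DataFrame) -> np.ndarray:
        probe = frame.copy()
        probe["drinking_water_ml"] = 0.0
        scored = score_table(probe, config)
        return target[frame.index.to_numpy()] - scored["balance"].to_numpy(float)

    df["drinking_water_ml"] = 0.0
    needed = np.empty(n)
    needed[:] = water_needed(df)

    resampled = 0
    for _ in range(max_resample):
        infeasible = np.flatnonzero(needed < 0)
        if infeasible.size == 0:
            break
        resampled += infeasible.size
        redraw = _draw_loss_side(rng, marg, infeasible.size)
        for col, arr in redraw.items():
            df.loc[infeasible, col] = arr
        needed[infeasible] = water_needed(df.iloc[infeasible])

    augmented_idx = np.flatnonzero(needed < 0)
    if augmented_idx.size:
        # deterministic fallback: maximal loss scales, then exactly enough
        # extra walking time; the latent target is still met with zero
        # drinking water.
        df.loc[augmented_idx, "urination_scale"] = 5
        df.loc[augmented_idx, "defecation_scale"] = 5
        df.loc[augmented_idx, "sweat_rest_scale"] = 10
        df.loc[augmented_idx, "sweat_exercise_scale"] = 10
        needed[augmented_idx] = water_needed(df.iloc[augmented_idx])
        still = augmented_idx[needed[augmented_idx] < 0]
        if still.size:
            mult = config.sweat_scale_multipliers[10]
            rate = config.sweat_exercise_rates["walking"]
            deficit = -needed[still]
            extra_week_min = deficit * 7.0 * 60.0 / (rate * mult)
            days = pd.to_numeric(df.loc[still, "ipaq_walking_days"]).to_numpy(float)
            minutes = pd.to_numeric(df.loc[still, "ipaq_walking_min"]).to_numpy(float)
            df.loc[still, "ipaq_walking_days"] = 7
            df.loc[still, "ipaq_walking_min"] = (days * minutes
                                                 + extra_week_min) / 7.0
            needed[still] = water_needed(df.iloc[still])

    df["drinking_water_ml"] = np.maximum(needed, 0.0)
    return SyntheticCohort(df, pd.Series(target, name="latent_balance"),
                           resampled=resampled,
                           augmented=int(augmented_idx.size))


@dataclass
class MissingnessResult:
    """Cohort with deleted cells, the deletion mask, and the deleted truth."""

    data: pd.DataFrame
    mask: pd.DataFrame      # True where a cell was deleted
    truth: pd.DataFrame     # original values at deleted cells, NaN elsewhere

    def reconstruct(self) -> pd.DataFrame:
        out = self.data.copy()
        for col in self.mask.columns:
            m = self.mask[col].to_numpy()
            vals = out[col].to_numpy(dtype=object, copy=True)
            vals[m] = self.truth[col].to_numpy(dtype=object)[m]
            out[col] = pd.Series(vals, index=out.index).infer_objects()
        return out


def _mar_scores(df: pd.DataFrame, predictors: Mapping[str, float]) -> np.ndarray:
    z = np.zeros(len(df))
    for col, slope in predictors.items():
        if col == "gender":
            x = (df["gender"].astype("string").str.lower() == "male").to_numpy(float)
        else:
            x = pd.to_numeric(df[col], errors="coerce").to_numpy(float)
            if np.isnan(x).any():
                raise ValueError(f"MAR predictor {col!r} has missing values")
            sd = x.std()
            x = (x - x.mean()) / (sd if sd > 0 else 1.0)
        z += slope * x
    return z


def inject_missingness(cohort: pd.DataFrame,
                       spec: MissingnessSpec | None = None,
                       seed: int = 0) -> MissingnessResult:
    """Delete cells by the configured mechanism and keep the deleted truth."""
    spec = spec or MissingnessSpec()
    rng = np.random.default_rng(seed)
    data = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index,
                        columns=list(spec.variables))
    truth = pd.DataFrame(np.nan, index=cohort.index,
                         columns=list(spec.variables), dtype=object)
    if spec.rate == 0:
        return MissingnessResult(data, mask, truth)
    if spec.mechanism == "MAR":
        z = _mar_scores(cohort, spec.predictors)
    for var in spec.variables:
        if var not in cohort.columns:
            raise ValueError(f"missingness variable {var!r} not in cohort")
        if spec.mechanism == "MCAR":
            prob = np.full(len(cohort), spec.rate)
        else:
            def mean_rate(a, z=z):
                return float(np.mean(1 / (1 + np.exp(-(a + z))))) - spec.rate
            a = brentq(mean_rate, -30.0, 30.0)
            prob = 1 / (1 + np.exp(-(a + z)))
        deleted = rng.random(len(cohort)) < prob
        mask[var] = deleted
        truth.loc[deleted, var] = data.loc[deleted, var]
        data.loc[deleted, var] = np.nan
    return MissingnessResult(data, mask, truth)
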