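"""Water-balance scoring: raw questionnaire answers -> mL/day components.

Daily water balance is the net of total intake (water contained in foods,
water from the five non-water beverage categories, and plain drinking water)
against total loss (urine, feces, sweat).  Respiratory loss is treated as
cancelling against metabolic water production, so neither appears.  Derived
covariates (BMI and its WHO class, beverage-variety score, IPAQ MET·min/week)
are produced alongside.

All component values are snapped to a dyadic grid of 2**-30 mL (about 1e-9),
finer than any questionnaire resolution; because every component is then an
exact binary float well below the 53-bit mantissa limit, the accounting
identity ``balance + loss_total - intake_total == 0`` holds exactly in
floating point for every complete record, not merely to rounding error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import (
    ACTIVITY_CLASSES,
    BEVERAGE_CATEGORIES,
    FrequencyRecode,
    ScoringConfig,
)

__all__ = [
    "recode_frequency",
    "water_from_foods",
    "water_from_beverages",
    "beverage_variety",
    "urine_loss",
    "fecal_loss",
    "sweat_loss",
    "score_ipaq",
    "compute_bmi",
    "categorize_bmi",
    "compute_balance",
    "score_table",
    "WBQScorer",
    "WaterProfile",
    "PROFILE_COLUMNS",
    "ConfigurationError",
]

_GRID = float(2 ** 30)  # dyadic quantum, mL

#: IPAQ short-form MET weights per activity class.
IPAQ_MET = {"vigorous": 8.0, "moderate": 4.0, "walking": 3.3}

#: Beverage-variety dichotomisation cut-off (median types consumed).
VARIETY_CUTOFF = 3

PROFILE_COLUMNS = (
    "water_from_foods", "water_from_beverages", "water_from_water",
    "intake_total", "urine_loss", "fecal_loss", "sweat_loss", "loss_total",
    "balance", "beverage_variety_count", "beverage_variety_binary",
    "bmi", "bmi_category", "ipaq_met_min_week",
)


class ConfigurationError(ValueError):
    """An item or level referenced by the data is absent from the config."""


def _q(x):
    """Snap mL/day values to the dyadic grid (see module docstring)."""
    return np.round(np.asarray(x, dtype=float) * _GRID) / _GRID


def _recode_of(config) -> FrequencyRecode:
    if isinstance(config, FrequencyRecode):
        return config
    if isinstance(config, ScoringConfig):
        return config.frequency_recode
    if config is None:
        return FrequencyRecode()
    raise TypeError(f"expected FrequencyRecode or ScoringConfig, got {type(config)}")


def recode_frequency(category: str | int, config=None) -> float:
    """Times/day for a consumption-frequency category (label or 1-based code)."""
    return _recode_of(config).value(category)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v is pd.NA


def water_from_foods(food_freq: Mapping[str, object],
                     config: ScoringConfig | None = None) -> float:
    """mL/day of water contained in foods.

    Sums, over items, recoded frequency x serving size (g) x water fraction
    (1 g of water taken as 1 mL).  A missing frequency contributes 0.
    """
    config = config or ScoringConfig()
    total = 0.0
    for item, cat in food_freq.items():
        if item not in config.composition_table:
            raise ConfigurationError(f"item {item!r} absent from composition table")
        if _is_missing(cat):
            continue
        frac, serving = config.composition_table[item]
        total += recode_frequency(cat, config) * serving * frac
    return float(_q(total))


def water_from_beverages(beverage_freq: Mapping[str, object],
                         config: ScoringConfig | None = None) -> float:
    """mL/day of water from the five beverage categories (plain water excluded)."""
    config = config or ScoringConfig()
    total = 0.0
    for cat_name, cat in beverage_freq.items():
        if cat_name not in config.beverage_servings:
            raise ConfigurationError(
                f"beverage category {cat_name!r} absent from beverage servings")
        if _is_missing(cat):
            continue
        serving, frac = config.beverage_servings[cat_name]
        total += recode_frequency(cat, config) * serving * frac
    return float(_q(total))


def beverage_variety(beverage_freq: Mapping[str, object],
                     config: ScoringConfig | None = None) -> tuple[int, int]:
    """(count of beverage categories consumed, broad-variety indicator).

    A category counts as consumed when its recoded frequency is strictly
    positive; the indicator is 1 when the count exceeds the median-based
    cut-off of 3 types.
    """
    config = config or ScoringConfig()
    count = 0
    for cat in beverage_freq.values():
        if not _is_missing(cat) and recode_frequency(cat, config) > 0:
            count += 1
    return count, int(count > VARIETY_CUTOFF)


def _scale_lookup(scale, table: Mapping[int, float], hi: int, what: str) -> float:
    if _is_missing(scale):
        return float("nan")
    s = int(scale)
    if s != float(scale) or not 1 <= s <= hi:
        raise ValueError(f"{what} scale out of range 1–{hi}: {scale!r}")
    return float(table[s])


def urine_loss(urination_scale, config: ScoringConfig | None = None) -> float:
    """mL/day urinary loss from the 5-point urination-frequency scale."""
    config = config or ScoringConfig()
    return float(_q(_scale_lookup(urination_scale, config.urine_loss_map, 5, "urination")))


def fecal_loss(defecation_scale, config: ScoringConfig | None = None) -> float:
    """mL/day fecal loss from the 5-point defecation-frequency scale."""
    config = config or ScoringConfig()
    return float(_q(_scale_lookup(defecation_scale, config.fecal_loss_map, 5, "defecation")))


def sweat_loss(sweat_rest_scale, sweat_exercise_scale,
               ipaq: Mapping[str, object] | None = None,
               config: ScoringConfig | None = None) -> float:
    """mL/day sweat loss: resting component plus exercise component.

    The resting 10-point scale maps directly to mL/day.  Each IPAQ activity
    class contributes (weekly hours / 7) x class base rate (mL/h) x the
    10-point exercise-sweat multiplier.  Missing IPAQ entries count as no
    reported activity.
    """
    config = config or ScoringConfig()
    rest = _scale_lookup(sweat_rest_scale, config.sweat_rest_map, 10, "resting sweat")
    if math.isnan(rest):
        return float("nan")
    ipaq = ipaq or {}
    exercise = 0.0
    any_activity = False
    for cls in ACTIVITY_CLASSES:
        days = ipaq.get(f"{cls}_days", 0)
        minutes = ipaq.get(f"{cls}_min", 0)
        days = 0.0 if _is_missing(days) else float(days)
        minutes = 0.0 if _is_missing(minutes) else float(minutes)
        if days * minutes > 0:
            any_activity = True
            exercise += (days * minutes / 60.0 / 7.0) * config.sweat_exercise_rates[cls]
    if any_activity:
        mult = _scale_lookup(sweat_exercise_scale, config.sweat_scale_multipliers,
                             10, "exercise sweat")
        if math.isnan(mult):
            return float("nan")
        exercise *= mult
    return float(_q(rest + exercise))


def score_ipaq(ipaq: Mapping[str, object]) -> float:
    """IPAQ short-form activity volume in MET·min/week.

    8.0 x vigorous + 4.0 x moderate + 3.3 x walking, each days/week x
    minutes/session.
    """
    total = 0.0
    for cls, met in IPAQ_MET.items():
        days = ipaq.get(f"{cls}_days", 0)
        minutes = ipaq.get(f"{cls}_min", 0)
        days = 0.0 if _is_missing(days) else float(days)
        minutes = 0.0 if _is_missing(minutes) else float(minutes)
        if days > 7 or days < 0:
            raise ValueError(f"IPAQ days/week out of range 0–7: {days}")
        if minutes < 0:
            raise ValueError(f"IPAQ minutes must be non-negative: {minutes}")
        total += met * days * minutes
    return total


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, weight (kg) divided by height (m) squared."""
    if _is_missing(weight_kg) or _is_missing(height_m):
        return float("nan")
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("weight and height must be positive")
    return float(weight_kg) / float(height_m) ** 2


def categorize_bmi(bmi: float) -> str | float:
    """WHO class: <18.5 underweight, [18.5, 25) normal, [25, 30) overweight, >=30 obese."""
    if _is_missing(bmi):
        return float("nan")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


@dataclass(frozen=True)
class WaterProfile:
    """Per-respondent intake components, loss components and balance (mL/day)."""

    water_from_foods: float
    water_from_beverages: float
    water_from_water: float
    intake_total: float
    urine_loss: float
    fecal_loss: float
    sweat_loss: float
    loss_total: float
    balance: float
    beverage_variety_count: int
    beverage_variety_binary: int
    bmi: float
    bmi_category: str | float
    ipaq_met_min_week: float


def compute_balance(water_from_foods: float, water_from_beverages: float,
                    water_from_water: float, urine: float, fecal: float,
                    sweat: float) -> dict[str, float]:
    """Totals and balance from the six components; missing propagates."""
    intake = water_from_foods + water_from_beverages + water_from_water
    loss = urine + fecal + sweat
    return {"intake_total": intake, "loss_total": loss, "balance": intake - loss}


# ---------------------------------------------------------------------------
# vectorised table scoring


def _freq_to_value(codes: pd.Series, values: np.ndarray) -> np.ndarray:
    """Map 1-based frequency codes to times/day; NaN stays NaN."""
    arr = pd.to_numeric(codes, errors="coerce").to_numpy(dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    idx = arr[ok].astype(int)
    if ok.any() and (idx.min() < 1 or idx.max() > len(values)):
        raise ValueError("frequency code out of range 1–6")
    out[ok] = values[idx - 1]
    return out


def _map_scale(col: pd.Series, table: Mapping[int, float], hi: int,
               what: str) -> np.ndarray:
    arr = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    idx = arr[ok].astype(int)
    if ok.any() and (idx.min() < 1 or idx.max() > hi):
        raise ValueError(f"{what} scale out of range 1–{hi}")
    lut = np.array([table[i] for i in range(1, hi + 1)])
    out[ok] = lut[idx - 1]
    return out


def score_table(responses: pd.DataFrame,
                config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score a validated respondent table into water-profile columns.

    Returns the input columns with the :data:`PROFILE_COLUMNS` appended.
    Missing food/beverage frequencies contribute zero intake; a missing
    drinking-water amount or excretion/sweat scale makes the affected total
    (and the balance) missing.
    """
    config = config or ScoringConfig()
    df = responses
    n = len(df)
    values = np.asarray(config.frequency_recode.values)

    foods = np.zeros(n)
    for item, (frac, serving) in config.composition_table.items():
        col = f"food_{item}"
        if col not in df.columns:
            continue
        freq = _freq_to_value(df[col], values)
        foods += np.nan_to_num(freq) * serving * frac
    foods = _q(foods)

    bev = np.zeros(n)
    consumed = np.zeros(n, dtype=int)
    for cat in BEVERAGE_CATEGORIES:
        col = f"bev_{cat}"
        if col not in df.columns:
            continue
        serving, frac = config.beverage_servings[cat]
        freq = _freq_to_value(df[col], values)
        bev += np.nan_to_num(freq) * serving * frac
        consumed += (np.nan_to_num(freq) > 0).astype(int)
    bev = _q(bev)

    water = _q(pd.to_numeric(df["drinking_water_ml"], errors="coerce").to_numpy(float))
    urine = _q(_map_scale(df["urination_scale"], config.urine_loss_map, 5, "urination"))
    fecal = _q(_map_scale(df["defecation_scale"], config.fecal_loss_map, 5, "defecation"))

    rest = _map_scale(df["sweat_rest_scale"], config.sweat_rest_map, 10, "resting sweat")
    mult = _map_scale(df["sweat_exercise_scale"], config.sweat_scale_multipliers,
                      10, "exercise sweat")
    exercise = np.zeros(n)
    any_act = np.zeros(n, dtype=bool)
    for cls in ACTIVITY_CLASSES:
        days = pd.to_numeric(df.get(f"ipaq_{cls}_days"), errors="coerce").to_numpy(float)
        minutes = pd.to_numeric(df.get(f"ipaq_{cls}_min"), errors="coerce").to_numpy(float)
        hours_week = np.nan_to_num(days) * np.nan_to_num(minutes) / 60.0
        any_act |= hours_week > 0
        exercise += hours_week / 7.0 * config.sweat_exercise_rates[cls]
    sweat = _q(rest + np.where(any_act, exercise * mult, 0.0))

    totals = compute_balance(foods, bev, water, urine, fecal, sweat)

    weight = pd.to_numeric(df["weight_kg"], errors="coerce").to_numpy(float)
    height = pd.to_numeric(df["height_m"], errors="coerce").to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = weight / height ** 2
    bmi_cat = pd.Series(bmi).map(categorize_bmi)

    met = np.zeros(n)
    for cls, w in IPAQ_MET.items():
        days = pd.to_numeric(df.get(f"ipaq_{cls}_days"), errors="coerce").to_numpy(float)
        minutes = pd.to_numeric(df.get(f"ipaq_{cls}_min"), errors="coerce").to_numpy(float)
        met += w * np.nan_to_num(days) * np.nan_to_num(minutes)

    out = df.copy()
    out["water_from_foods"] = foods
    out["water_from_beverages"] = bev
    out["water_from_water"] = water
    out["intake_total"] = totals["intake_total"]
    out["urine_loss"] = urine
    out["fecal_loss"] = fecal
    out["sweat_loss"] = sweat
    out["loss_total"] = totals["loss_total"]
    out["balance"] = totals["balance"]
    out["beverage_variety_count"] = consumed
    out["beverage_variety_binary"] = (consumed > VARIETY_CUTOFF).astype(int)
    out["bmi"] = bmi
    out["bmi_category"] = bmi_cat.to_numpy(dtype=object)
    out["ipaq_met_min_week"] = met
    return out


class WBQScorer(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`score_table`.

    ``fit`` validates the configuration; ``transform`` appends the water
    profile columns to a validated respondent table.  Stateless beyond its
    config, so it composes with sklearn pipelines.
    """

    def __init__(self, config: ScoringConfig | None = None):
        self.config = config

    def fit(self, X: pd.DataFrame, y=None) -> "WBQScorer":
        self.config_ = self.config or ScoringConfig()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        return score_table(X, self.config_)
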