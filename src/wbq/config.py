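"""Scoring configuration: frequency recoding and the fluid gain/loss mapping tables.

Every number that turns a questionnaire answer into millilitres per day lives
here, so a sensitivity analysis is a single config swap.  The six
times-per-day constants behind the consumption-frequency categories are the
instrument's published recode; the excretion and sweating tables are
config-overridable defaults spanning published healthy-adult ranges (the
instrument's sources do not print the exact grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "FREQUENCY_LABELS",
    "DEFAULT_FREQUENCY_VALUES",
    "BEVERAGE_CATEGORIES",
    "ACTIVITY_CLASSES",
    "FrequencyRecode",
    "ScoringConfig",
    "default_composition_table",
]

#: The six ordered consumption-frequency categories of the questionnaire.
FREQUENCY_LABELS: tuple[str, ...] = (
    "never/rarely",
    "1–2 times per week",
    "3–6 times per week",
    "1–2 times per day",
    "3–4 times per day",
    ">5 times per day",
)

#: Published mean times-per-day value for each category, in category order.
DEFAULT_FREQUENCY_VALUES: tuple[float, ...] = (0.0, 0.066, 0.214, 0.643, 1.0, 2.5)

#: The five beverage categories of the instrument (plain water is separate).
BEVERAGE_CATEGORIES: tuple[str, ...] = (
    "juices_soda",
    "coffee_milk",
    "milkshake_granita",
    "tea",
    "alcohol",
)

#: IPAQ short-form activity classes used for exercise sweating.
ACTIVITY_CLASSES: tuple[str, ...] = ("vigorous", "moderate", "walking")


def _normalise_label(label: str) -> str:
    """Canonicalise a frequency label: unify dashes, case and spacing."""
    s = label.strip().lower()
    for dash in ("–", "—", "−"):
        s = s.replace(dash, "-")
    return " ".join(s.split())


_CANONICAL = {_normalise_label(lbl): i for i, lbl in enumerate(FREQUENCY_LABELS)}


@dataclass(frozen=True)
class FrequencyRecode:
    """Ordered mapping of the 6 frequency categories to times/day values."""

    values: tuple[float, ...] = DEFAULT_FREQUENCY_VALUES

    def __post_init__(self) -> None:
        if len(self.values) != len(FREQUENCY_LABELS):
            raise ValueError(
                f"frequency recode needs {len(FREQUENCY_LABELS)} values, "
                f"got {len(self.values)}"
            )
        vals = tuple(float(v) for v in self.values)
        if any(v < 0 for v in vals):
            raise ValueError("frequency recode values must be non-negative")
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("frequency recode values must be non-decreasing")
        object.__setattr__(self, "values", vals)

    def value(self, category: str | int) -> float:
        """Times/day for a category given as label text or 1-based code."""
        if isinstance(category, str):
            key = _normalise_label(category)
            if key not in _CANONICAL:
                raise ValueError(f"unknown frequency category: {category!r}")
            return self.values[_CANONICAL[key]]
        code = int(category)
        if not 1 <= code <= len(self.values):
            raise ValueError(f"frequency code out of range 1–6: {category!r}")
        return self.values[code - 1]


def _linear_grid(lo: float, hi: float, n: int) -> dict[int, float]:
    step = (hi - lo) / (n - 1)
    return {i + 1: lo + i * step for i in range(n)}


def default_composition_table() -> dict[str, tuple[float, float]]:
    """Water fraction and serving size (g) for the shipped food-item fixture.

    A compact stand-in for a full nutrient-composition database: twenty items
    common in a Mediterranean diet, with water fractions typical of standard
    composition tables and household serving sizes.
    """
    return {
        "apple": (0.86, 182.0),
        "banana": (0.75, 118.0),
        "orange": (0.87, 131.0),
        "watermelon": (0.92, 280.0),
        "grapes": (0.81, 92.0),
        "tomato": (0.94, 123.0),
        "cucumber": (0.95, 100.0),
        "green_salad": (0.95, 85.0),
        "cooked_vegetables": (0.90, 135.0),
        "vegetable_soup": (0.92, 240.0),
        "legumes": (0.70, 180.0),
        "rice": (0.68, 158.0),
        "pasta": (0.62, 140.0),
        "potatoes": (0.77, 150.0),
        "bread": (0.36, 50.0),
        "yogurt": (0.85, 170.0),
        "cheese": (0.40, 30.0),
        "eggs": (0.76, 50.0),
        "poultry_meat": (0.64, 120.0),
        "fish": (0.70, 120.0),
    }


@dataclass(frozen=True)
class ScoringConfig:
    """All mapping tables needed to score a questionnaire into mL/day.

    Parameters
    ----------
    frequency_recode
        Category -> times/day recode shared by foods and beverages.
    composition_table
        item -> (water fraction in [0, 1], serving size in g).
    beverage_servings
        beverage category -> (serving volume mL, water fraction in [0, 1]).
    urine_loss_map, fecal_loss_map
        5-point excretion-frequency scale -> mL/day.
    sweat_rest_map
        10-point resting-sweat scale -> mL/day.
    sweat_exercise_rates
        activity class -> base sweating rate in mL per hour of activity.
    sweat_scale_multipliers
        10-point exercise-sweat scale -> multiplier on the base rate.
    """

    frequency_recode: FrequencyRecode = field(default_factory=FrequencyRecode)
    composition_table: Mapping[str, tuple[float, float]] = field(
        default_factory=default_composition_table
    )
    beverage_servings: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "juices_soda": (330.0, 0.90),
            "coffee_milk": (150.0, 0.95),
            "milkshake_granita": (250.0, 0.80),
            "tea": (250.0, 0.99),
            "alcohol": (330.0, 0.92),
        }
    )
    urine_loss_map: Mapping[int, float] = field(
        default_factory=lambda: {1: 800.0, 2: 1100.0, 3: 1400.0, 4: 1700.0, 5: 2000.0}
    )
    fecal_loss_map: Mapping[int, float] = field(
        default_factory=lambda: {1: 50.0, 2: 100.0, 3: 150.0, 4: 250.0, 5: 400.0}
    )
    sweat_rest_map: Mapping[int, float] = field(
        default_factory=lambda: _linear_grid(300.0, 1000.0, 10)
    )
    sweat_exercise_rates: Mapping[str, float] = field(
        default_factory=lambda: {"vigorous": 1000.0, "moderate": 600.0, "walking": 300.0}
    )
    sweat_scale_multipliers: Mapping[int, float] = field(
        default_factory=lambda: _linear_grid(0.2, 2.0, 10)
    )

    def __post_init__(self) -> None:
        for name, table, domain in (
            ("urine_loss_map", self.urine_loss_map, range(1, 6)),
            ("fecal_loss_map", self.fecal_loss_map, range(1, 6)),
            ("sweat_rest_map", self.sweat_rest_map, range(1, 11)),
            ("sweat_scale_multipliers", self.sweat_scale_multipliers, range(1, 11)),
        ):
            missing = [k for k in domain if k not in table]
            if missing:
                raise ValueError(f"{name} is missing scale levels {missing}")
            if any(float(v) < 0 for v in table.values()):
                raise ValueError(f"{name} has negative values")
        missing = [c for c in ACTIVITY_CLASSES if c not in self.sweat_exercise_rates]
        if missing:
            raise ValueError(f"sweat_exercise_rates missing classes {missing}")
        for item, (frac, size) in {
            **dict(self.composition_table),
            **dict(self.beverage_servings),
        }.items():
            # composition stores (fraction, serving); beverages (serving, fraction)
            lo, hi = sorted((float(frac), float(size)))
            if lo < 0:
                raise ValueError(f"negative entry for {item!r}")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequency_recode"] = list(self.frequency_recode.values)
        d["composition_table"] = {k: list(v) for k, v in self.composition_table.items()}
        d["beverage_servings"] = {k: list(v) for k, v in self.beverage_servings.items()}
        for key in ("urine_loss_map", "fecal_loss_map", "sweat_rest_map",
                    "sweat_scale_multipliers"):
            d[key] = {int(k): float(v) for k, v in d[key].items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringConfig":
        kwargs: dict = {}
        if "frequency_recode" in d:
            kwargs["frequency_recode"] = FrequencyRecode(tuple(d["frequency_recode"]))
        for key in ("composition_table", "beverage_servings"):
            if key in d:
                kwargs[key] = {k: tuple(v) for k, v in d[key].items()}
        for key in ("urine_loss_map", "fecal_loss_map", "sweat_rest_map",
                    "sweat_scale_multipliers"):
            if key in d:
                kwargs[key] = {int(k): float(v) for k, v in d[key].items()}
        if "sweat_exercise_rates" in d:
            kwargs["sweat_exercise_rates"] = {
                k: float(v) for k, v in d["sweat_exercise_rates"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
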