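"""Scoring: recoding constants, component arithmetic, invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wbq.config import FrequencyRecode, ScoringConfig
from wbq.scoring import (
    ConfigurationError,
    beverage_variety,
    categorize_bmi,
    compute_balance,
    compute_bmi,
    fecal_loss,
    recode_frequency,
    score_ipaq,
    score_table,
    sweat_loss,
    urine_loss,
    water_from_beverages,
    water_from_foods,
)


@pytest.mark.parametrize("label,expected", [
    ("never/rarely", 0.0),
    ("1–2 times per week", 0.066),
    ("3–6 times per week", 0.214),
    ("1–2 times per day", 0.643),
    ("3–4 times per day", 1.0),
    (">5 times per day", 2.5),
])
def test_recode_frequency_published_constants(label, expected):
    assert recode_frequency(label) == expected
    # ASCII-dash spelling and 1-based codes are accepted too
    assert recode_frequency(label.replace("–", "-")) == expected


@pytest.mark.parametrize("code,expected",
                         list(enumerate([0.0, 0.066, 0.214, 0.643, 1.0, 2.5], 1)))
def test_recode_frequency_codes(code, expected):
    assert recode_frequency(code) == expected


def test_recode_frequency_unknown_label():
    with pytest.raises(ValueError, match="unknown frequency category"):
        recode_frequency("weekly-ish")
    with pytest.raises(ValueError):
        recode_frequency(7)


def test_recode_must_be_monotone():
    with pytest.raises(ValueError):
        FrequencyRecode((0, 0.5, 0.2, 0.6, 1.0, 2.0))


class TestWaterFromFoods:
    config = ScoringConfig(composition_table={"melon": (0.90, 200.0),
                                              "bread": (0.36, 50.0)})

    def test_hand_arithmetic(self):
        got = water_from_foods({"melon": "1–2 times per day"}, self.config)
        assert got == pytest.approx(0.643 * 200 * 0.90, abs=1e-9)

    def test_all_never_is_zero(self):
        assert water_from_foods({"melon": 1, "bread": 1}, self.config) == 0.0

    def test_two_items_sum(self):
        items = {"melon": 4, "bread": 2}
        expected = sum(recode_frequency(c) * s * f
                       for c, (f, s) in ((items["melon"], (0.90, 200.0)),
                                         (items["bread"], (0.36, 50.0))))
        assert water_from_foods(items, self.config) == pytest.approx(expected,
                                                                     abs=1e-9)

    def test_missing_frequency_contributes_zero(self):
        assert water_from_foods({"melon": np.nan, "bread": 6},
                                self.config) == pytest.approx(
            2.5 * 50 * 0.36, abs=1e-9)

    def test_unknown_item_is_config_error(self):
        with pytest.raises(ConfigurationError, match="ouzo"):
            water_from_foods({"ouzo": 2}, self.config)


class TestWaterFromBeverages:
    def test_all_never_is_zero(self):
        assert water_from_beverages({c: 1 for c in
                                     ("juices_soda", "coffee_milk",
                                      "milkshake_granita", "tea", "alcohol")}) == 0

    def test_tea_weekly(self):
        cfg = ScoringConfig()
        assert cfg.beverage_servings["tea"] == (250.0, 0.99)
        got = water_from_beverages({"tea": "1–2 times per week"}, cfg)
        assert got == pytest.approx(0.066 * 250 * 0.99, abs=1e-9)

    def test_coffee_three_four_daily_recodes_to_one(self):
        cfg = ScoringConfig(beverage_servings={"coffee_milk": (150.0, 0.95)})
        got = water_from_beverages({"coffee_milk": "3–4 times per day"}, cfg)
        assert got == pytest.approx(142.5, abs=1e-9)


@pytest.mark.parametrize("codes,expected", [
    ((1, 1, 1, 1, 1), (0, 0)),
    ((2, 3, 4, 1, 1), (3, 0)),
    ((2, 2, 2, 2, 1), (4, 1)),
    ((6, 5, 4, 3, 2), (5, 1)),
])
def test_beverage_variety_cutoff_at_three(codes, expected):
    cats = ("juices_soda", "coffee_milk", "milkshake_granita", "tea", "alcohol")
    assert beverage_variety(dict(zip(cats, codes))) == expected


class TestLossLookups:
    def test_default_urine_map_ends(self):
        assert urine_loss(1) == 800.0
        assert urine_loss(5) == 2000.0

    def test_default_fecal_mid(self):
        assert fecal_loss(3) == 150.0

    def test_monotone_in_scale(self):
        u = [urine_loss(s) for s in range(1, 6)]
        f = [fecal_loss(s) for s in range(1, 6)]
        assert u == sorted(u) and f == sorted(f)

    @pytest.mark.parametrize("bad", [0, 6, 2.5])
    def test_out_of_range_scale(self, bad):
        with pytest.raises(ValueError):
            urine_loss(bad)


class TestSweatLoss:
    def test_rest_only(self):
        cfg = ScoringConfig()
        assert sweat_loss(1, 5, {}) == cfg.sweat_rest_map[1]

    def test_one_hour_daily_moderate(self):
        # scale 5 has multiplier exactly 1.0 on the default linear grid
        ipaq = {"moderate_days": 7, "moderate_min": 60}
        got = sweat_loss(1, 5, ipaq)
        assert got == pytest.approx(300.0 + 600.0, abs=1e-9)

    def test_multiplier_scales_exercise_component_linearly(self):
        ipaq = {"vigorous_days": 3, "vigorous_min": 40}
        base = ScoringConfig()
        doubled = ScoringConfig(sweat_scale_multipliers={
            k: 2 * v for k, v in base.sweat_scale_multipliers.items()})
        rest = base.sweat_rest_map[2]
        a = sweat_loss(2, 6, ipaq, base) - rest
        b = sweat_loss(2, 6, ipaq, doubled) - rest
        assert b == pytest.approx(2 * a, abs=1e-6)

    def test_out_of_range_scale(self):
        with pytest.raises(ValueError):
            sweat_loss(11, 5, {})


class TestBalanceArithmetic:
    def test_worked_example(self):
        got = compute_balance(500, 200, 2000, 1400, 150, 800)
        assert got["intake_total"] == 2700
        assert got["loss_total"] == 2350
        assert got["balance"] == 350

    def test_all_zero(self):
        assert compute_balance(0, 0, 0, 0, 0, 0)["balance"] == 0

    def test_missing_scale_propagates_to_balance(self, small_cohort):
        df = small_cohort.head(4).copy()
        df.loc[df.index[2], "urination_scale"] = np.nan
        scored = score_table(df)
        assert math.isnan(scored["balance"].iloc[2])
        assert not scored["balance"].drop(scored.index[2]).isna().any()


class TestBMI:
    def test_direct_arithmetic(self):
        assert compute_bmi(70, 1.70) == pytest.approx(24.2214532872, abs=1e-9)
        assert categorize_bmi(compute_bmi(70, 1.70)) == "normal"

    @pytest.mark.parametrize("bmi,cat", [
        (18.49, "underweight"), (18.5, "normal"), (24.99, "normal"),
        (25.0, "overweight"), (29.99, "overweight"), (30.0, "obese"),
    ])
    def test_who_boundaries(self, bmi, cat):
        assert categorize_bmi(bmi) == cat

    def test_non_positive_inputs(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 1.7)
        with pytest.raises(ValueError):
            compute_bmi(70, -1)


class TestIPAQ:
    def test_all_zero(self):
        assert score_ipaq({}) == 0.0

    def test_vigorous_only(self):
        assert score_ipaq({"vigorous_days": 3, "vigorous_min": 30}) == 720.0

    def test_walking(self):
        assert score_ipaq({"walking_days": 7, "walking_min": 10}) == \
            pytest.approx(231.0)

    def test_days_out_of_range(self):
        with pytest.raises(ValueError):
            score_ipaq({"moderate_days": 8, "moderate_min": 10})


# ---------------------------------------------------------------------------
# invariants on full-table scoring


def test_conservation_is_exact(scored_small):
    """balance + loss_total - intake_total is exactly zero in floating point."""
    check = (scored_small["balance"] + scored_small["loss_total"]
             - scored_small["intake_total"])
    assert (check == 0.0).all()


def test_scoring_is_deterministic(small_cohort):
    a = score_table(small_cohort)
    b = score_table(small_cohort)
    pd.testing.assert_frame_equal(a, b)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(row=st.integers(0, 59),
       col=st.sampled_from(["bev_tea", "bev_alcohol", "food_apple",
                            "food_rice"]),
       bump=st.integers(1, 3))
def test_increasing_frequency_never_decreases_intake(small_cohort, row, col,
                                                     bump):
    base = score_table(small_cohort)
    df = small_cohort.copy()
    df[col] = pd.to_numeric(df[col])
    new = min(int(df[col].iloc[row]) + bump, 6)
    df.iloc[row, df.columns.get_loc(col)] = new
    scored = score_table(df)
    assert scored["intake_total"].iloc[row] >= base["intake_total"].iloc[row]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(row=st.integers(0, 59),
       col=st.sampled_from(["urination_scale", "defecation_scale",
                            "sweat_rest_scale"]),
       bump=st.integers(1, 2))
def test_increasing_loss_scale_never_increases_balance(small_cohort, row, col,
                                                       bump):
    base = score_table(small_cohort)
    df = small_cohort.copy()
    df[col] = pd.to_numeric(df[col])
    hi = 10 if col == "sweat_rest_scale" else 5
    df.iloc[row, df.columns.get_loc(col)] = min(int(df[col].iloc[row]) + bump, hi)
    scored = score_table(df)
    assert scored["balance"].iloc[row] <= base["balance"].iloc[row]


def test_table_scoring_matches_scalar_ops(small_cohort):
    """Vectorised table scoring agrees with the per-respondent operations."""
    cfg = ScoringConfig()
    scored = score_table(small_cohort, cfg)
    row = small_cohort.iloc[7]
    foods = water_from_foods(
        {c[len("food_"):]: row[c] for c in row.index if c.startswith("food_")},
        cfg)
    bev = water_from_beverages(
        {c[len("bev_"):]: row[c] for c in row.index if c.startswith("bev_")},
        cfg)
    ipaq = {c[len("ipaq_"):]: row[c] for c in row.index if c.startswith("ipaq_")}
    sweat = sweat_loss(row["sweat_rest_scale"], row["sweat_exercise_scale"],
                       ipaq, cfg)
    assert scored["water_from_foods"].iloc[7] == pytest.approx(foods, abs=1e-9)
    assert scored["water_from_beverages"].iloc[7] == pytest.approx(bev, abs=1e-9)
    assert scored["sweat_loss"].iloc[7] == pytest.approx(sweat, abs=1e-9)
    assert scored["ipaq_met_min_week"].iloc[7] == pytest.approx(score_ipaq(ipaq))
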