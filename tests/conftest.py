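"""Shared fixtures: a small hand-written food table and a two-variant plan.

Nutrient numbers are deliberately round so expected totals can be verified
by hand arithmetic in the tests.
"""

from __future__ import annotations

import pytest

from nutricontrol.model import (
    FoodItem,
    FoodPlan,
    HydrationRule,
    Meal,
    NutrientVector,
    PlanTargets,
)


def make_food(food_id: str, name: str, energy: float, protein: float, carbs: float,
              lipids: float, **extra) -> FoodItem:
    return FoodItem(
        food_id=food_id,
        name=name,
        nutrients_per_100g=NutrientVector(
            energy=energy, protein=protein, carbs=carbs, lipids=lipids, **extra
        ),
    )


@pytest.fixture
def food_table() -> dict[str, FoodItem]:
    foods = [
        make_food("rice", "Boiled rice", 130.0, 2.5, 28.0, 0.3, fiber=0.4, iron=0.2),
        make_food("chicken", "Chicken breast", 165.0, 31.0, 0.0, 3.6, iron=1.0),
        make_food("milk", "Whole milk", 60.0, 3.2, 4.8, 3.2, calcium=120.0, water=88.0),
        make_food("bread", "Wheat bread", 250.0, 9.0, 49.0, 3.0, fiber=2.7, sodium=500.0),
        make_food("olive_oil", "Olive oil", 884.0, 0.0, 0.0, 100.0),
        # pasta_half has exactly half pasta's energy density with the same
        # macro ratios: its energy-matched quantity is exactly 2x.
        make_food("pasta", "Cooked pasta", 200.0, 8.0, 40.0, 2.0),
        make_food("pasta_half", "Diluted pasta", 100.0, 4.0, 20.0, 1.0),
        make_food("apple", "Apple", 52.0, 0.3, 14.0, 0.2, fiber=2.4, water=85.0),
        make_food("snackbar", "Snack bar", 500.0, 10.0, 60.0, 24.0, magnesium=80.0),
        make_food("water_only", "Spring water", 0.0, 0.0, 0.0, 0.0, water=100.0),
    ]
    return {f.food_id: f for f in foods}


@pytest.fixture
def simple_plan() -> FoodPlan:
    variants = {
        "monday": (
            Meal("breakfast", (("bread", 100.0), ("milk", 200.0))),
            Meal("lunch", (("chicken", 150.0), ("rice", 200.0))),
            Meal("dinner", (("pasta", 150.0), ("olive_oil", 10.0))),
        ),
        "train": (
            Meal("breakfast", (("bread", 50.0),)),
            Meal("event", (("snackbar", 60.0),)),
        ),
    }
    targets = PlanTargets(
        energy_kcal=2000.0,
        alpha=0.3,
        gamma=0.5,
        beta=0.2,
        micronutrient_targets={"iron": 10.0, "calcium": 800.0},
        fiber_g=25.0,
        water_ml=2000.0,
    )
    return FoodPlan(
        plan_id="p1",
        person_id="u1",
        variants=variants,
        targets=targets,
        water_rules=(HydrationRule(25.0, 300.0), HydrationRule(30.0, 500.0)),
    )
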