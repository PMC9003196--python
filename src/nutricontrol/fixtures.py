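"""Seeded synthetic data: food tables, week plans, and adherence logs.

Everything here is a pure function of the spec's seed, so any stochastic
test is replayable. The generator emulates the study conditions of a
nutrition-control deployment: a small food composition table spanning the
usual food classes, a nutritionist-style week plan (seven weekday variants
plus "train" and "competition" event variants), and a week of user
behaviour — meal confirmations with realistic adherence, occasional food
substitutions, smart-bottle water sips and smartwatch activity calories.

Default condition choices (see docs/methods.md for rationale): 12 foods,
four meals per day, 85% meal adherence, 10% substitution rate among eaten
meals, ~8 water sips/day of ~200 mL, ~400 active kcal/day.

What it does not emulate: real food-table measurement error, within-person
day-to-day appetite correlation, or device clock drift — synthetic results
bound bookkeeping correctness, not behavioural realism.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DomainError
from .intake import confirm_meal, log_activity, log_water, substitute_food
from .model import (
    FoodItem,
    FoodPlan,
    HydrationRule,
    IntakeLog,
    Meal,
    NutrientVector,
    PlanTargets,
)
from .plan import WEEKDAY_KEYS, equivalent_foods, plan_totals

__all__ = ["FixtureSpec", "generate_food_table", "generate_plan", "generate_week"]

#: Macronutrient density ranges per 100 g by food class: (protein, carbs, lipids).
_FOOD_CLASSES: dict[str, tuple[tuple[float, float], tuple[float, float], tuple[float, float]]] = {
    "cereal": ((7, 13), (55, 75), (1, 7)),
    "protein": ((18, 30), (0, 5), (2, 15)),
    "dairy": ((3, 10), (4, 12), (1, 8)),
    "vegetable": ((1, 4), (3, 10), (0, 1)),
    "fruit": ((0.5, 1.5), (10, 20), (0, 1)),
    "fat": ((0, 2), (0, 5), (40, 80)),
    "legume": ((15, 25), (40, 60), (1, 5)),
}

_MEAL_HOURS = {
    "breakfast": 8,
    "morning_snack": 10,
    "lunch": 13,
    "afternoon_snack": 16,
    "dinner": 20,
    "supper": 22,
    "event": 18,
}

#: A Monday, so generated dates line up with weekday variant keys.
_WEEK_START = datetime.date(2022, 3, 7)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic world; generation is a pure function of ``seed``."""

    n_foods: int = 12
    plan_days: int = 7
    adherence: float = 0.85
    substitution_prob: float = 0.10
    water_sips_per_day: float = 8.0
    sip_volume_ml: tuple[float, float] = (200.0, 50.0)  # (mean, sd)
    activity_kcal: tuple[float, float] = (400.0, 100.0)  # (mean, sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foods <= 0:
            raise DomainError("n_foods must be > 0")
        if not (1 <= self.plan_days <= 7):
            raise DomainError("plan_days must lie in 1..7")
        for name in ("adherence", "substitution_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name} must lie in [0, 1]")


def generate_food_table(spec: FixtureSpec) -> dict[str, FoodItem]:
    """A reproducible food table with Atwater-consistent energies.

    Each food's energy is set to exactly 4·protein + 4·carbs + 9·lipids,
    and the four control micronutrients are populated in realistic ranges.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(_FOOD_CLASSES)
    table: dict[str, FoodItem] = {}
    for i in range(spec.n_foods):
        cls = classes[i % len(classes)]
        (p_lo, p_hi), (c_lo, c_hi), (l_lo, l_hi) = _FOOD_CLASSES[cls]
        protein = round(float(rng.uniform(p_lo, p_hi)), 1)
        carbs = round(float(rng.uniform(c_lo, c_hi)), 1)
        lipids = round(float(rng.uniform(l_lo, l_hi)), 1)
        nutrients = NutrientVector(
            energy=4.0 * protein + 4.0 * carbs + 9.0 * lipids,
            protein=protein,
            carbs=carbs,
            lipids=lipids,
            fiber=round(float(rng.uniform(0, 10)), 1),
            water=round(float(rng.uniform(5, 90)), 1),
            iron=round(float(rng.uniform(0.5, 5)), 2),
            calcium=round(float(rng.uniform(10, 300)), 1),
            sodium=round(float(rng.uniform(5, 500)), 1),
            magnesium=round(float(rng.uniform(10, 150)), 1),
        )
        food_id = f"F{i:03d}"
        table[food_id] = FoodItem(food_id=food_id, name=f"{cls}_{i}", nutrients_per_100g=nutrients)
    return table


def generate_plan(
    spec: FixtureSpec,
    food_table: Mapping[str, FoodItem],
    person_id: str = "P001",
) -> FoodPlan:
    """A week plan over the given food table, plus train/competition variants.

    Targets are set self-consistently from the generated meals (mean weekday
    energy; α/γ/β at the plan's own macro energy shares), which keeps the
    plan valid under its own targets — the regime a nutritionist would hand
    over.
    """
    rng = np.random.default_rng(spec.seed + 1)
    food_ids = sorted(food_table)
    meal_slots = ("breakfast", "lunch", "afternoon_snack", "dinner")

    def make_meals(slots: tuple[str, ...]) -> tuple[Meal, ...]:
        meals = []
        for slot in slots:
            n_items = int(rng.integers(1, 4))
            chosen = rng.choice(food_ids, size=min(n_items, len(food_ids)), replace=False)
            items = tuple((str(fid), float(rng.integers(5, 26)) * 10.0) for fid in chosen)
            meals.append(Meal(meal_type=slot, items=items))
        return tuple(meals)

    variants: dict[str, tuple[Meal, ...]] = {
        WEEKDAY_KEYS[d]: make_meals(meal_slots) for d in range(spec.plan_days)
    }
    variants["train"] = make_meals(("breakfast", "lunch", "dinner", "event"))
    variants["competition"] = make_meals(("breakfast", "event", "dinner"))

    # Self-consistent targets from the weekday variants' own totals.
    day_keys = [WEEKDAY_KEYS[d] for d in range(spec.plan_days)]
    draft = FoodPlan(
        plan_id="FIXTURE",
        person_id=person_id,
        variants=variants,
        targets=PlanTargets(energy_kcal=1.0, alpha=0.3, gamma=0.5, beta=0.2),
    )
    totals = [plan_totals(draft, k, food_table)[1] for k in day_keys]
    n = len(totals)
    energy = sum(t.energy for t in totals) / n
    protein = sum(t.protein for t in totals) / n
    carbs = sum(t.carbs for t in totals) / n
    alpha = 4.0 * protein / energy
    gamma = 4.0 * carbs / energy
    beta = 1.0 - alpha - gamma
    targets = PlanTargets(
        energy_kcal=energy,
        alpha=alpha,
        gamma=gamma,
        beta=beta,
        micronutrient_targets={
            m: sum(getattr(t, m) for t in totals) / n
            for m in ("iron", "calcium", "sodium", "magnesium")
        },
        fiber_g=sum(t.fiber for t in totals) / n,
        water_ml=2000.0,
    )
    return FoodPlan(
        plan_id="FIXTURE",
        person_id=person_id,
        variants=variants,
        targets=targets,
        water_rules=(HydrationRule(25.0, 300.0), HydrationRule(30.0, 500.0)),
    )


def generate_week(
    spec: FixtureSpec,
    plan: FoodPlan,
    food_table: Mapping[str, FoodItem],
) -> IntakeLog:
    """Seven days of simulated user behaviour against a plan.

    Each planned meal is eaten with probability ``adherence``; an eaten meal
    has one item swapped for an energy-equivalent food with probability
    ``substitution_prob`` (when an equivalent exists), else it is confirmed
    as planned. Water sips and a daily activity-calorie reading emulate the
    smart-bottle and smartwatch streams.
    """
    rng = np.random.default_rng(spec.seed + 2)
    log = IntakeLog()
    for day_offset in range(7):
        date = _WEEK_START + datetime.timedelta(days=day_offset)
        variant_key = WEEKDAY_KEYS[date.weekday() % len(WEEKDAY_KEYS)]
        if variant_key not in plan.variants:
            continue
        key = date.isoformat()
        for meal in plan.variant(variant_key):
            if rng.random() >= spec.adherence:
                continue  # meal skipped entirely
            ts = datetime.datetime.combine(date, datetime.time(_MEAL_HOURS[meal.meal_type]))
            swapped = False
            if meal.items and rng.random() < spec.substitution_prob:
                idx = int(rng.integers(0, len(meal.items)))
                old_id, qty = meal.items[idx]
                candidates = [
                    c
                    for c in equivalent_foods(food_table[old_id], qty, food_table, tolerance=0.5)
                    if c.food.food_id != old_id
                ]
                if candidates:
                    pick = candidates[int(rng.integers(0, len(candidates)))]
                    substitute_food(
                        log, plan, variant_key, meal.meal_type,
                        old_id, pick.food.food_id, pick.quantity_g, ts, key=key,
                    )
                    swapped = True
            if not swapped:
                confirm_meal(log, plan, variant_key, meal.meal_type, ts, key=key)
        n_sips = int(rng.poisson(spec.water_sips_per_day))
        for s in range(n_sips):
            volume = max(50.0, float(rng.normal(*spec.sip_volume_ml)))
            minute = int(rng.integers(0, 60))
            ts = datetime.datetime.combine(date, datetime.time(8 + (s % 12), minute))
            log_water(log, volume, ts, key=key, source="bottle")
        kcal = max(0.0, float(rng.normal(*spec.activity_kcal)))
        ts = datetime.datetime.combine(date, datetime.time(21, 30))
        log_activity(log, kcal, ts, key=key, source="watch")
    return log
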