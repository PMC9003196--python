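"""Food-plan construction and validation.

Turns a total-energy target into macronutrient quantities, aggregates a
plan's nutrient totals against a food composition table, validates those
totals against the nutritionist's targets, searches a food table for
nutritionally equivalent substitutes, and adjusts daily water goals to the
environment temperature.

The macronutrient split assigns fractions α (protein), γ (carbohydrate) and
β (lipid) of the day's energy, with α + γ + β = 1; gram quantities follow
from the Atwater factors 4/4/9 kcal per gram. Fiber and water carry no
energy here.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, UnknownFoodError, ValidationError
from .model import (
    FoodItem,
    FoodPlan,
    HydrationRule,
    Meal,
    NutrientVector,
    PlanTargets,
    check_hydration_rules,
    nv_add,
    nv_scale,
)

__all__ = [
    "ATWATER_KCAL_PER_G",
    "MacroSplit",
    "PlanDeviation",
    "SubstitutionCandidate",
    "HydrationRule",
    "macro_energy_split",
    "grams_per_kg",
    "total_grams",
    "plan_totals",
    "validate_plan",
    "equivalent_foods",
    "adjust_water_goal",
    "variant_for_key",
    "resolve_food",
]

#: Atwater energy densities, kcal per gram of macronutrient.
ATWATER_KCAL_PER_G: dict[str, float] = {"protein": 4.0, "carbs": 4.0, "lipids": 9.0}

#: Floor used when a relative error is taken against a zero target.
_REL_EPS = 1e-9

WEEKDAY_KEYS = ("monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday")


@dataclass(frozen=True)
class MacroSplit:
    """Energy and gram allocation of a day's energy to the three
    caloric macronutrients."""

    energy_protein: float
    energy_carbs: float
    energy_lipids: float
    grams_protein: float
    grams_carbs: float
    grams_lipids: float

    @property
    def total_energy(self) -> float:
        return self.energy_protein + self.energy_carbs + self.energy_lipids


@dataclass(frozen=True)
class PlanDeviation:
    """One nutrient whose plan total misses its target beyond tolerance."""

    scope: str  # "day" | "meal"
    nutrient: str
    target: float
    actual: float
    relative_error: float
    meal_type: str | None = None


@dataclass(frozen=True)
class SubstitutionCandidate:
    """A food that can stand in for another at an energy-matched quantity."""

    food: FoodItem
    quantity_g: float
    macro_error: float  # summed relative protein/carbs/lipids error


def macro_energy_split(energy_kcal: float, alpha: float, gamma: float, beta: float) -> MacroSplit:
    """Split day energy into macronutrient energies and gram quantities.

    α, γ, β are the protein/carb/lipid energy fractions (must sum to 1);
    grams divide each energy share by its Atwater factor.
    """
    if energy_kcal <= 0:
        raise DomainError(f"energy_kcal must be > 0, got {energy_kcal}")
    total = alpha + gamma + beta
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"alpha + gamma + beta must sum to 1, got {total}")
    for name, v in (("alpha", alpha), ("gamma", gamma), ("beta", beta)):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    e_p, e_c, e_l = alpha * energy_kcal, gamma * energy_kcal, beta * energy_kcal
    return MacroSplit(
        energy_protein=e_p,
        energy_carbs=e_c,
        energy_lipids=e_l,
        grams_protein=e_p / ATWATER_KCAL_PER_G["protein"],
        grams_carbs=e_c / ATWATER_KCAL_PER_G["carbs"],
        grams_lipids=e_l / ATWATER_KCAL_PER_G["lipids"],
    )


def grams_per_kg(total_g: float, weight_kg: float) -> float:
    """Express a daily gram quantity per kilogram of body weight."""
    if weight_kg <= 0:
        raise DomainError("weight_kg must be > 0")
    return total_g / weight_kg


def total_grams(g_per_kg: float, weight_kg: float) -> float:
    """Inverse of :func:`grams_per_kg`."""
    if weight_kg <= 0:
        raise DomainError("weight_kg must be > 0")
    return g_per_kg * weight_kg


def resolve_food(food_table: Mapping[str, FoodItem], food_id: str) -> FoodItem:
    try:
        return food_table[food_id]
    except KeyError:
        raise UnknownFoodError(food_id) from None


def meal_vector(meal: Meal, food_table: Mapping[str, FoodItem]) -> NutrientVector:
    """Nutrient total of one meal: Σ composition × quantity/100."""
    total = NutrientVector.zero()
    for food_id, qty in meal.items:
        total = nv_add(total, nv_scale(resolve_food(food_table, food_id).nutrients_per_100g, qty / 100.0))
    return total


def plan_totals(
    plan: FoodPlan, variant_key: str, food_table: Mapping[str, FoodItem]
) -> tuple[dict[str, NutrientVector], NutrientVector]:
    """Per-meal and whole-day nutrient totals of one plan variant."""
    per_meal: dict[str, NutrientVector] = {}
    day = NutrientVector.zero()
    for meal in plan.variant(variant_key):
        v = meal_vector(meal, food_table)
        per_meal[meal.meal_type] = nv_add(per_meal.get(meal.meal_type, NutrientVector.zero()), v)
        day = nv_add(day, v)
    return per_meal, day


def _relative_error(actual: float, target: float) -> float:
    return abs(actual - target) / max(target, _REL_EPS)


def target_vector(targets: PlanTargets) -> NutrientVector:
    """Day targets as a nutrient vector (macro grams via the energy split)."""
    split = macro_energy_split(targets.energy_kcal, targets.alpha, targets.gamma, targets.beta)
    micros = {m: float(targets.micronutrient_targets.get(m, 0.0)) for m in ("iron", "calcium", "sodium", "magnesium")}
    return NutrientVector(
        energy=targets.energy_kcal,
        protein=split.grams_protein,
        carbs=split.grams_carbs,
        lipids=split.grams_lipids,
        fiber=targets.fiber_g,
        water=targets.water_ml,
        **micros,
    )


def validate_plan(
    plan: FoodPlan,
    variant_key: str,
    food_table: Mapping[str, FoodItem],
    tolerance: float = 0.05,
) -> list[PlanDeviation]:
    """Check a plan variant against its targets.

    Day totals are compared per nutrient with a target (energy, the three
    macro gram quantities, fiber, and any micronutrient with a set target);
    per-meal energy is checked when the plan declares meal energy fractions.
    Returns one deviation per nutrient whose relative error exceeds
    ``tolerance``; an empty list means the variant meets its targets.
    """
    if tolerance < 0:
        raise DomainError("tolerance must be >= 0")
    per_meal, day = plan_totals(plan, variant_key, food_table)
    tv = target_vector(plan.targets)

    checked = ["energy", "protein", "carbs", "lipids"]
    if plan.targets.fiber_g > 0:
        checked.append("fiber")
    if plan.targets.water_ml > 0:
        checked.append("water")
    checked += sorted(plan.targets.micronutrient_targets)

    deviations: list[PlanDeviation] = []
    for nutrient in checked:
        target = getattr(tv, nutrient)
        actual = getattr(day, nutrient)
        err = _relative_error(actual, target)
        if err > tolerance:
            deviations.append(
                PlanDeviation(scope="day", nutrient=nutrient, target=target, actual=actual, relative_error=err)
            )

    fractions = plan.targets.meal_energy_fractions or {}
    for meal_type, fraction in sorted(fractions.items()):
        target = fraction * plan.targets.energy_kcal
        actual = per_meal.get(meal_type, NutrientVector.zero()).energy
        err = _relative_error(actual, target)
        if err > tolerance:
            deviations.append(
                PlanDeviation(
                    scope="meal",
                    nutrient="energy",
                    target=target,
                    actual=actual,
                    relative_error=err,
                    meal_type=meal_type,
                )
            )
    return deviations


def equivalent_foods(
    target: FoodItem,
    quantity_g: float,
    food_table: Mapping[str, FoodItem],
    tolerance: float = 0.15,
) -> list[SubstitutionCandidate]:
    """Foods that can replace ``quantity_g`` of ``target`` at equal energy.

    For every candidate the quantity ``q`` solving the energy match is
    ``q = quantity_g × E_target / E_candidate`` (per-100 g energies); foods
    with zero energy density cannot match and are skipped. A candidate
    survives when each of its protein/carb/lipid amounts at ``q`` is within
    ``tolerance`` (relative) of the target portion's. The ranking — summed
    relative macro error ascending, ties by food_id — is independent of
    food-table ordering. The target food itself always ranks first with zero
    error.
    """
    if tolerance <= 0:
        raise DomainError("tolerance must be > 0")
    if quantity_g <= 0:
        raise DomainError("quantity_g must be > 0")
    want = target.portion(quantity_g)
    candidates: list[SubstitutionCandidate] = []
    for food in food_table.values():
        e100 = food.nutrients_per_100g.energy
        if e100 <= 0:
            continue
        q = quantity_g * target.nutrients_per_100g.energy / e100
        if q <= 0:
            continue
        got = food.portion(q)
        errors = [
            _relative_error(getattr(got, m), getattr(want, m))
            for m in ("protein", "carbs", "lipids")
        ]
        if all(err <= tolerance for err in errors):
            candidates.append(SubstitutionCandidate(food=food, quantity_g=q, macro_error=sum(errors)))
    candidates.sort(key=lambda c: (c.macro_error, c.food.food_id))
    return candidates


def adjust_water_goal(
    base_ml: float, temperature_c: float, rules: Iterable[HydrationRule]
) -> float:
    """Daily water goal adjusted for environment temperature.

    Each rule whose threshold the temperature strictly exceeds adds its
    increment; the result is monotone non-decreasing in temperature and
    equals the base at or below the first threshold.
    """
    if base_ml < 0:
        raise DomainError("base_ml must be >= 0")
    rules = check_hydration_rules(rules)
    return base_ml + sum(r.extra_ml for r in rules if temperature_c > r.threshold_c)


def variant_for_key(plan: FoodPlan, key: str) -> str:
    """Map a log key (ISO date or event label) to a plan variant key.

    Dates map to their weekday name (``"monday"``…); event labels must match
    a variant directly.
    """
    try:
        day = datetime.date.fromisoformat(key)
    except ValueError:
        if key in plan.variants:
            return key
        raise ValidationError(f"no plan variant for event key {key!r}") from None
    weekday = WEEKDAY_KEYS[day.weekday()]
    if weekday in plan.variants:
        return weekday
    raise ValidationError(f"no plan variant for weekday {weekday!r} (key {key!r})")
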