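"""Core domain model: nutrient accounting, persons, appointments, plans and logs.

The universal accounting currency is :class:`NutrientVector`: energy plus the
three caloric macronutrients, fiber, water, and the four control
micronutrients (iron, calcium, sodium, magnesium) that nutritionists track
across population groups. Vector addition and scalar scaling are exact
component-wise bookkeeping — no hidden rounding anywhere in the model.

Quantities are stored in grams and food composition per 100 g (the dominant
food-table convention), so scaling a composition to a portion uses the factor
``quantity_g / 100``. Persons carry only an opaque ``id``: names and contact
details never enter these types.
"""

from __future__ import annotations

import dataclasses
import datetime
import enum
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

from .errors import DomainError, ValidationError

__all__ = [
    "NUTRIENT_FIELDS",
    "MICRONUTRIENTS",
    "GOAL_METRICS",
    "LIFESTYLES",
    "MEAL_TYPES",
    "NutrientVector",
    "Person",
    "Appointment",
    "FoodItem",
    "Meal",
    "HydrationRule",
    "PlanTargets",
    "FoodPlan",
    "LogKind",
    "LogEntry",
    "IntakeLog",
    "nv_add",
    "nv_scale",
]

#: Component order of a NutrientVector: (field name, unit).
NUTRIENT_FIELDS: tuple[tuple[str, str], ...] = (
    ("energy", "kcal"),
    ("protein", "g"),
    ("carbs", "g"),
    ("lipids", "g"),
    ("fiber", "g"),
    ("water", "mL"),
    ("iron", "mg"),
    ("calcium", "mg"),
    ("sodium", "mg"),
    ("magnesium", "mg"),
)

#: The four control micronutrients.
MICRONUTRIENTS: tuple[str, ...] = ("iron", "calcium", "sodium", "magnesium")

#: Goal metrics a nutritionist may set targets for in an appointment.
GOAL_METRICS: frozenset[str] = frozenset(
    {
        "weight",
        "body_fat",
        "visceral_fat",
        "fat_free_mass",
        "muscle_mass",
        "body_mass_index",
        "exercise_performance",
    }
)

#: Physical-intensity lifestyle categories (see :mod:`nutricontrol.energy`).
LIFESTYLES: tuple[str, ...] = ("sedentary_light", "moderate", "vigorous")

#: Meal slots of a plan day, plus "event" for out-of-schedule occasions.
MEAL_TYPES: tuple[str, ...] = (
    "breakfast",
    "morning_snack",
    "lunch",
    "afternoon_snack",
    "dinner",
    "supper",
    "event",
)


@dataclass(frozen=True)
class NutrientVector:
    """Amounts of energy and nutrients; all components non-negative.

    Units: energy kcal; protein/carbs/lipids/fiber g; water mL;
    iron/calcium/sodium/magnesium mg.
    """

    energy: float = 0.0
    protein: float = 0.0
    carbs: float = 0.0
    lipids: float = 0.0
    fiber: float = 0.0
    water: float = 0.0
    iron: float = 0.0
    calcium: float = 0.0
    sodium: float = 0.0
    magnesium: float = 0.0

    def __post_init__(self) -> None:
        for name, _unit in NUTRIENT_FIELDS:
            value = getattr(self, name)
            if value < 0:
                raise DomainError(f"NutrientVector.{name} must be >= 0, got {value}")

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(
            **{name: getattr(self, name) + getattr(other, name) for name, _ in NUTRIENT_FIELDS}
        )

    def scale(self, factor: float) -> "NutrientVector":
        """Component-wise scaling by a non-negative dimensionless factor."""
        if factor < 0:
            raise DomainError(f"scale factor must be >= 0, got {factor}")
        return NutrientVector(
            **{name: getattr(self, name) * factor for name, _ in NUTRIENT_FIELDS}
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name, _ in NUTRIENT_FIELDS}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name, _ in NUTRIENT_FIELDS)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "NutrientVector":
        known = {name for name, _ in NUTRIENT_FIELDS}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown nutrient fields: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def zero(cls) -> "NutrientVector":
        return cls()


def nv_add(a: NutrientVector, b: NutrientVector) -> NutrientVector:
    """Component-wise sum of two nutrient vectors."""
    return a + b


def nv_scale(v: NutrientVector, factor: float) -> NutrientVector:
    """Component-wise product; ``factor = quantity_g / 100`` converts a
    per-100 g composition to an actual portion."""
    return v.scale(factor)


@dataclass(frozen=True)
class Person:
    """Anthropometric profile behind an opaque identifier.

    ``weight_kg`` and ``height_m`` are mandatory; body-composition masses are
    optional because they require a measurement the person may not have.
    """

    id: str
    sex: str  # "male" | "female"
    age_years: float
    weight_kg: float
    height_m: float
    fat_mass_kg: Optional[float] = None
    lean_mass_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight_kg <= 0:
            raise DomainError("weight_kg must be > 0")
        if self.height_m <= 0:
            raise DomainError("height_m must be > 0")
        if self.age_years < 0:
            raise DomainError("age_years must be >= 0")
        if self.fat_mass_kg is not None and not (0 <= self.fat_mass_kg < self.weight_kg):
            raise DomainError("fat_mass_kg must satisfy 0 <= fat_mass < weight")

    @property
    def height_cm(self) -> float:
        """Height in centimetres — the native unit of the BMR equations."""
        return self.height_m * 100.0

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Person":
        return cls(
            id=str(data["id"]),
            sex=data["sex"],
            age_years=float(data["age_years"]),
            weight_kg=float(data["weight_kg"]),
            height_m=float(data["height_m"]),
            fat_mass_kg=None if data.get("fat_mass_kg") is None else float(data["fat_mass_kg"]),
            lean_mass_kg=None if data.get("lean_mass_kg") is None else float(data["lean_mass_kg"]),
        )


@dataclass(frozen=True)
class Appointment:
    """What the nutritionist captures in a consultation: metrics, goals and
    lifestyle context that drive food-plan creation."""

    person: Person
    date: datetime.date
    goals: Mapping[str, float] = field(default_factory=dict)
    lifestyle: str = "sedentary_light"
    context: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.goals) - GOAL_METRICS
        if bad:
            raise ValidationError(f"unknown goal metrics: {sorted(bad)}")
        if self.lifestyle not in LIFESTYLES:
            raise ValidationError(
                f"lifestyle must be one of {LIFESTYLES}, got {self.lifestyle!r}"
            )

    def as_dict(self) -> dict[str, Any]:
        return {
            "person": self.person.as_dict(),
            "date": self.date.isoformat(),
            "goals": dict(self.goals),
            "lifestyle": self.lifestyle,
            "context": dict(self.context),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Appointment":
        return cls(
            person=Person.from_dict(data["person"]),
            date=datetime.date.fromisoformat(data["date"]),
            goals={k: float(v) for k, v in data.get("goals", {}).items()},
            lifestyle=data.get("lifestyle", "sedentary_light"),
            context={k: str(v) for k, v in data.get("context", {}).items()},
        )


@dataclass(frozen=True)
class FoodItem:
    """One row of a food composition table: nutrients per 100 g of food."""

    food_id: str
    name: str
    nutrients_per_100g: NutrientVector

    def portion(self, quantity_g: float) -> NutrientVector:
        """Nutrients of ``quantity_g`` grams of this food."""
        if quantity_g < 0:
            raise DomainError("quantity_g must be >= 0")
        return self.nutrients_per_100g.scale(quantity_g / 100.0)


@dataclass(frozen=True)
class Meal:
    """A meal slot with its (food_id, quantity_g) items."""

    meal_type: str
    items: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValidationError(
                f"meal_type must be one of {MEAL_TYPES}, got {self.meal_type!r}"
            )
        object.__setattr__(self, "items", tuple((fid, float(q)) for fid, q in self.items))
        for fid, qty in self.items:
            if qty <= 0:
                raise ValidationError(f"quantity_g must be > 0 for {fid!r}, got {qty}")

    def as_dict(self) -> dict[str, Any]:
        return {
            "meal_type": self.meal_type,
            "items": [{"food_id": f, "quantity_g": q} for f, q in self.items],
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Meal":
        return cls(
            meal_type=data["meal_type"],
            items=tuple((i["food_id"], float(i["quantity_g"])) for i in data.get("items", [])),
        )


@dataclass(frozen=True)
class HydrationRule:
    """Add ``extra_ml`` to the daily water goal once the environment
    temperature strictly exceeds ``threshold_c``. Rules accumulate."""

    threshold_c: float
    extra_ml: float

    def __post_init__(self) -> None:
        if self.extra_ml < 0:
            raise DomainError("extra_ml must be >= 0")


def check_hydration_rules(rules: Iterable[HydrationRule]) -> tuple[HydrationRule, ...]:
    """Validate that thresholds are strictly increasing; returns a tuple."""
    rules = tuple(rules)
    for a, b in zip(rules, rules[1:]):
        if b.threshold_c <= a.threshold_c:
            raise ValidationError(
                f"hydration rule thresholds must be strictly increasing: "
                f"{a.threshold_c} then {b.threshold_c}"
            )
    return rules


@dataclass(frozen=True)
class PlanTargets:
    """Daily targets of a food plan.

    ``energy_kcal`` is the TEE estimate; ``alpha``/``gamma``/``beta`` are the
    fractions of that energy assigned to protein, carbohydrate and lipid and
    must sum to 1. ``meal_energy_fractions`` optionally splits day energy
    between meal slots (nutritionist-chosen, e.g. lunch 0.30).
    """

    energy_kcal: float
    alpha: float
    gamma: float
    beta: float
    micronutrient_targets: Mapping[str, float] = field(default_factory=dict)
    fiber_g: float = 0.0
    water_ml: float = 0.0
    meal_energy_fractions: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "beta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        total = self.alpha + self.gamma + self.beta
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"alpha + gamma + beta must equal 1, got {total}")
        bad = set(self.micronutrient_targets) - set(MICRONUTRIENTS)
        if bad:
            raise ValidationError(f"unknown micronutrient targets: {sorted(bad)}")
        if self.meal_energy_fractions is not None:
            bad = set(self.meal_energy_fractions) - set(MEAL_TYPES)
            if bad:
                raise ValidationError(f"unknown meal types in energy fractions: {sorted(bad)}")

    def as_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "energy_kcal": self.energy_kcal,
            "alpha": self.alpha,
            "gamma": self.gamma,
            "beta": self.beta,
            "micronutrient_targets": dict(self.micronutrient_targets),
            "fiber_g": self.fiber_g,
            "water_ml": self.water_ml,
        }
        if self.meal_energy_fractions is not None:
            d["meal_energy_fractions"] = dict(self.meal_energy_fractions)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PlanTargets":
        return cls(
            energy_kcal=float(data["energy_kcal"]),
            alpha=float(data["alpha"]),
            gamma=float(data["gamma"]),
            beta=float(data["beta"]),
            micronutrient_targets={
                k: float(v) for k, v in data.get("micronutrient_targets", {}).items()
            },
            fiber_g=float(data.get("fiber_g", 0.0)),
            water_ml=float(data.get("water_ml", 0.0)),
            meal_energy_fractions=(
                {k: float(v) for k, v in data["meal_energy_fractions"].items()}
                if data.get("meal_energy_fractions") is not None
                else None
            ),
        )


@dataclass(frozen=True)
class FoodPlan:
    """A nutritionist-authored plan: meal schedules per variant key.

    Variant keys are days of the week (``"monday"`` … ``"sunday"``) or event
    labels such as ``"train"`` or ``"competition"``.
    """

    plan_id: str
    person_id: str
    variants: Mapping[str, tuple[Meal, ...]]
    targets: PlanTargets
    water_rules: tuple[HydrationRule, ...] = ()

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("a food plan needs at least one variant")
        object.__setattr__(
            self,
            "variants",
            {k: tuple(meals) for k, meals in dict(self.variants).items()},
        )
        object.__setattr__(self, "water_rules", check_hydration_rules(self.water_rules))

    def variant(self, variant_key: str) -> tuple[Meal, ...]:
        try:
            return self.variants[variant_key]
        except KeyError:
            raise ValidationError(
                f"plan {self.plan_id!r} has no variant {variant_key!r}; "
                f"available: {sorted(self.variants)}"
            ) from None

    def meal(self, variant_key: str, meal_type: str) -> Meal:
        for m in self.variant(variant_key):
            if m.meal_type == meal_type:
                return m
        raise ValidationError(
            f"variant {variant_key!r} of plan {self.plan_id!r} has no {meal_type!r} meal"
        )

    def as_dict(self) -> dict[str, Any]:
        return {
            "plan_id": self.plan_id,
            "person_id": self.person_id,
            "variants": {k: [m.as_dict() for m in v] for k, v in self.variants.items()},
            "targets": self.targets.as_dict(),
            "water_rules": [
                {"threshold_c": r.threshold_c, "extra_ml": r.extra_ml} for r in self.water_rules
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FoodPlan":
        return cls(
            plan_id=str(data["plan_id"]),
            person_id=str(data["person_id"]),
            variants={
                k: tuple(Meal.from_dict(m) for m in meals)
                for k, meals in data["variants"].items()
            },
            targets=PlanTargets.from_dict(data["targets"]),
            water_rules=tuple(
                HydrationRule(float(r["threshold_c"]), float(r["extra_ml"]))
                for r in data.get("water_rules", [])
            ),
        )


class LogKind(str, enum.Enum):
    """Event kinds an intake log can record."""

    MEAL_CONFIRM = "meal_confirm"
    PARTIAL = "partial"
    SUBSTITUTION = "substitution"
    EXTRA_FOOD = "extra_food"
    FOOD_REMOVED = "food_removed"
    WATER = "water"
    ACTIVITY_CALORIES = "activity_calories"


@dataclass(frozen=True)
class LogEntry:
    """One time-stamped event, tied to a calendar day (ISO date key) or to a
    named event such as ``"train"``."""

    timestamp: datetime.datetime
    key: str
    kind: LogKind
    meal_type: Optional[str] = None
    food_id: Optional[str] = None
    old_food_id: Optional[str] = None
    new_food_id: Optional[str] = None
    quantity_g: Optional[float] = None
    percentage: Optional[float] = None
    volume_ml: Optional[float] = None
    kcal: Optional[float] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind is LogKind.PARTIAL:
            if self.percentage is None or not (0 < self.percentage <= 100):
                raise DomainError(
                    f"partial intake percentage must lie in (0, 100], got {self.percentage}"
                )
        if self.kind is LogKind.WATER:
            if self.volume_ml is None or self.volume_ml <= 0:
                raise DomainError(f"water volume_ml must be > 0, got {self.volume_ml}")
        if self.kind is LogKind.ACTIVITY_CALORIES:
            if self.kcal is None or self.kcal < 0:
                raise DomainError(f"activity kcal must be >= 0, got {self.kcal}")
        if self.kind in (LogKind.EXTRA_FOOD, LogKind.SUBSTITUTION):
            if self.quantity_g is None or self.quantity_g <= 0:
                raise DomainError(f"quantity_g must be > 0, got {self.quantity_g}")


@dataclass
class IntakeLog:
    """Append-only sequence of log entries for one person."""

    entries: list[LogEntry] = field(default_factory=list)

    def add(self, entry: LogEntry) -> "IntakeLog":
        self.entries.append(entry)
        return self

    def for_key(self, key: str) -> list[LogEntry]:
        return [e for e in self.entries if e.key == key]

    def __len__(self) -> int:
        return len(self.entries)
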