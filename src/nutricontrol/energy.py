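"""Energy-expenditure estimation.

Resting energy expenditure (REE) is approximated by the classic basal
metabolic rate (BMR) equation family — Harris–Benedict (original
coefficients), Mifflin-St Jeor, Katch-McArdle and Cunningham — each frozen
here as published so results are reproducible without any external lookup.

The physical activity level ``PAL = TEE / REE`` scales REE up to total energy
expenditure (TEE). PAL comes either from a lifestyle category lookup or from
a 24-hour time-allocation over habitual activities, each weighted by its
physical activity ratio (PAR, a multiple of BMR; PAR = 1 at rest). Gender
does not enter PAL: the BMR already absorbs the difference in energy needs.

Daily caloric balance is ``CB = CC - PEE - REE - TEF`` where CC is caloric
consumption, PEE the physical-activity expenditure (e.g. smartwatch-logged)
and TEF the thermic effect of food, carried as a parameter defaulting to 0
because it is not measured here.

UNITS — read carefully: BMI takes height in METRES; the BMR equations take
height in CENTIMETRES (each formula's native convention).
:meth:`nutricontrol.model.Person.height_cm` converts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from ._utils import round_half_up
from .errors import DomainError, ValidationError

__all__ = [
    "LIFESTYLE_PAL_RANGES",
    "REFERENCE_DAY_ACTIVITIES",
    "EnergyComponents",
    "ActivityProfile",
    "PalRange",
    "TimeAllocationResult",
    "bmi",
    "ree_harris_benedict",
    "ree_mifflin",
    "ree_katch_mcardle",
    "ree_cunningham",
    "fat_free_mass",
    "pal_from_lifestyle",
    "pal_from_time_allocation",
    "tee",
    "caloric_balance",
    "m_to_cm",
    "cm_to_m",
]

#: PAL ranges per physical-intensity lifestyle category.
LIFESTYLE_PAL_RANGES: dict[str, tuple[float, float]] = {
    "sedentary_light": (1.40, 1.69),
    "moderate": (1.70, 1.99),
    "vigorous": (2.00, 2.40),
}

#: Reference day of habitual activities for a population group, with
#: FAO/WHO-style PAR factors: the worked time-allocation example this
#: package reproduces (Σ hours = 24, Σ time×PAR = 42.6, PAL ≈ 1.8).
REFERENCE_DAY_ACTIVITIES: tuple[tuple[str, float, float], ...] = (
    ("Sleeping", 6, 1.0),
    ("Personal Care (dressing, showering)", 2, 2.3),
    ("Eating", 2, 1.5),
    ("Walking without a load", 2, 3.2),
    ("Sitting", 4, 1.5),
    ("Cooking", 2, 2.1),
    ("Household work", 2, 2.8),
    ("Light leisure activities", 2, 1.4),
    ("Driving car", 2, 2.0),
)


def m_to_cm(height_m: float) -> float:
    return height_m * 100.0


def cm_to_m(height_cm: float) -> float:
    return height_cm / 100.0


@dataclass(frozen=True)
class EnergyComponents:
    """Caloric balance decomposition; all components in kcal/day.

    ``cb = cc - pee - ree - tef`` holds exactly by construction.
    """

    cc: float
    pee: float
    ree: float
    tef: float
    cb: float

    def __post_init__(self) -> None:
        if self.cb != self.cc - self.pee - self.ree - self.tef:
            raise ValidationError("cb must equal cc - pee - ree - tef exactly")


class PalRange(NamedTuple):
    low: float
    high: float
    midpoint: float


class TimeAllocationResult(NamedTuple):
    """PAL from a 24-hour activity breakdown.

    ``total_time_par`` is the intermediate Σ(hours × PAR); ``pal`` the exact
    quotient over 24 h; ``pal_1dp`` the conventional one-decimal (half-up)
    report.
    """

    pal: float
    total_time_par: float
    pal_1dp: float


@dataclass(frozen=True)
class ActivityProfile:
    """How a person's PAL was obtained: lifestyle lookup or time allocation."""

    method: str  # "lifestyle" | "time_allocation"
    pal: float
    lifestyle: Optional[str] = None
    activities: Optional[tuple[tuple[str, float, float], ...]] = None

    def __post_init__(self) -> None:
        if self.method not in ("lifestyle", "time_allocation"):
            raise ValidationError(f"unknown PAL method {self.method!r}")
        if self.pal <= 0:
            raise DomainError("PAL must be > 0")


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m². Height in METRES."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("bmi requires weight_kg > 0 and height_m > 0")
    return weight_kg / height_m**2


def _check_bmr_inputs(weight_kg: float, height_cm: float, age_years: float) -> None:
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("BMR equations require weight_kg > 0 and height_cm > 0")
    if age_years < 0:
        raise DomainError("age_years must be >= 0")


def ree_harris_benedict(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    """Harris–Benedict REE, kcal/day, original coefficients. Height in CM.

    men:   66.4730 + 13.7516·W + 5.0033·H − 6.7550·A
    women: 655.0955 + 9.5634·W + 1.8496·H − 4.6756·A
    """
    _check_bmr_inputs(weight_kg, height_cm, age_years)
    if sex == "male":
        return 66.4730 + 13.7516 * weight_kg + 5.0033 * height_cm - 6.7550 * age_years
    if sex == "female":
        return 655.0955 + 9.5634 * weight_kg + 1.8496 * height_cm - 4.6756 * age_years
    raise DomainError(f"sex must be 'male' or 'female', got {sex!r}")


def ree_mifflin(sex: str, weight_kg: float, height_cm: float, age_years: float) -> float:
    """Mifflin-St Jeor REE, kcal/day. Height in CM.

    10·W + 6.25·H − 5·A + 5 (men) or − 161 (women).
    """
    _check_bmr_inputs(weight_kg, height_cm, age_years)
    base = 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age_years
    if sex == "male":
        return base + 5.0
    if sex == "female":
        return base - 161.0
    raise DomainError(f"sex must be 'male' or 'female', got {sex!r}")


def ree_katch_mcardle(lean_mass_kg: float) -> float:
    """Katch-McArdle REE from lean (fat-free) mass: 370 + 21.6·LBM."""
    if lean_mass_kg < 0:
        raise DomainError("lean_mass_kg must be >= 0")
    return 370.0 + 21.6 * lean_mass_kg


def ree_cunningham(lean_mass_kg: float) -> float:
    """Cunningham REE from lean (fat-free) mass: 500 + 22·LBM."""
    if lean_mass_kg < 0:
        raise DomainError("lean_mass_kg must be >= 0")
    return 500.0 + 22.0 * lean_mass_kg


def fat_free_mass(weight_kg: float, fat_mass_kg: float) -> float:
    """Fat-free mass = weight − fat mass, kg."""
    if fat_mass_kg < 0:
        raise DomainError("fat_mass_kg must be >= 0")
    if fat_mass_kg >= weight_kg:
        raise DomainError(
            f"fat_mass_kg ({fat_mass_kg}) must be strictly less than weight_kg ({weight_kg})"
        )
    return weight_kg - fat_mass_kg


def pal_from_lifestyle(category: str) -> PalRange:
    """PAL range (and midpoint) for a physical-intensity lifestyle category."""
    try:
        low, high = LIFESTYLE_PAL_RANGES[category]
    except KeyError:
        raise DomainError(
            f"unknown lifestyle category {category!r}; expected one of "
            f"{sorted(LIFESTYLE_PAL_RANGES)}"
        ) from None
    return PalRange(low, high, (low + high) / 2.0)


def pal_from_time_allocation(
    activities: Sequence[tuple[float, float] | tuple[str, float, float]],
) -> TimeAllocationResult:
    """PAL from a 24-hour breakdown of (hours, PAR) activities.

    Accepts ``(hours, par)`` pairs or named ``(name, hours, par)`` triples.
    Hours must sum to 24 and every PAR must be >= 1 (1 means resting, no
    energy requirement above REE). PAL = Σ(hours × PAR) / 24.
    """
    pairs: list[tuple[float, float]] = []
    for item in activities:
        if len(item) == 3:
            _, hours, par = item  # type: ignore[misc]
        else:
            hours, par = item  # type: ignore[misc]
        pairs.append((float(hours), float(par)))
    total_hours = sum(h for h, _ in pairs)
    if abs(total_hours - 24.0) > 1e-9:
        raise ValidationError(
            f"activity hours must sum to 24, got {total_hours} "
            f"({24.0 - total_hours:+g} h unaccounted)"
        )
    for hours, par in pairs:
        if hours < 0:
            raise DomainError(f"activity hours must be >= 0, got {hours}")
        if par < 1.0:
            raise DomainError(f"PAR must be >= 1 (1 = rest), got {par}")
    total_time_par = sum(h * p for h, p in pairs)
    pal = total_time_par / 24.0
    return TimeAllocationResult(pal=pal, total_time_par=total_time_par, pal_1dp=round_half_up(pal, 1))


def tee(ree: float, pal: float) -> float:
    """Total energy expenditure = REE × PAL, kcal/day."""
    if ree <= 0:
        raise DomainError("ree must be > 0")
    if pal <= 0:
        raise DomainError("pal must be > 0")
    return ree * pal


def caloric_balance(cc: float, pee: float, ree: float, tef: float = 0.0) -> EnergyComponents:
    """Daily caloric balance CB = CC − PEE − REE − TEF (may be negative)."""
    for name, v in (("cc", cc), ("pee", pee), ("ree", ree), ("tef", tef)):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    return EnergyComponents(cc=cc, pee=pee, ree=ree, tef=tef, cb=cc - pee - ree - tef)
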