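"""Intake and hydration logging, device-export ingestion, daily statistics.

Users confirm planned meals (fully or as a percentage), swap or remove
individual foods inside a meal, log extra foods, and log water; smart-bottle
and smartwatch exports arrive as ``timestamp,value`` CSV files. Statistics
for a day (or a named event) pair what was consumed against the plan's
targets, with the water goal optionally adjusted for the day's temperature.

Accounting model: substitution and removal entries *modify* the planned
meal's composition; a meal is counted as consumed exactly once when any
confirm / partial / substitution / removal entry exists for it, and a
partial percentage scales the (modified) meal. Confirm and partial are
mutually exclusive per (key, meal type). Statistics are therefore a pure
function of the set of entries, independent of logging order. Extra foods
count against the day total only, not any particular meal.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from .errors import ConflictError, DomainError, ValidationError
from .model import (
    FoodItem,
    FoodPlan,
    IntakeLog,
    LogEntry,
    LogKind,
    NutrientVector,
    nv_add,
    nv_scale,
)
from .plan import adjust_water_goal, resolve_food, target_vector

__all__ = [
    "DailyStats",
    "IngestReport",
    "confirm_meal",
    "log_partial",
    "log_extra_food",
    "substitute_food",
    "remove_food",
    "log_water",
    "log_activity",
    "ingest_device_csv",
    "daily_stats",
]

#: Entry kinds that mark a planned meal as consumed.
_MEAL_KINDS = (LogKind.MEAL_CONFIRM, LogKind.PARTIAL, LogKind.SUBSTITUTION, LogKind.FOOD_REMOVED)


@dataclass(frozen=True)
class DailyStats:
    """Consumption of one day (or event) paired with the plan's targets.

    ``fraction_of_target`` maps each nutrient to consumed/target, or ``None``
    where the target is zero (undefined rather than a division error).
    """

    key: str
    consumed: NutrientVector
    target: NutrientVector
    water_consumed_ml: float
    water_target_ml: float
    pee_logged_kcal: float
    fraction_of_target: Mapping[str, Optional[float]]


@dataclass
class IngestReport:
    """Outcome of one device-CSV ingestion batch."""

    accepted: int = 0
    skipped_duplicates: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)


def _meal_entries(log: IntakeLog, key: str, meal_type: str) -> list[LogEntry]:
    return [e for e in log.for_key(key) if e.kind in _MEAL_KINDS and e.meal_type == meal_type]


def _check_no_confirm_or_partial(log: IntakeLog, key: str, meal_type: str) -> None:
    for e in _meal_entries(log, key, meal_type):
        if e.kind in (LogKind.MEAL_CONFIRM, LogKind.PARTIAL):
            raise ConflictError(
                f"meal {meal_type!r} on {key!r} already logged as {e.kind.value}"
            )


def confirm_meal(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    meal_type: str,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
) -> IntakeLog:
    """Record that a planned meal was eaten exactly as planned.

    Re-confirming the same (key, meal type), or confirming after a partial,
    raises :class:`ConflictError`.
    """
    key = key if key is not None else timestamp.date().isoformat()
    plan.meal(variant_key, meal_type)  # existence check
    _check_no_confirm_or_partial(log, key, meal_type)
    return log.add(LogEntry(timestamp=timestamp, key=key, kind=LogKind.MEAL_CONFIRM, meal_type=meal_type))


def log_partial(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    meal_type: str,
    percentage: float,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
) -> IntakeLog:
    """Record a partial intake: ``percentage`` ∈ (0, 100] of the planned meal."""
    key = key if key is not None else timestamp.date().isoformat()
    plan.meal(variant_key, meal_type)
    _check_no_confirm_or_partial(log, key, meal_type)
    return log.add(
        LogEntry(timestamp=timestamp, key=key, kind=LogKind.PARTIAL, meal_type=meal_type, percentage=percentage)
    )


def log_extra_food(
    log: IntakeLog,
    food_table: Mapping[str, FoodItem],
    food_id: str,
    quantity_g: float,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
) -> IntakeLog:
    """Record food eaten outside the plan; counts toward the day total."""
    key = key if key is not None else timestamp.date().isoformat()
    resolve_food(food_table, food_id)
    return log.add(
        LogEntry(timestamp=timestamp, key=key, kind=LogKind.EXTRA_FOOD, food_id=food_id, quantity_g=quantity_g)
    )


def substitute_food(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    meal_type: str,
    old_food_id: str,
    new_food_id: str,
    quantity_g: float,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
) -> IntakeLog:
    """Swap one planned food for ``quantity_g`` of another inside a meal.

    The meal counts as consumed with the swap applied; the event itself is
    kept so the preference model can learn from it.
    """
    key = key if key is not None else timestamp.date().isoformat()
    meal = plan.meal(variant_key, meal_type)
    if old_food_id not in {fid for fid, _ in meal.items}:
        raise ValidationError(
            f"{old_food_id!r} is not part of the planned {meal_type!r} meal"
        )
    return log.add(
        LogEntry(
            timestamp=timestamp,
            key=key,
            kind=LogKind.SUBSTITUTION,
            meal_type=meal_type,
            old_food_id=old_food_id,
            new_food_id=new_food_id,
            quantity_g=quantity_g,
        )
    )


def remove_food(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    meal_type: str,
    food_id: str,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
) -> IntakeLog:
    """Record a meal eaten without one of its planned foods."""
    key = key if key is not None else timestamp.date().isoformat()
    meal = plan.meal(variant_key, meal_type)
    if food_id not in {fid for fid, _ in meal.items}:
        raise ValidationError(f"{food_id!r} is not part of the planned {meal_type!r} meal")
    return log.add(
        LogEntry(timestamp=timestamp, key=key, kind=LogKind.FOOD_REMOVED, meal_type=meal_type, food_id=food_id)
    )


def log_water(
    log: IntakeLog,
    volume_ml: float,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
    source: str = "manual",
) -> IntakeLog:
    """Record a water intake; ``source`` is "manual" or "bottle"."""
    key = key if key is not None else timestamp.date().isoformat()
    return log.add(
        LogEntry(timestamp=timestamp, key=key, kind=LogKind.WATER, volume_ml=volume_ml, source=source)
    )


def log_activity(
    log: IntakeLog,
    kcal: float,
    timestamp: datetime.datetime,
    key: Optional[str] = None,
    source: str = "watch",
) -> IntakeLog:
    """Record physical-activity calories (smartwatch or manual)."""
    key = key if key is not None else timestamp.date().isoformat()
    return log.add(
        LogEntry(timestamp=timestamp, key=key, kind=LogKind.ACTIVITY_CALORIES, kcal=kcal, source=source)
    )


def ingest_device_csv(log: IntakeLog, path: str | Path, kind: str) -> tuple[IntakeLog, IngestReport]:
    """Ingest a device export: header ``timestamp,value``, one reading per row.

    ``kind`` is ``"water"`` (smart-bottle volumes, mL) or ``"activity"``
    (smartwatch active calories, kcal). Malformed rows are rejected with
    their line number and never abort the batch. Duplicate timestamps —
    within the file or against device entries already in the log — are
    skipped, first occurrence wins.
    """
    if kind not in ("water", "activity"):
        raise DomainError(f"device kind must be 'water' or 'activity', got {kind!r}")
    entry_kind = LogKind.WATER if kind == "water" else LogKind.ACTIVITY_CALORIES
    source = "bottle" if kind == "water" else "watch"
    seen = {
        e.timestamp
        for e in log.entries
        if e.kind is entry_kind and e.source == source
    }
    report = IngestReport()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 and row and row[0].strip().lower() == "timestamp":
                continue  # header
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                report.rejected.append((lineno, "expected 2 columns (timestamp,value)"))
                continue
            try:
                ts = datetime.datetime.fromisoformat(row[0].strip())
            except ValueError:
                report.rejected.append((lineno, f"bad timestamp {row[0]!r}"))
                continue
            try:
                value = float(row[1])
            except ValueError:
                report.rejected.append((lineno, f"bad value {row[1]!r}"))
                continue
            if ts in seen:
                report.skipped_duplicates += 1
                continue
            try:
                if kind == "water":
                    log_water(log, value, ts, source=source)
                else:
                    log_activity(log, value, ts, source=source)
            except DomainError as exc:
                report.rejected.append((lineno, str(exc)))
                continue
            seen.add(ts)
            report.accepted += 1
    return log, report


def consumed_vector(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    key: str,
    food_table: Mapping[str, FoodItem],
) -> NutrientVector:
    """Exact nutrient sum of everything logged as eaten under ``key``."""
    entries = log.for_key(key)
    total = NutrientVector.zero()

    # Planned meals: composition modifiers first, then one consumption.
    by_meal: dict[str, list[LogEntry]] = {}
    for e in entries:
        if e.kind in _MEAL_KINDS and e.meal_type is not None:
            by_meal.setdefault(e.meal_type, []).append(e)
    for meal_type, meal_entries in by_meal.items():
        meal = plan.meal(variant_key, meal_type)
        items: dict[str, float] = {}
        for fid, qty in meal.items:
            items[fid] = items.get(fid, 0.0) + qty
        for e in meal_entries:
            if e.kind is LogKind.FOOD_REMOVED and e.food_id is not None:
                items.pop(e.food_id, None)
            elif e.kind is LogKind.SUBSTITUTION:
                items.pop(e.old_food_id, None)
                items[e.new_food_id] = items.get(e.new_food_id, 0.0) + float(e.quantity_g or 0.0)
        factor = 1.0
        for e in meal_entries:
            if e.kind is LogKind.PARTIAL and e.percentage is not None:
                factor = e.percentage / 100.0
        vec = NutrientVector.zero()
        for fid, qty in items.items():
            vec = nv_add(vec, nv_scale(resolve_food(food_table, fid).nutrients_per_100g, qty / 100.0))
        total = nv_add(total, vec.scale(factor))

    for e in entries:
        if e.kind is LogKind.EXTRA_FOOD and e.food_id is not None:
            total = nv_add(
                total,
                nv_scale(resolve_food(food_table, e.food_id).nutrients_per_100g, float(e.quantity_g) / 100.0),
            )
    return total


def daily_stats(
    log: IntakeLog,
    plan: FoodPlan,
    variant_key: str,
    key: str,
    food_table: Mapping[str, FoodItem],
    temperature_c: Optional[float] = None,
) -> DailyStats:
    """Aggregate one day's (or event's) log against the plan targets.

    Water targets pass through the plan's hydration rules when a temperature
    reading is supplied. Logged activity calories sum into ``pee_logged_kcal``
    — the PEE observation usable in a caloric-balance computation.
    """
    consumed = consumed_vector(log, plan, variant_key, key, food_table)
    entries = log.for_key(key)
    water = sum(float(e.volume_ml) for e in entries if e.kind is LogKind.WATER)
    pee = sum(float(e.kcal) for e in entries if e.kind is LogKind.ACTIVITY_CALORIES)
    target = target_vector(plan.targets)
    water_target = plan.targets.water_ml
    if temperature_c is not None:
        water_target = adjust_water_goal(water_target, temperature_c, plan.water_rules)
    fractions: dict[str, Optional[float]] = {}
    for name in consumed.as_dict():
        t = getattr(target, name)
        fractions[name] = (getattr(consumed, name) / t) if t > 0 else None
    return DailyStats(
        key=key,
        consumed=consumed,
        target=target,
        water_consumed_ml=water,
        water_target_ml=water_target,
        pee_logged_kcal=pee,
        fraction_of_target=fractions,
    )
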