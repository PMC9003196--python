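"""Readers and writers for the package's file contracts.

Formats (all UTF-8, comma-separated, ``.`` decimal, header row mandatory):

* food table CSV — ``food_id,name,energy_kcal,protein_g,carbs_g,lipids_g,
  fiber_g,water_ml,iron_mg,calcium_mg,sodium_mg,magnesium_mg``, one food per
  row with nutrients per 100 g;
* plan / appointment / preference-model JSON documents;
* intake log CSV — ``timestamp,key,kind,ref,amount`` where ``ref`` carries
  the kind-specific reference (meal type, food id, ``meal:old>new`` for
  substitutions, ``meal:food`` for removals, source for water/activity) and
  ``amount`` the numeric payload (percentage, grams, mL or kcal);
* device export CSV — ``timestamp,value`` (parsed by
  :func:`nutricontrol.intake.ingest_device_csv`).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .model import (
    Appointment,
    FoodItem,
    FoodPlan,
    IntakeLog,
    LogEntry,
    LogKind,
    NutrientVector,
)
from .preferences import PreferenceModel

__all__ = [
    "FOOD_TABLE_COLUMNS",
    "LOG_COLUMNS",
    "read_food_table",
    "write_food_table",
    "read_plan",
    "write_plan",
    "read_appointment",
    "write_appointment",
    "read_log",
    "write_log",
    "read_preference_model",
    "write_preference_model",
]

FOOD_TABLE_COLUMNS = (
    "food_id",
    "name",
    "energy_kcal",
    "protein_g",
    "carbs_g",
    "lipids_g",
    "fiber_g",
    "water_ml",
    "iron_mg",
    "calcium_mg",
    "sodium_mg",
    "magnesium_mg",
)

#: column suffix → NutrientVector field
_COLUMN_TO_FIELD = {
    "energy_kcal": "energy",
    "protein_g": "protein",
    "carbs_g": "carbs",
    "lipids_g": "lipids",
    "fiber_g": "fiber",
    "water_ml": "water",
    "iron_mg": "iron",
    "calcium_mg": "calcium",
    "sodium_mg": "sodium",
    "magnesium_mg": "magnesium",
}

LOG_COLUMNS = ("timestamp", "key", "kind", "ref", "amount")


def read_food_table(path: str | Path) -> dict[str, FoodItem]:
    """Load a food composition table; keys are food ids, values per-100 g."""
    df = pd.read_csv(path, dtype={"food_id": str, "name": str}, float_precision="round_trip")
    missing = set(FOOD_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"food table missing columns: {sorted(missing)}")
    table: dict[str, FoodItem] = {}
    for row in df.itertuples(index=False):
        food_id = str(row.food_id)
        if food_id in table:
            raise ValidationError(f"duplicate food_id {food_id!r} in food table")
        nutrients = NutrientVector(
            **{field: float(getattr(row, col)) for col, field in _COLUMN_TO_FIELD.items()}
        )
        table[food_id] = FoodItem(food_id=food_id, name=str(row.name), nutrients_per_100g=nutrients)
    return table


def write_food_table(table: Mapping[str, FoodItem], path: str | Path) -> None:
    rows = []
    for food in table.values():
        row: dict[str, object] = {"food_id": food.food_id, "name": food.name}
        for col, field in _COLUMN_TO_FIELD.items():
            row[col] = getattr(food.nutrients_per_100g, field)
        rows.append(row)
    pd.DataFrame(rows, columns=list(FOOD_TABLE_COLUMNS)).to_csv(path, index=False)


def read_plan(path: str | Path) -> FoodPlan:
    with open(path, encoding="utf-8") as fh:
        return FoodPlan.from_dict(json.load(fh))


def write_plan(plan: FoodPlan, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(plan.as_dict(), fh, indent=2)
        fh.write("\n")


def read_appointment(path: str | Path) -> Appointment:
    with open(path, encoding="utf-8") as fh:
        return Appointment.from_dict(json.load(fh))


def write_appointment(appointment: Appointment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(appointment.as_dict(), fh, indent=2)
        fh.write("\n")


def _entry_ref_amount(e: LogEntry) -> tuple[str, str]:
    if e.kind is LogKind.MEAL_CONFIRM:
        return e.meal_type or "", ""
    if e.kind is LogKind.PARTIAL:
        return e.meal_type or "", repr(float(e.percentage))
    if e.kind is LogKind.EXTRA_FOOD:
        return e.food_id or "", repr(float(e.quantity_g))
    if e.kind is LogKind.SUBSTITUTION:
        return f"{e.meal_type}:{e.old_food_id}>{e.new_food_id}", repr(float(e.quantity_g))
    if e.kind is LogKind.FOOD_REMOVED:
        return f"{e.meal_type}:{e.food_id}", ""
    if e.kind is LogKind.WATER:
        return e.source or "manual", repr(float(e.volume_ml))
    if e.kind is LogKind.ACTIVITY_CALORIES:
        return e.source or "watch", repr(float(e.kcal))
    raise ValidationError(f"unknown log kind {e.kind!r}")


def write_log(log: IntakeLog, path: str | Path) -> None:
    rows = []
    for e in log.entries:
        ref, amount = _entry_ref_amount(e)
        rows.append(
            {
                "timestamp": e.timestamp.isoformat(),
                "key": e.key,
                "kind": e.kind.value,
                "ref": ref,
                "amount": amount,
            }
        )
    pd.DataFrame(rows, columns=list(LOG_COLUMNS)).to_csv(path, index=False)


def _entry_from_row(timestamp: str, key: str, kind: str, ref: str, amount: str) -> LogEntry:
    ts = datetime.datetime.fromisoformat(timestamp)
    k = LogKind(kind)
    value = float(amount) if amount not in ("", None) else None
    if k is LogKind.MEAL_CONFIRM:
        return LogEntry(timestamp=ts, key=key, kind=k, meal_type=ref)
    if k is LogKind.PARTIAL:
        return LogEntry(timestamp=ts, key=key, kind=k, meal_type=ref, percentage=value)
    if k is LogKind.EXTRA_FOOD:
        return LogEntry(timestamp=ts, key=key, kind=k, food_id=ref, quantity_g=value)
    if k is LogKind.SUBSTITUTION:
        try:
            meal_type, swap = ref.split(":", 1)
            old_id, new_id = swap.split(">", 1)
        except ValueError:
            raise ValidationError(f"bad substitution ref {ref!r}; expected 'meal:old>new'") from None
        return LogEntry(
            timestamp=ts, key=key, kind=k, meal_type=meal_type,
            old_food_id=old_id, new_food_id=new_id, quantity_g=value,
        )
    if k is LogKind.FOOD_REMOVED:
        try:
            meal_type, food_id = ref.split(":", 1)
        except ValueError:
            raise ValidationError(f"bad removal ref {ref!r}; expected 'meal:food'") from None
        return LogEntry(timestamp=ts, key=key, kind=k, meal_type=meal_type, food_id=food_id)
    if k is LogKind.WATER:
        return LogEntry(timestamp=ts, key=key, kind=k, volume_ml=value, source=ref or "manual")
    if k is LogKind.ACTIVITY_CALORIES:
        return LogEntry(timestamp=ts, key=key, kind=k, kcal=value, source=ref or "watch")
    raise ValidationError(f"unknown log kind {kind!r}")


def read_log(path: str | Path) -> IntakeLog:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"log file missing columns: {sorted(missing)}")
    log = IntakeLog()
    for row in df.itertuples(index=False):
        log.add(_entry_from_row(row.timestamp, row.key, row.kind, row.ref, row.amount))
    return log


def read_preference_model(path: str | Path) -> PreferenceModel:
    with open(path, encoding="utf-8") as fh:
        return PreferenceModel.from_dict(json.load(fh))


def write_preference_model(model: PreferenceModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.as_dict(), fh, indent=2)
        fh.write("\n")
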