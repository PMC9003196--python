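"""Food-preference learning from intake logs.

The system suggests substitutes that are both nutritionally equivalent and
liked. Liking is estimated per (food, context) — context being the meal type
and day of week — by an exponentially decayed acceptance frequency: each
acceptance event (a confirmed meal containing the food, or the food logged
as an extra) pulls the score toward 1, each rejection (the food substituted
away) pulls it toward 0, with per-event decay ``d``:

    score ← score · d + (1 − d) · outcome

Scores therefore stay in [0, 1] under any event sequence and recent events
dominate. Unseen (food, context) pairs sit at a neutral prior. The update is
deliberately a transparent deterministic baseline — it is swappable behind
:func:`recommend`, which ranks the nutritionally equivalent candidates by
preference score first and macro error second.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

from .errors import DomainError
from .model import FoodItem, FoodPlan, IntakeLog, LogKind
from .plan import SubstitutionCandidate, equivalent_foods, variant_for_key

__all__ = ["Context", "PreferenceModel", "update_preferences", "recommend"]

#: (meal_type or None, day-of-week 0=Monday..6 or None)
Context = tuple[Optional[str], Optional[int]]


def _context_of(meal_type: Optional[str], key: str, timestamp: datetime.datetime) -> Context:
    try:
        dow = datetime.date.fromisoformat(key).weekday()
    except ValueError:
        dow = timestamp.weekday()
    return (meal_type, dow)


@dataclass
class PreferenceModel:
    """Decayed acceptance-frequency scores per (food_id, context)."""

    decay: float = 0.8
    prior: float = 0.5
    scores: dict[tuple[str, Context], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.decay <= 1.0):
            raise DomainError("decay must lie in (0, 1]")
        if not (0.0 <= self.prior <= 1.0):
            raise DomainError("prior must lie in [0, 1]")

    def score(self, food_id: str, context: Context) -> float:
        return self.scores.get((food_id, context), self.prior)

    def _update(self, food_id: str, context: Context, outcome: float) -> None:
        current = self.score(food_id, context)
        self.scores[(food_id, context)] = current * self.decay + (1.0 - self.decay) * outcome

    def as_dict(self) -> dict[str, Any]:
        return {
            "decay": self.decay,
            "prior": self.prior,
            "scores": [
                {"food_id": f, "meal_type": c[0], "day_of_week": c[1], "score": s}
                for (f, c), s in sorted(self.scores.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PreferenceModel":
        model = cls(decay=float(data.get("decay", 0.8)), prior=float(data.get("prior", 0.5)))
        for row in data.get("scores", []):
            ctx: Context = (row.get("meal_type"), row.get("day_of_week"))
            model.scores[(row["food_id"], ctx)] = float(row["score"])
        return model


def update_preferences(
    model: PreferenceModel,
    log: IntakeLog,
    plan: Optional[FoodPlan] = None,
) -> PreferenceModel:
    """Fold an ordered log into the model (mutates and returns it).

    Confirmed meals score every planned food of that meal as accepted (the
    plan is needed to resolve meal contents); extra foods score themselves
    as accepted; substitutions score the replaced food as rejected and the
    replacement as accepted. Other entry kinds carry no preference signal.
    """
    for e in sorted(log.entries, key=lambda e: e.timestamp):
        ctx = _context_of(e.meal_type, e.key, e.timestamp)
        if e.kind is LogKind.MEAL_CONFIRM and plan is not None and e.meal_type:
            meal = plan.meal(variant_for_key(plan, e.key), e.meal_type)
            for food_id, _qty in meal.items:
                model._update(food_id, ctx, 1.0)
        elif e.kind is LogKind.EXTRA_FOOD and e.food_id:
            model._update(e.food_id, _context_of(None, e.key, e.timestamp), 1.0)
        elif e.kind is LogKind.SUBSTITUTION:
            if e.old_food_id:
                model._update(e.old_food_id, ctx, 0.0)
            if e.new_food_id:
                model._update(e.new_food_id, ctx, 1.0)
    return model


def recommend(
    model: PreferenceModel,
    target_food: FoodItem,
    quantity_g: float,
    food_table: Mapping[str, FoodItem],
    tolerance: float = 0.15,
    context: Context = (None, None),
) -> list[tuple[SubstitutionCandidate, float]]:
    """Rank nutritionally equivalent substitutes by learned preference.

    Candidates come from :func:`nutricontrol.plan.equivalent_foods`; within
    that set preference score (descending) dominates, macro error
    (ascending) breaks score ties, food_id breaks the rest. Returns
    (candidate, score) pairs.
    """
    candidates = equivalent_foods(target_food, quantity_g, food_table, tolerance)
    scored = [(c, model.score(c.food.food_id, context)) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0].macro_error, cs[0].food.food_id))
    return scored
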