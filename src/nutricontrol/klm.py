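"""Keystroke-level-model (KLM) estimation of user interaction cost.

The KLM predicts how long an expert takes to perform a UI task by summing
standard operator times: K (keystroke, 0.12 s), P (point, 1.1 s), H (homing
the hands on a device, 0.4 s), B (button press, 0.1 s), M (mental
preparation, 1.35 s), plus D (draw) and R (system response), both measured
in real time and defaulting to 0 here. A unit task splits into acquisition
and execution, T_task = T_acquire + T_execute, with T_execute the sum over
the task's operator string.

Operator strings support a numeric repeat prefix applying to the next single
operator — ``"42K"`` means forty-two keystrokes — which is how text entry
such as typing an API token is written compactly.

:data:`REFERENCE_TASKS` holds the interaction tasks of the nutrition app's
user interface with their previously estimated times;
:func:`interaction_report` recomputes every row from its operator sequence
and flags any row whose recomputation disagrees with the recorded estimate.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

from ._utils import round_half_up
from .errors import DomainError, KlmParseError

__all__ = [
    "OPERATORS",
    "KlmOperatorTimes",
    "KlmTask",
    "ReferenceTask",
    "ReportRow",
    "REFERENCE_TASKS",
    "parse_klm",
    "render_klm",
    "execute_time",
    "task_time",
    "interaction_report",
]

#: The seven KLM operators.
OPERATORS: tuple[str, ...] = ("K", "P", "H", "D", "B", "M", "R")


@dataclass(frozen=True)
class KlmOperatorTimes:
    """Per-operator durations in seconds.

    K/P/H/B/M carry the standard KLM estimates; R (system response) and D
    (draw) are measured in real time on the deployed system and default to 0.
    """

    K: float = 0.12
    P: float = 1.1
    H: float = 0.4
    B: float = 0.1
    M: float = 1.35
    R: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        for op in OPERATORS:
            if getattr(self, op) < 0:
                raise DomainError(f"operator time {op} must be >= 0")

    def time_of(self, op: str) -> float:
        return getattr(self, op)


class ExecuteTime(NamedTuple):
    seconds: float  # rounded half-up to 2 decimals, the reporting convention
    exact: float


_TOKEN = re.compile(r"(\d+)?([A-Za-z])")


def parse_klm(operator_string: str) -> Counter:
    """Parse an operator string into per-operator counts.

    Grammar: ``(digits? operator)*`` over the alphabet KPHDBM R; a digit
    prefix repeats the single operator that follows (``"3K" == "KKK"``).
    Illegal characters or dangling digits raise :class:`KlmParseError` with
    the offending position.
    """
    counts: Counter = Counter()
    pos = 0
    s = operator_string.strip()
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise KlmParseError(f"illegal character {s[pos]!r}", pos)
        repeat, op = m.group(1), m.group(2).upper()
        if op not in OPERATORS:
            raise KlmParseError(f"unknown operator {m.group(2)!r}", m.start(2))
        counts[op] += int(repeat) if repeat else 1
        pos = m.end()
    return counts


def render_klm(counts: Mapping[str, int]) -> str:
    """Canonical string for a count multiset (K,P,H,D,B,M,R order, repeat
    prefixes for counts above 1); ``parse_klm`` round-trips it exactly."""
    parts = []
    for op in OPERATORS:
        n = int(counts.get(op, 0))
        if n < 0:
            raise DomainError(f"negative count for operator {op}")
        if n == 1:
            parts.append(op)
        elif n > 1:
            parts.append(f"{n}{op}")
    return "".join(parts)


def execute_time(counts: Mapping[str, int], times: KlmOperatorTimes = KlmOperatorTimes()) -> ExecuteTime:
    """T_execute = Σ count(op) × time(op); returns (2-decimal report, exact)."""
    exact = sum(int(counts.get(op, 0)) * times.time_of(op) for op in OPERATORS)
    return ExecuteTime(seconds=round_half_up(exact, 2), exact=exact)


@dataclass(frozen=True)
class KlmTask:
    """A named UI task: operator string plus acquisition time."""

    name: str
    operator_string: str
    t_acquire: float = 0.0

    def __post_init__(self) -> None:
        if self.t_acquire < 0:
            raise DomainError("t_acquire must be >= 0")
        parse_klm(self.operator_string)  # fail fast on bad strings


def task_time(task: KlmTask, times: KlmOperatorTimes = KlmOperatorTimes()) -> float:
    """T_task = T_acquire + T_execute, reported at 2 decimals (half-up)."""
    exact = task.t_acquire + execute_time(parse_klm(task.operator_string), times).exact
    return round_half_up(exact, 2)


@dataclass(frozen=True)
class ReferenceTask:
    """One row of the app's interaction study: actor, task, optional
    sub-task, operator sequence ("" where no manual interaction exists) and
    the previously estimated time in seconds."""

    actor: str
    task: str
    sub_task: str
    sequence: str
    estimated_s: float


#: Interaction tasks of the user application with their recorded estimates.
#: Sub-tasks marked * repeat for each item in the meal.
REFERENCE_TASKS: tuple[ReferenceTask, ...] = (
    ReferenceTask("User", "Visualize food plan", "Graphical representation of the meal", "PB", 1.20),
    ReferenceTask("User", "Visualize food plan", "Composition of the meal (by food)", "PBP", 2.30),
    ReferenceTask("User", "Log food intake", "Add new food to the meal *", "PBPBMHKKKMHPBPB", 8.66),
    ReferenceTask("User", "Log food intake", "Add new extra food (snack between meals) *", "PBPBMHKKKMHPBPB", 8.66),
    ReferenceTask("User", "Log food intake", "Remove food *", "PBPBPB", 3.60),
    ReferenceTask("User", "Log food intake", "Specify percentage of food intake *", "PBPBPBPB", 4.80),
    ReferenceTask("User", "Log food intake", "Change food plan food *", "PBPBPB", 3.60),
    ReferenceTask("User", "Log food intake", "Confirm food intake from food plan with no changes *", "PB", 1.20),
    ReferenceTask("User", "Log water intake", "Through food plan", "PBPBPB", 3.60),
    ReferenceTask("User", "Log water intake", "Through interaction menu", "PBPBPBPB", 4.80),
    ReferenceTask("Fitbit (bottle)", "Update water intake", "", "", 0.00),
    ReferenceTask("User", "Visualize statistics", "", "PBPB", 1.20),
    ReferenceTask("System", "Update food entries for train and competition", "", "", 0.00),
    ReferenceTask("User", "Change active food plan (train or competition)", "", "PBPBPBPB", 4.80),
    ReferenceTask("User", "Connect watch API", "", "PBPBPBMH42KMHPB", 13.34),
    ReferenceTask("User", "Provide consent to access Fitbit API", "", "PBPBPBR", 4.60),
)


@dataclass(frozen=True)
class ReportRow:
    """A reconciliation row: recomputed vs recorded time."""

    actor: str
    task: str
    sub_task: str
    sequence: str
    computed_s: float
    estimated_s: float
    flagged: bool


def interaction_report(
    tasks: Iterable[ReferenceTask] = REFERENCE_TASKS,
    times: KlmOperatorTimes = KlmOperatorTimes(),
    flag_tolerance_s: float = 0.005,
) -> list[ReportRow]:
    """Recompute every task's execution time from its operator sequence
    (T_acquire = 0) and flag rows where it differs from the recorded
    estimate by more than ``flag_tolerance_s``."""
    rows = []
    for t in tasks:
        computed = execute_time(parse_klm(t.sequence), times).seconds
        rows.append(
            ReportRow(
                actor=t.actor,
                task=t.task,
                sub_task=t.sub_task,
                sequence=t.sequence,
                computed_s=computed,
                estimated_s=t.estimated_s,
                flagged=abs(computed - t.estimated_s) > flag_tolerance_s,
            )
        )
    return rows
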