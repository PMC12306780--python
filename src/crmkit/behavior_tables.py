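"""Cycle-level fertility behavior and intention-by-behavior cross-tabs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chart_core import (
    CoupleCycle,
    DayFertilityStatus,
    FertilityStatus,
    NoChartError,
)
from .intentions import IntentionLevel, SOCResponse

__all__ = [
    "CycleBehavior",
    "TABLE_ROW_ORDER",
    "cycle_has_fertile_intercourse",
    "compute_cycle_behavior",
    "intention_behavior_table",
    "flag_barrier_withdrawal",
]

# most- to least-achieving, the published reporting order
TABLE_ROW_ORDER = (
    IntentionLevel.TRYING_HARD_CONCEIVE,
    IntentionLevel.CONCEIVE,
    IntentionLevel.NEUTRAL,
    IntentionLevel.AVOID,
    IntentionLevel.TRYING_HARD_AVOID,
    IntentionLevel.ABSTAIN,
)

ROW_LABELS = {
    IntentionLevel.TRYING_HARD_CONCEIVE: "Trying hard to conceive",
    IntentionLevel.CONCEIVE: "Conceive",
    IntentionLevel.NEUTRAL: "Unsure",
    IntentionLevel.AVOID: "Avoid pregnancy",
    IntentionLevel.TRYING_HARD_AVOID: "Trying hard to avoid pregnancy",
    IntentionLevel.ABSTAIN: "Abstain",
}


@dataclass(frozen=True)
class CycleBehavior:
    couple_id: str
    cycle_index: int
    any_intercourse: bool
    intercourse_on_fertile: bool
    intercourse_on_fertile_or_unknown: bool
    barrier_or_withdrawal: bool = False

    def __post_init__(self) -> None:
        if self.intercourse_on_fertile and not self.intercourse_on_fertile_or_unknown:
            raise ValueError("fertile intercourse implies fertile-or-unknown")
        if self.intercourse_on_fertile_or_unknown and not self.any_intercourse:
            raise ValueError("fertile-or-unknown intercourse implies any intercourse")


def cycle_has_fertile_intercourse(
    cycle: CoupleCycle,
    statuses: Sequence[DayFertilityStatus],
    include_unknown: bool = False,
) -> bool:
    """True iff any intercourse day is FERTILE (or UNKNOWN when included)."""
    if not cycle.has_chart:
        raise NoChartError(f"cycle {cycle.couple_id}/{cycle.cycle_index} has no chart")
    accept = {FertilityStatus.FERTILE}
    if include_unknown:
        accept.add(FertilityStatus.UNKNOWN)
    return any(
        day.intercourse and status.status in accept
        for day, status in zip(cycle.days, statuses)
    )


def compute_cycle_behavior(
    cycle: CoupleCycle,
    statuses: Sequence[DayFertilityStatus],
    barrier_or_withdrawal: bool = False,
) -> CycleBehavior:
    return CycleBehavior(
        couple_id=cycle.couple_id,
        cycle_index=cycle.cycle_index,
        any_intercourse=any(d.intercourse for d in cycle.days),
        intercourse_on_fertile=cycle_has_fertile_intercourse(cycle, statuses, False),
        intercourse_on_fertile_or_unknown=cycle_has_fertile_intercourse(
            cycle, statuses, True
        ),
        barrier_or_withdrawal=barrier_or_withdrawal,
    )


def intention_behavior_table(
    intentions: Mapping[tuple[str, int], Optional[IntentionLevel]],
    behaviors: Iterable[CycleBehavior],
) -> tuple[pd.DataFrame, int]:
    """Per-intention counts of cycles with fertile-day intercourse.

    ``intentions`` maps (couple_id, cycle_index) to the reconciled couple
    intention (None = missing). Returns the table (one row per intention
    level, most achieving first, plus a Total row) and the number of cycles
    excluded for missing intention or missing chart-derived behavior.

    Columns: n_fertile (intercourse on a known fertile day),
    n_fertile_or_unknown (adding days of undetermined fertility), total.
    """
    rows = {level: [0, 0, 0] for level in TABLE_ROW_ORDER}
    included_keys = set()
    for b in behaviors:
        key = (b.couple_id, b.cycle_index)
        level = intentions.get(key)
        if level is None:
            continue
        included_keys.add(key)
        rows[level][0] += int(b.intercourse_on_fertile)
        rows[level][1] += int(b.intercourse_on_fertile_or_unknown)
        rows[level][2] += 1
    all_keys = set(intentions) | {
        (b.couple_id, b.cycle_index) for b in behaviors
    }
    excluded = len(all_keys - included_keys)
    table = pd.DataFrame(
        [rows[level] for level in TABLE_ROW_ORDER],
        index=[ROW_LABELS[level] for level in TABLE_ROW_ORDER],
        columns=["n_fertile", "n_fertile_or_unknown", "total"],
    )
    table.loc["Total"] = table.sum(axis=0)
    return table, excluded


def flag_barrier_withdrawal(
    cycle_key: tuple[str, int],
    soc_responses: Iterable[SOCResponse],
    chart_flags: Optional[Mapping[tuple[str, int], bool]] = None,
) -> bool:
    """Whether any source indicates condom or withdrawal use in the cycle.

    The SOC question asks about the cycle immediately prior to the
    questionnaire, so a response at cycle k+1 flags cycle k. Chart
    annotations (when present) are unioned in.
    """
    couple_id, cycle_index = cycle_key
    if chart_flags and chart_flags.get(cycle_key, False):
        return True
    for r in soc_responses:
        if (
            r.couple_id == couple_id
            and r.cycle_index == cycle_index + 1
            and ({"condom", "withdrawal"} & set(r.prior_cycle_methods))
        ):
            return True
    return False


def barrier_withdrawal_flags(
    soc_responses: Iterable[SOCResponse],
    chart_flags: Optional[Mapping[tuple[str, int], bool]] = None,
    cycle_keys: Optional[Iterable[tuple[str, int]]] = None,
) -> dict[tuple[str, int], bool]:
    """Vectorized form of :func:`flag_barrier_withdrawal` over a cohort."""
    flagged: set[tuple[str, int]] = set()
    for r in soc_responses:
        if {"condom", "withdrawal"} & set(r.prior_cycle_methods):
            flagged.add((r.couple_id, r.cycle_index - 1))
    if chart_flags:
        flagged.update(k for k, v in chart_flags.items() if v)
    if cycle_keys is None:
        return {k: True for k in flagged}
    return {k: k in flagged for k in cycle_keys}
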