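"""Correct-use cycle classification: eligibility cascade and category rules.

Three nested evidence levels (L1 ⊇ L2 ⊇ L3) progressively restrict which
cycles count as correct use, and five behavior categories — two for use to
conceive, three for use to avoid — are assigned from day statuses and
intercourse placement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .chart_core import (
    CoupleCycle,
    DayFertilityStatus,
    FertilityStatus,
    NoChartError,
)

__all__ = [
    "ExitAnswer",
    "RecordingFidelity",
    "TeacherAssessment",
    "Level",
    "Category",
    "CorrectUseLabel",
    "IncompleteChartError",
    "couple_eligible",
    "classify_cycle_correct_use",
    "correct_use_table",
    "assign_assessments",
]


class ExitAnswer(str, enum.Enum):
    ALL_WITHOUT_EXCEPTION = "ALL_WITHOUT_EXCEPTION"
    NEARLY_ALL_RARE_EXCEPTION = "NEARLY_ALL_RARE_EXCEPTION"
    NOT_ALL = "NOT_ALL"
    MISSING = "MISSING"


_ELIGIBLE_ANSWERS = {ExitAnswer.ALL_WITHOUT_EXCEPTION, ExitAnswer.NEARLY_ALL_RARE_EXCEPTION}


@dataclass(frozen=True)
class RecordingFidelity:
    couple_id: str
    partner: str  # "F" or "M"
    exit_answer: ExitAnswer


@dataclass(frozen=True)
class TeacherAssessment:
    couple_id: str
    cycle_index: int
    consistent_observations: bool
    peak_id_ok: bool
    accurate_charting: bool

    @property
    def satisfactory(self) -> bool:
        return self.consistent_observations and self.peak_id_ok and self.accurate_charting


class Level(str, enum.Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"


class Category(str, enum.Enum):
    CONCEIVE_ANY_FERTILE = "CONCEIVE_ANY_FERTILE"
    CONCEIVE_PEAK_TYPE = "CONCEIVE_PEAK_TYPE"
    AVOID_STRICT = "AVOID_STRICT"
    AVOID_POSTPEAK_ONLY = "AVOID_POSTPEAK_ONLY"
    AVOID_LAST_DRY_PREPEAK = "AVOID_LAST_DRY_PREPEAK"


@dataclass(frozen=True, order=True)
class CorrectUseLabel:
    level: Level
    category: Category


class IncompleteChartError(ValueError):
    """Cycle lacks daily observations for the entire cycle."""


def couple_eligible(fidelity: Iterable[RecordingFidelity]) -> bool:
    """True iff at least one partner reported recording (nearly) all acts."""
    return any(f.exit_answer in _ELIGIBLE_ANSWERS for f in fidelity)


def _fertile_window_start(statuses: Sequence[DayFertilityStatus], peak: int) -> Optional[int]:
    """First day (1-based) of the contiguous fertile run containing the peak."""
    start = None
    for i in range(peak - 1, -1, -1):
        if statuses[i].status is FertilityStatus.FERTILE:
            start = i + 1
        else:
            break
    return start


def classify_cycle_correct_use(
    cycle: CoupleCycle,
    statuses: Sequence[DayFertilityStatus],
    assessment: Optional[TeacherAssessment] = None,
    barrier_or_withdrawal: bool = False,
    strict_end_of_day: bool = True,
) -> set[CorrectUseLabel]:
    """Assign correct-use labels at every evidence level the cycle attains.

    Preconditions (enforced): a fully charted cycle (no day unknown for
    missing observations) with at least one recorded act of intercourse.
    L1 = those preconditions; L2 adds a fully satisfactory teacher
    assessment; L3 additionally excludes barrier/withdrawal cycles and
    nonstandard chart formats.

    With ``strict_end_of_day`` (default), intercourse without a recorded
    end-of-day time on an end-of-day-only non-fertile day is treated as
    potentially fertile, disqualifying the avoid categories.
    """
    if not cycle.has_chart:
        raise NoChartError(f"cycle {cycle.couple_id}/{cycle.cycle_index} has no chart")
    if any(s.status is FertilityStatus.UNKNOWN and not d.observed
           for d, s in zip(cycle.days, statuses)):
        raise IncompleteChartError(
            f"cycle {cycle.couple_id}/{cycle.cycle_index}: incomplete chart"
        )
    if not any(d.intercourse for d in cycle.days):
        raise IncompleteChartError(
            f"cycle {cycle.couple_id}/{cycle.cycle_index}: no recorded intercourse"
        )

    acts = [(d, s) for d, s in zip(cycle.days, statuses) if d.intercourse]
    any_fertile = any(s.status is FertilityStatus.FERTILE for _, s in acts)
    any_unknown = any(s.status is FertilityStatus.UNKNOWN for _, s in acts)
    any_peak_type = any(d.discharge == "peak-type-mucus" for d, _ in acts)
    timing_ambiguous = any(
        s.end_of_day_only and d.intercourse_end_of_day is not True for d, s in acts
    )

    categories: set[Category] = set()
    if any_fertile:
        categories.add(Category.CONCEIVE_ANY_FERTILE)
        if any_peak_type:
            categories.add(Category.CONCEIVE_PEAK_TYPE)
    else:
        avoid_ok = not any_unknown and not (strict_end_of_day and timing_ambiguous)
        if avoid_ok:
            categories.add(Category.AVOID_STRICT)
            peak = cycle.peak_day
            if peak is not None:
                if all(d.day_of_cycle >= peak + 4 for d, _ in acts):
                    categories.add(Category.AVOID_POSTPEAK_ONLY)
                window_start = _fertile_window_start(statuses, peak)
                if window_start is not None and window_start > 1:
                    last_dry = window_start - 1
                    if any(d.day_of_cycle == last_dry for d, _ in acts):
                        categories.add(Category.AVOID_LAST_DRY_PREPEAK)

    levels = [Level.L1]
    if assessment is not None and assessment.satisfactory:
        levels.append(Level.L2)
        if not barrier_or_withdrawal and not cycle.nonstandard_chart:
            levels.append(Level.L3)
    return {CorrectUseLabel(lv, cat) for lv in levels for cat in categories}


@dataclass(frozen=True)
class CorrectUseCycle:
    """One labeled cycle feeding the correct-use summary/life tables."""

    couple_id: str
    cycle_index: int
    ordinal: int
    labels: frozenset[CorrectUseLabel]
    pregnancy: bool


def correct_use_table(cycles: Iterable[CorrectUseCycle]) -> pd.DataFrame:
    """Couples / cycles / pregnancies per (category, level) cell.

    Row order mirrors the published correct-use summary: the two conceive
    categories, then the three avoid categories, each at L1, L2, L3.
    """
    cycles = list(cycles)
    records = []
    for cat in Category:
        for lvl in Level:
            label = CorrectUseLabel(lvl, cat)
            sub = [c for c in cycles if label in c.labels]
            records.append(
                {
                    "category": cat.value,
                    "level": lvl.value,
                    "couples": len({c.couple_id for c in sub}),
                    "cycles": len(sub),
                    "pregnancies": sum(c.pregnancy for c in sub),
                }
            )
    return pd.DataFrame.from_records(records)


def assign_assessments(
    assessments: Iterable[TeacherAssessment],
    visit_dates: Mapping[tuple[str, int], int],
    cycle_end_dates: Mapping[tuple[str, int], int],
) -> dict[tuple[str, int], TeacherAssessment]:
    """Map each cycle to the follow-up assessment nearest its end date.

    ``visit_dates`` keys are (couple_id, cycle_index as recorded on the
    assessment); ``cycle_end_dates`` keys are (couple_id, cycle_index) for
    every analytic cycle. Ties in date distance break toward the earlier
    visit.
    """
    by_couple: dict[str, list[tuple[int, TeacherAssessment]]] = {}
    for a in assessments:
        date = visit_dates.get((a.couple_id, a.cycle_index))
        if date is None:
            continue
        by_couple.setdefault(a.couple_id, []).append((date, a))
    for visits in by_couple.values():
        visits.sort(key=lambda t: t[0])
    out: dict[tuple[str, int], TeacherAssessment] = {}
    for key, end_date in cycle_end_dates.items():
        couple_id, _ = key
        visits = by_couple.get(couple_id)
        if not visits:
            continue
        best = min(visits, key=lambda t: (abs(t[0] - end_date), t[0]))
        out[key] = best[1]
    return out
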