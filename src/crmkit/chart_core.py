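"""Daily fertility-chart data model and day-level classification.

Implements the chart record types, the configurable rule table that maps
each charted day to FERTILE / NON_FERTILE / UNKNOWN, peak-day
identification, cycle-length imputation for uncharted cycles, and the
post-peak pregnancy-surveillance flag.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import yaml

__all__ = [
    "BLEEDING_CODES",
    "DISCHARGE_CODES",
    "FREQUENCY_CODES",
    "FertilityStatus",
    "DayRecord",
    "DayFertilityStatus",
    "CoupleCycle",
    "CycleSource",
    "PeakInfo",
    "RuleTable",
    "ChartError",
    "NoChartError",
    "InvalidObservationCode",
    "UnobservedDischargeError",
    "PeakUnknownError",
    "classify_days",
    "identify_peak",
    "identify_peak_day",
    "is_peak_type_mucus",
    "impute_cycle_length",
    "flag_possible_pregnancy",
    "read_chart_file",
    "write_chart_file",
    "cycles_from_day_records",
]

BLEEDING_CODES = frozenset({"H", "M", "L", "VL", "B", "none"})
DISCHARGE_CODES = frozenset({"dry", "non-peak-mucus", "peak-type-mucus", "unobserved"})
FREQUENCY_CODES = frozenset({"x1", "x2", "x3", "AD", "none"})

MISSING_TOKEN = "."


class ChartError(ValueError):
    """Base class for chart-data errors."""


class NoChartError(ChartError):
    """Raised when an operation needing daily chart data gets none."""


class InvalidObservationCode(ChartError):
    """Raised for a bleeding/discharge/frequency code outside the vocabulary."""


class UnobservedDischargeError(ChartError):
    """Raised when a discharge-dependent query hits an unobserved day."""


class PeakUnknownError(ChartError):
    """Raised when pregnancy surveillance has neither peak nor menses timing."""


class FertilityStatus(str, Enum):
    FERTILE = "FERTILE"
    NON_FERTILE = "NON_FERTILE"
    UNKNOWN = "UNKNOWN"


class CycleSource(str, Enum):
    CHART_AND_SOC = "CHART_AND_SOC"
    CHART_ONLY = "CHART_ONLY"
    SOC_ONLY = "SOC_ONLY"
    IMPUTED = "IMPUTED"

    @property
    def has_chart(self) -> bool:
        return self in (CycleSource.CHART_AND_SOC, CycleSource.CHART_ONLY)


@dataclass(frozen=True)
class DayRecord:
    """One charted couple-day.

    ``intercourse_end_of_day`` is ``None`` when the chart did not record
    whether intercourse happened at the end of the day; it may only be set
    when ``intercourse`` is true.
    """

    couple_id: str
    cycle_index: int
    day_of_cycle: int
    bleeding: str = "none"
    discharge: str = "unobserved"
    observation_frequency: str = "none"
    intercourse: bool = False
    intercourse_end_of_day: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.day_of_cycle < 1:
            raise ChartError(f"day_of_cycle must be >= 1, got {self.day_of_cycle}")
        if self.bleeding not in BLEEDING_CODES:
            raise InvalidObservationCode(f"invalid bleeding code: {self.bleeding!r}")
        if self.discharge not in DISCHARGE_CODES:
            raise InvalidObservationCode(f"invalid discharge code: {self.discharge!r}")
        if self.observation_frequency not in FREQUENCY_CODES:
            raise InvalidObservationCode(
                f"invalid observation frequency code: {self.observation_frequency!r}"
            )
        if self.intercourse_end_of_day is not None and not self.intercourse:
            raise ChartError("intercourse_end_of_day set without intercourse")

    @property
    def observed(self) -> bool:
        """True when the day carries any fertility-relevant observation."""
        return self.discharge != "unobserved" or self.bleeding != "none"


@dataclass(frozen=True)
class DayFertilityStatus:
    """Classified status of one charted day.

    ``end_of_day_only`` marks NON_FERTILE days on which the method restricts
    intercourse to the end of the day (pre-peak dry days and Peak+4), so that
    acts without a recorded time of day can be treated as timing-ambiguous.
    """

    status: FertilityStatus
    end_of_day_only: bool = False

    def __post_init__(self) -> None:
        if self.end_of_day_only and self.status is not FertilityStatus.NON_FERTILE:
            raise ChartError("end_of_day_only applies to NON_FERTILE days only")


@dataclass
class CoupleCycle:
    """One menstrual cycle for one couple."""

    couple_id: str
    cycle_index: int
    length_days: int
    days: tuple[DayRecord, ...] = ()
    start_date: Optional[int] = None  # study day of cycle start
    peak_day: Optional[int] = None
    source: CycleSource = CycleSource.CHART_ONLY
    pregnancy_in_cycle: bool = False
    nonstandard_chart: bool = False

    def __post_init__(self) -> None:
        self.days = tuple(sorted(self.days, key=lambda d: d.day_of_cycle))
        if self.length_days < 1:
            raise ChartError("length_days must be positive")
        if self.source.has_chart and len(self.days) != self.length_days:
            raise ChartError(
                f"cycle {self.couple_id}/{self.cycle_index}: length_days="
                f"{self.length_days} but {len(self.days)} day records"
            )
        if self.source is CycleSource.IMPUTED and self.days:
            raise ChartError("imputed cycles must have no day records")
        if self.peak_day is not None and not 1 <= self.peak_day <= self.length_days:
            raise ChartError("peak_day outside cycle")

    @property
    def has_chart(self) -> bool:
        return self.source.has_chart


@dataclass(frozen=True)
class PeakInfo:
    day: Optional[int]
    possible_double_peak: bool = False


@dataclass(frozen=True)
class RuleTable:
    """Day-classification rule set (data, not code).

    Defaults reconstruct published method instructions: bleeding days are
    fertile; any mucus day is fertile; dry days within ``count_of_three``
    days of a pre-peak mucus patch are fertile; Peak+1..Peak+3 are fertile;
    Peak+4 is non-fertile end-of-day only; Peak+5 onward non-fertile; dry
    pre-peak days are non-fertile end-of-day only; days without the required
    observations are of unknown fertility.
    """

    version: str = "1.0"
    menses_bleeding_fertile: tuple[str, ...] = ("H", "M", "L", "VL", "B")
    count_of_three: int = 3
    post_peak_fertile_days: int = 3  # Peak+1..Peak+3
    end_of_day_only_post_peak_day: int = 4  # Peak+4
    prepeak_dry_end_of_day_only: bool = True

    @classmethod
    def default(cls) -> "RuleTable":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "menses_bleeding_fertile" in raw:
            raw["menses_bleeding_fertile"] = tuple(raw["menses_bleeding_fertile"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "version": self.version,
            "menses_bleeding_fertile": list(self.menses_bleeding_fertile),
            "count_of_three": self.count_of_three,
            "post_peak_fertile_days": self.post_peak_fertile_days,
            "end_of_day_only_post_peak_day": self.end_of_day_only_post_peak_day,
            "prepeak_dry_end_of_day_only": self.prepeak_dry_end_of_day_only,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def is_peak_type_mucus(day: DayRecord) -> bool:
    """True iff the day's discharge observation is peak-type mucus."""
    if day.discharge == "unobserved":
        raise UnobservedDischargeError(
            f"day {day.day_of_cycle}: discharge unobserved"
        )
    return day.discharge == "peak-type-mucus"


def identify_peak(cycle: CoupleCycle) -> PeakInfo:
    """Locate the peak day: the last peak-type mucus day of the cycle.

    Emits ``possible_double_peak`` when peak-type mucus occurs in two or
    more runs separated by at least one non-peak-type day, which a user may
    misread as a completed peak (stress-cycle pattern).
    """
    if not cycle.has_chart:
        raise NoChartError(f"cycle {cycle.couple_id}/{cycle.cycle_index} has no chart")
    peak_days = [d.day_of_cycle for d in cycle.days if d.discharge == "peak-type-mucus"]
    if not peak_days:
        return PeakInfo(day=None)
    runs = 1
    for prev, cur in zip(peak_days, peak_days[1:]):
        if cur - prev > 1:
            runs += 1
    return PeakInfo(day=peak_days[-1], possible_double_peak=runs > 1)


def identify_peak_day(cycle: CoupleCycle) -> Optional[int]:
    return identify_peak(cycle).day


def classify_days(
    cycle: CoupleCycle, rules: Optional[RuleTable] = None
) -> tuple[DayFertilityStatus, ...]:
    """Classify every day of a charted cycle as fertile / non-fertile / unknown.

    Pure function of (cycle, rules); one status per day, in day order.
    """
    if rules is None:
        rules = RuleTable.default()
    if not cycle.has_chart:
        raise NoChartError(f"cycle {cycle.couple_id}/{cycle.cycle_index} has no chart")

    peak = cycle.peak_day if cycle.peak_day is not None else identify_peak(cycle).day
    days = cycle.days
    statuses: list[DayFertilityStatus] = []
    for i, day in enumerate(days):
        statuses.append(_classify_one(day, i, days, peak, rules))
    return tuple(statuses)


def _classify_one(
    day: DayRecord,
    idx: int,
    days: Sequence[DayRecord],
    peak: Optional[int],
    rules: RuleTable,
) -> DayFertilityStatus:
    if not day.observed:
        return DayFertilityStatus(FertilityStatus.UNKNOWN)
    if day.bleeding in rules.menses_bleeding_fertile:
        return DayFertilityStatus(FertilityStatus.FERTILE)
    if day.discharge in ("peak-type-mucus", "non-peak-mucus"):
        return DayFertilityStatus(FertilityStatus.FERTILE)
    # dry day from here on
    d = day.day_of_cycle
    if peak is not None and d > peak:
        if d <= peak + rules.post_peak_fertile_days:
            return DayFertilityStatus(FertilityStatus.FERTILE)
        if d == peak + rules.end_of_day_only_post_peak_day:
            return DayFertilityStatus(FertilityStatus.NON_FERTILE, end_of_day_only=True)
        return DayFertilityStatus(FertilityStatus.NON_FERTILE)
    # pre-peak (or no peak identified): count-of-three after any mucus patch
    for back in range(1, rules.count_of_three + 1):
        j = idx - back
        if j < 0:
            break
        prev = days[j]
        if prev.observed and prev.discharge in ("peak-type-mucus", "non-peak-mucus"):
            return DayFertilityStatus(FertilityStatus.FERTILE)
    return DayFertilityStatus(
        FertilityStatus.NON_FERTILE,
        end_of_day_only=rules.prepeak_dry_end_of_day_only,
    )


def impute_cycle_length(history: Iterable[int]) -> int:
    """Median of a woman's observed cycle lengths, rounded half-up."""
    lengths = sorted(int(x) for x in history)
    if not lengths:
        raise ChartError("no lengths available for imputation")
    n = len(lengths)
    mid = n // 2
    if n % 2 == 1:
        med = float(lengths[mid])
    else:
        med = (lengths[mid - 1] + lengths[mid]) / 2.0
    return int(math.floor(med + 0.5))


def flag_possible_pregnancy(
    cycle: CoupleCycle,
    postpeak_threshold_days: int = 17,
    next_cycle_start_delay: Optional[int] = None,
    menses_delay_days: int = 7,
) -> bool:
    """Pregnancy surveillance: lengthened post-peak phase or delayed menses.

    ``next_cycle_start_delay`` is days past the expected next-cycle start
    (expected length minus actual gap), when known. With no identified peak
    day the post-peak criterion is unavailable and the menses-delay
    criterion is used alone; if that too is unknown, raises
    :class:`PeakUnknownError`.
    """
    menses_criterion = (
        next_cycle_start_delay is not None
        and next_cycle_start_delay >= menses_delay_days
    )
    if cycle.peak_day is None:
        if next_cycle_start_delay is None:
            raise PeakUnknownError(
                f"cycle {cycle.couple_id}/{cycle.cycle_index}: peak unknown and "
                "no menses timing available"
            )
        return menses_criterion
    postpeak = cycle.length_days - cycle.peak_day
    return postpeak >= postpeak_threshold_days or menses_criterion


# ---------------------------------------------------------------------------
# Chart file I/O (tab-delimited, "." for missing, bit-exact round trip)

CHART_COLUMNS = [
    "couple_id",
    "cycle_index",
    "day_of_cycle",
    "bleeding",
    "discharge",
    "observation_frequency",
    "intercourse",
    "intercourse_end_of_day",
]


def _fmt_bool(value: Optional[bool]) -> str:
    if value is None:
        return MISSING_TOKEN
    return "1" if value else "0"


def _parse_bool(token: str) -> Optional[bool]:
    if token == MISSING_TOKEN:
        return None
    if token in ("1", "0"):
        return token == "1"
    raise ChartError(f"invalid boolean token: {token!r}")


def write_chart_file(days: Iterable[DayRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CHART_COLUMNS)
        for d in days:
            writer.writerow(
                [
                    d.couple_id,
                    d.cycle_index,
                    d.day_of_cycle,
                    d.bleeding,
                    d.discharge,
                    d.observation_frequency,
                    _fmt_bool(d.intercourse),
                    _fmt_bool(d.intercourse_end_of_day),
                ]
            )


def read_chart_file(path) -> list[DayRecord]:
    records: list[DayRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != CHART_COLUMNS:
            raise ChartError(f"{path}: bad or missing chart header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CHART_COLUMNS):
                raise ChartError(f"{path}:{lineno}: expected {len(CHART_COLUMNS)} fields")
            try:
                records.append(
                    DayRecord(
                        couple_id=row[0],
                        cycle_index=int(row[1]),
                        day_of_cycle=int(row[2]),
                        bleeding=row[3],
                        discharge=row[4],
                        observation_frequency=row[5],
                        intercourse=bool(_parse_bool(row[6])),
                        intercourse_end_of_day=_parse_bool(row[7]),
                    )
                )
            except ChartError as exc:
                raise ChartError(f"{path}:{lineno}: {exc}") from exc
    return records


def cycles_from_day_records(
    days: Iterable[DayRecord],
    source: CycleSource = CycleSource.CHART_ONLY,
) -> list[CoupleCycle]:
    """Group flat day records into :class:`CoupleCycle` objects."""
    grouped: dict[tuple[str, int], list[DayRecord]] = {}
    for d in days:
        grouped.setdefault((d.couple_id, d.cycle_index), []).append(d)
    cycles = []
    for (couple_id, cycle_index), recs in sorted(grouped.items()):
        recs.sort(key=lambda r: r.day_of_cycle)
        cycle = CoupleCycle(
            couple_id=couple_id,
            cycle_index=cycle_index,
            length_days=recs[-1].day_of_cycle,
            days=tuple(recs),
            source=source,
        )
        cycle.peak_day = identify_peak(cycle).day
        cycles.append(cycle)
    return cycles
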