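"""Start-of-cycle intention questionnaires: scale, reconciliation, tables.

The six-level intention scale is totally ordered from least to most
conception-oriented ("achieving"); partner discrepancies resolve to the
most achieving response. Responses completed too late in the cycle are
dropped by the prospective-window filter before tabulation.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "IntentionLevel",
    "SOCResponse",
    "CoupleCycleIntention",
    "IntentionError",
    "FOUR_GROUP_ORDER",
    "LIFETABLE_GROUPS",
    "reconcile_couple_intention",
    "filter_prospective",
    "collapse_intentions",
    "concordance_table",
    "dedupe_responses",
    "read_soc_file",
    "write_soc_file",
]


class IntentionError(ValueError):
    pass


class IntentionLevel(enum.IntEnum):
    """Pregnancy intention for the upcoming cycle, ordered by 'achieving'.

    Larger value = more conception-oriented. ABSTAIN ranks least achieving.
    """

    ABSTAIN = 0
    TRYING_HARD_AVOID = 1
    AVOID = 2
    NEUTRAL = 3
    CONCEIVE = 4
    TRYING_HARD_CONCEIVE = 5

    @classmethod
    def from_token(cls, token: str) -> Optional["IntentionLevel"]:
        if token in (".", "", "MISSING"):
            return None
        try:
            return cls[token]
        except KeyError:
            raise IntentionError(f"unknown intention token: {token!r}") from None

    @property
    def token(self) -> str:
        return self.name


METHOD_FLAGS = frozenset({"condom", "withdrawal", "BBT", "urine_hormone", "other"})

FOUR_GROUP_ORDER = ("Achieving", "Neutral", "Avoiding", "Abstaining")
LIFETABLE_GROUPS = ("Conceive", "Avoiding", "Abstain")

_FOUR_GROUP = {
    IntentionLevel.TRYING_HARD_CONCEIVE: "Achieving",
    IntentionLevel.CONCEIVE: "Achieving",
    IntentionLevel.NEUTRAL: "Neutral",
    IntentionLevel.AVOID: "Avoiding",
    IntentionLevel.TRYING_HARD_AVOID: "Avoiding",
    IntentionLevel.ABSTAIN: "Abstaining",
}
# undecided couples are grouped with trying-to-conceive for life tables
_LIFETABLE = {
    IntentionLevel.TRYING_HARD_CONCEIVE: "Conceive",
    IntentionLevel.CONCEIVE: "Conceive",
    IntentionLevel.NEUTRAL: "Conceive",
    IntentionLevel.AVOID: "Avoiding",
    IntentionLevel.TRYING_HARD_AVOID: "Avoiding",
    IntentionLevel.ABSTAIN: "Abstain",
}


@dataclass(frozen=True)
class SOCResponse:
    couple_id: str
    cycle_index: int
    partner: str  # "F" or "M"
    completion_day: int
    intention: Optional[IntentionLevel]
    prior_cycle_methods: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.partner not in ("F", "M"):
            raise IntentionError(f"partner must be F or M, got {self.partner!r}")
        if self.completion_day < 0:
            raise IntentionError("completion_day must be >= 0")
        unknown = set(self.prior_cycle_methods) - METHOD_FLAGS
        if unknown:
            raise IntentionError(f"unknown method flags: {sorted(unknown)}")


@dataclass(frozen=True)
class CoupleCycleIntention:
    couple_id: str
    cycle_index: int
    female: Optional[IntentionLevel]
    male: Optional[IntentionLevel]
    reconciled: Optional[IntentionLevel]
    prospective: bool = True

    @property
    def single_responder(self) -> bool:
        return (self.female is None) != (self.male is None)


def reconcile_couple_intention(
    female: Optional[IntentionLevel], male: Optional[IntentionLevel]
) -> IntentionLevel:
    """Most achieving of the two partners' intentions (join on the scale)."""
    present = [x for x in (female, male) if x is not None]
    if not present:
        raise IntentionError("no intention: both partners missing")
    return max(present)


def filter_prospective(
    responses: Iterable[SOCResponse], window_days: Optional[int] = 11
) -> list[SOCResponse]:
    """Keep responses completed within the first ``window_days`` of the cycle.

    ``window_days=None`` disables the filter (the "All" sensitivity arm).
    """
    responses = list(responses)
    if window_days is None:
        return responses
    return [r for r in responses if r.completion_day <= window_days]


def collapse_intentions(level: IntentionLevel, scheme: str = "four_group") -> str:
    """Map a six-level intention onto a coarse reporting group."""
    if level is None:
        raise IntentionError("missing intention cannot be collapsed")
    if scheme == "four_group":
        return _FOUR_GROUP[level]
    if scheme == "lifetable":
        return _LIFETABLE[level]
    raise IntentionError(f"unknown collapse scheme: {scheme!r}")


def dedupe_responses(responses: Iterable[SOCResponse]) -> list[SOCResponse]:
    """One response per (couple, cycle, partner): the earliest completed wins."""
    best: dict[tuple[str, int, str], SOCResponse] = {}
    for r in responses:
        key = (r.couple_id, r.cycle_index, r.partner)
        if key not in best or r.completion_day < best[key].completion_day:
            best[key] = r
    return [best[k] for k in sorted(best)]


def build_couple_cycle_intentions(
    responses: Iterable[SOCResponse],
    window_days: Optional[int] = 11,
) -> list[CoupleCycleIntention]:
    """Pair partner responses per cycle and reconcile to a couple intention."""
    kept = filter_prospective(dedupe_responses(responses), window_days)
    by_cycle: dict[tuple[str, int], dict[str, SOCResponse]] = {}
    for r in kept:
        by_cycle.setdefault((r.couple_id, r.cycle_index), {})[r.partner] = r
    out = []
    for (couple_id, cycle_index), partners in sorted(by_cycle.items()):
        female = partners["F"].intention if "F" in partners else None
        male = partners["M"].intention if "M" in partners else None
        reconciled = None
        if female is not None or male is not None:
            reconciled = reconcile_couple_intention(female, male)
        out.append(
            CoupleCycleIntention(
                couple_id=couple_id,
                cycle_index=cycle_index,
                female=female,
                male=male,
                reconciled=reconciled,
            )
        )
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    matrix: pd.DataFrame  # female rows x male columns, four-group order
    concordant: int
    total: int
    excluded: int

    @property
    def proportion(self) -> float:
        return self.concordant / self.total


def concordance_table(cycles: Iterable[CoupleCycleIntention]) -> ConcordanceResult:
    """4x4 female-by-male intention cross-tab and its diagonal concordance.

    Cycles missing either partner's intention are excluded and counted.
    """
    cycles = list(cycles)
    matrix = pd.DataFrame(
        0, index=list(FOUR_GROUP_ORDER), columns=list(FOUR_GROUP_ORDER), dtype=int
    )
    excluded = 0
    for c in cycles:
        if c.female is None or c.male is None:
            excluded += 1
            continue
        f = collapse_intentions(c.female, "four_group")
        m = collapse_intentions(c.male, "four_group")
        matrix.loc[f, m] += 1
    total = int(matrix.to_numpy().sum())
    if total == 0:
        raise IntentionError("no data: no cycle has both partners' intentions")
    concordant = int(sum(matrix.loc[g, g] for g in FOUR_GROUP_ORDER))
    return ConcordanceResult(
        matrix=matrix, concordant=concordant, total=total, excluded=excluded
    )


def concordance_from_matrix(matrix: pd.DataFrame) -> ConcordanceResult:
    """Concordance from an already-tabulated 4x4 count matrix."""
    matrix = matrix.loc[list(FOUR_GROUP_ORDER), list(FOUR_GROUP_ORDER)].astype(int)
    total = int(matrix.to_numpy().sum())
    if total == 0:
        raise IntentionError("no data")
    concordant = int(sum(matrix.loc[g, g] for g in FOUR_GROUP_ORDER))
    return ConcordanceResult(matrix=matrix, concordant=concordant, total=total, excluded=0)


# ---------------------------------------------------------------------------
# SOC file I/O

SOC_COLUMNS = [
    "couple_id",
    "cycle_index",
    "partner",
    "completion_day",
    "intention",
    "prior_cycle_methods",
]


def write_soc_file(responses: Iterable[SOCResponse], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SOC_COLUMNS)
        for r in responses:
            writer.writerow(
                [
                    r.couple_id,
                    r.cycle_index,
                    r.partner,
                    r.completion_day,
                    r.intention.token if r.intention is not None else ".",
                    ";".join(sorted(r.prior_cycle_methods)) or ".",
                ]
            )


def read_soc_file(path) -> list[SOCResponse]:
    out: list[SOCResponse] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != SOC_COLUMNS:
            raise IntentionError(f"{path}: bad or missing SOC header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SOC_COLUMNS):
                raise IntentionError(f"{path}:{lineno}: expected {len(SOC_COLUMNS)} fields")
            methods = frozenset(row[5].split(";")) if row[5] != "." else frozenset()
            out.append(
                SOCResponse(
                    couple_id=row[0],
                    cycle_index=int(row[1]),
                    partner=row[2],
                    completion_day=int(row[3]),
                    intention=IntentionLevel.from_token(row[4]),
                    prior_cycle_methods=methods,
                )
            )
    return out
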