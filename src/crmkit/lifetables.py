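"""Discrete life tables for cumulative pregnancy probabilities.

Two estimators:

* single-decrement over ordinal cycles — per-ordinal conditional pregnancy
  probability q_i = events_i / n_at_risk_i and cumulative probability
  CP(k) = 1 − Π_{i<=k}(1 − q_i), stratified by (collapsed) cycle intention;
* multiple-decrement over ordinal months — cause-specific hazards sharing
  one all-use denominator, yielding per-cause net termination rates
  NR_c(K) = 100 · Σ_m q_{c,m} · Π_{j<m} p_j with p_j the all-cause
  continuation probability.

The per-ordinal accounting is deliberately transparent: counts in, counts
out, no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "CycleAtRisk",
    "MonthAtRisk",
    "OrdinalRiskRow",
    "LifeTableResult",
    "MultiDecrementResult",
    "LifeTableError",
    "CoupleTimeline",
    "build_timeline",
    "single_decrement",
    "sensitivity_grid",
    "multiple_decrement",
    "round_half_up",
]

ORDINAL_MONTH_DAYS = 30.44


class LifeTableError(ValueError):
    pass


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in printed tables."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CycleAtRisk:
    """One couple-cycle contributed to a single-decrement stratum."""

    couple_id: str
    ordinal: int  # the couple's study cycle number, 1-based
    stratum: str
    event: bool  # pregnancy in this cycle


@dataclass(frozen=True)
class MonthAtRisk:
    """One couple-month for the multiple-decrement table.

    ``cause`` is None for months without a pregnancy; censoring is implicit
    in the couple simply having no later months.
    """

    couple_id: str
    ordinal: int
    cause: Optional[str] = None


@dataclass(frozen=True)
class OrdinalRiskRow:
    stratum: str
    ordinal: int
    n_at_risk: int
    events: int
    withdrawals: int
    events_by_cause: Mapping[str, int] = field(default_factory=dict)

    @property
    def q(self) -> float:
        return self.events / self.n_at_risk


@dataclass
class LifeTableResult:
    stratum: str
    rows: list[OrdinalRiskRow]
    couples_ever: int
    couples_at_first_ordinal: int
    n_cycles: int
    n_events: int

    def cumulative_probability(self, k: Optional[int] = None) -> float:
        """CP(k) = 1 − Π_{i<=k}(1 − q_i) over ordinals with nonzero risk."""
        surv = 1.0
        for row in self.rows:
            if k is not None and row.ordinal > k:
                break
            if row.n_at_risk > 0:
                surv *= 1.0 - row.q
        return 1.0 - surv

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum": r.stratum,
                    "ordinal": r.ordinal,
                    "n_at_risk": r.n_at_risk,
                    "events": r.events,
                    "withdrawals": r.withdrawals,
                    "q": r.q if r.n_at_risk else float("nan"),
                }
                for r in self.rows
            ]
        )


def single_decrement(
    cycles: Iterable[CycleAtRisk],
    max_ordinal: int = 13,
    stratum: Optional[str] = None,
) -> dict[str, LifeTableResult]:
    """Single-decrement life table(s) over ordinal cycles, per stratum.

    Each cycle joins the stratum its own (reconciled, collapsed) intention
    maps to, at its couple-level ordinal; n_at_risk at an ordinal is the
    number of such cycles, events the pregnancies among them. Ordinals with
    zero cycles are skipped (q undefined) but still reported with
    n_at_risk=0.
    """
    cycles = [c for c in cycles if 1 <= c.ordinal <= max_ordinal]
    if stratum is not None:
        cycles = [c for c in cycles if c.stratum == stratum]
    strata = sorted({c.stratum for c in cycles})
    out: dict[str, LifeTableResult] = {}
    for s in strata:
        sub = [c for c in cycles if c.stratum == s]
        rows = []
        for ordinal in range(1, max_ordinal + 1):
            at = [c for c in sub if c.ordinal == ordinal]
            events = sum(c.event for c in at)
            # withdrawals: couples present at this ordinal, no event, absent later
            later = {c.couple_id for c in sub if c.ordinal > ordinal}
            withdrawals = sum(
                1 for c in at if not c.event and c.couple_id not in later
            )
            rows.append(
                OrdinalRiskRow(
                    stratum=s,
                    ordinal=ordinal,
                    n_at_risk=len(at),
                    events=events,
                    withdrawals=withdrawals,
                )
            )
        out[s] = LifeTableResult(
            stratum=s,
            rows=rows,
            couples_ever=len({c.couple_id for c in sub}),
            couples_at_first_ordinal=len({c.couple_id for c in sub if c.ordinal == 1}),
            n_cycles=len(sub),
            n_events=sum(c.event for c in sub),
        )
    return out


@dataclass
class MultiDecrementResult:
    rows: list[OrdinalRiskRow]
    causes: list[str]
    net_rates: dict[str, float]  # per 100 couples at max ordinal
    continuation: float
    n_couples: int
    n_events: int

    def accounting_identity(self) -> float:
        """Σ_c NR_c/100 + continuation — equals 1 by construction."""
        return sum(self.net_rates.values()) / 100.0 + self.continuation


def multiple_decrement(
    months: Iterable[MonthAtRisk],
    max_ordinal: int = 12,
    half_unit_correction: bool = False,
) -> MultiDecrementResult:
    """Multiple-decrement life table over ordinal months, shared denominator.

    All causes draw on the same all-use month denominator. Months carrying a
    pregnancy with ``cause=None`` are routed to an ``"Unresolved"`` cause by
    the caller; here a None cause simply means no event. With
    ``half_unit_correction`` withdrawals contribute half a month of exposure
    at their last ordinal (Potter convention) instead of a full one.
    """
    months = [m for m in months if 1 <= m.ordinal <= max_ordinal]
    causes = sorted({m.cause for m in months if m.cause is not None})
    rows: list[OrdinalRiskRow] = []
    surv = 1.0
    net = {c: 0.0 for c in causes}
    for ordinal in range(1, max_ordinal + 1):
        at = [m for m in months if m.ordinal == ordinal]
        by_cause = {c: sum(1 for m in at if m.cause == c) for c in causes}
        events = sum(by_cause.values())
        later = {m.couple_id for m in months if m.ordinal > ordinal}
        withdrawals = sum(
            1 for m in at if m.cause is None and m.couple_id not in later
        )
        n = len(at)
        denom = n - 0.5 * withdrawals if half_unit_correction else n
        rows.append(
            OrdinalRiskRow(
                stratum="all-use",
                ordinal=ordinal,
                n_at_risk=n,
                events=events,
                withdrawals=withdrawals,
                events_by_cause=by_cause,
            )
        )
        if denom <= 0:
            continue
        q_all = 0.0
        for c in causes:
            q_c = by_cause[c] / denom
            net[c] += q_c * surv
            q_all += q_c
        if q_all > 1.0:
            raise LifeTableError(f"ordinal {ordinal}: total hazard exceeds 1")
        surv *= 1.0 - q_all
    return MultiDecrementResult(
        rows=rows,
        causes=causes,
        net_rates={c: 100.0 * v for c, v in net.items()},
        continuation=surv,
        n_couples=len({m.couple_id for m in months}),
        n_events=sum(1 for m in months if m.cause is not None),
    )


# ---------------------------------------------------------------------------
# Couple timelines

@dataclass(frozen=True)
class CoupleTimeline:
    """Analytic entry/exit for one couple, in study days.

    ``analytic_start`` is the later of the start of the consent cycle and
    the start of the first cycle with recorded intercourse; ``exit_day`` is
    the day of pregnancy / stopping / loss to follow-up / one-year cap.
    """

    couple_id: str
    analytic_start: int
    exit_day: int
    exit_reason: str  # pregnancy | completed_year | stopped | lost

    def __post_init__(self) -> None:
        if self.exit_day < self.analytic_start:
            raise LifeTableError(
                f"couple {self.couple_id}: invalid timeline (exit before entry)"
            )

    def ordinal_month(self, day: int, month_days: float = ORDINAL_MONTH_DAYS) -> int:
        """1-based ordinal month bin containing study ``day``."""
        if day < self.analytic_start:
            raise LifeTableError("day precedes analytic start")
        return int((day - self.analytic_start) // month_days) + 1

    def n_complete_months(self, month_days: float = ORDINAL_MONTH_DAYS) -> int:
        # half-day tolerance so a 365-day year counts as 12 ordinal months
        # of 30.44 days (12 * 30.44 = 365.28)
        return int((self.exit_day - self.analytic_start + 0.5) // month_days)


def build_timeline(
    couple_id: str,
    cycle_starts: Sequence[int],
    consent_day: int,
    first_intercourse_cycle: Optional[int],
    exit_day: int,
    exit_reason: str,
) -> CoupleTimeline:
    """Derive the analytic timeline from consent and recorded activity.

    ``cycle_starts`` are study-day starts of the couple's cycles in order;
    ``first_intercourse_cycle`` is the 1-based index of the first cycle with
    recorded intercourse (None if none recorded — entry falls back to the
    consent cycle).
    """
    if not cycle_starts:
        raise LifeTableError(f"couple {couple_id}: no cycles")
    consent_cycle_start = cycle_starts[0]
    for s in cycle_starts:
        if s <= consent_day:
            consent_cycle_start = s
    start = consent_cycle_start
    if first_intercourse_cycle is not None:
        fi_start = cycle_starts[first_intercourse_cycle - 1]
        start = max(start, fi_start)
    return CoupleTimeline(
        couple_id=couple_id,
        analytic_start=start,
        exit_day=exit_day,
        exit_reason=exit_reason,
    )


def months_at_risk(
    timeline: CoupleTimeline,
    pregnancy_day: Optional[int],
    cause: Optional[str],
    max_ordinal: int = 12,
    month_days: float = ORDINAL_MONTH_DAYS,
) -> list[MonthAtRisk]:
    """Expand a timeline into per-ordinal-month risk records.

    A pregnancy exits at the ordinal month containing its conception day;
    other exits censor at the end of the last *complete* month.
    """
    if pregnancy_day is not None:
        last = min(timeline.ordinal_month(pregnancy_day, month_days), max_ordinal)
        out = [
            MonthAtRisk(timeline.couple_id, m, None) for m in range(1, last)
        ]
        out.append(MonthAtRisk(timeline.couple_id, last, cause))
        return out
    last = min(timeline.n_complete_months(month_days), max_ordinal)
    return [MonthAtRisk(timeline.couple_id, m, None) for m in range(1, last + 1)]


# ---------------------------------------------------------------------------
# Sensitivity grid (window x barrier-exclusion, per life-table stratum)

SENSITIVITY_STRATA = ("Conceive", "Avoiding", "TryingHardAvoid", "Abstain")


@dataclass(frozen=True)
class SensitivityCycle:
    """Input cycle for the sensitivity grid, carrying both axes' flags."""

    couple_id: str
    ordinal: int
    stratum: str  # lifetable-collapsed intention group
    trying_hard_avoid: bool  # member of the strictest avoid subgroup
    event: bool
    prospective: bool  # SOC completed within the window
    barrier_or_withdrawal: bool


def sensitivity_grid(
    cycles: Iterable[SensitivityCycle],
    max_ordinal: int = 13,
) -> pd.DataFrame:
    """Life tables across {window, all} x {barrier excluded, included} arms.

    Returns one row per (window arm, barrier arm, stratum) with couple,
    cycle and pregnancy counts and the cumulative probability at 6 and
    ``max_ordinal`` cycles.
    """
    cycles = list(cycles)
    records = []
    for window_label, keep_window in (("<=11d", True), ("all", False)):
        for barrier_label, exclude_barrier in (("excluded", True), ("included", False)):
            pool = [
                c
                for c in cycles
                if (c.prospective or not keep_window)
                and not (exclude_barrier and c.barrier_or_withdrawal)
            ]
            for stratum in SENSITIVITY_STRATA:
                if stratum == "TryingHardAvoid":
                    sub = [c for c in pool if c.trying_hard_avoid]
                else:
                    sub = [c for c in pool if c.stratum == stratum]
                risk = [
                    CycleAtRisk(c.couple_id, c.ordinal, stratum, c.event) for c in sub
                ]
                tables = single_decrement(risk, max_ordinal=max_ordinal)
                result = tables.get(stratum)
                records.append(
                    {
                        "window": window_label,
                        "barrier": barrier_label,
                        "stratum": stratum,
                        "couples": result.couples_ever if result else 0,
                        "couples_at_first_ordinal": (
                            result.couples_at_first_ordinal if result else 0
                        ),
                        "cycles": result.n_cycles if result else 0,
                        "pregnancies": result.n_events if result else 0,
                        "cp6": result.cumulative_probability(6) if result else 0.0,
                        f"cp{max_ordinal}": (
                            result.cumulative_probability(max_ordinal) if result else 0.0
                        ),
                    }
                )
    return pd.DataFrame.from_records(records)
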