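"""End-to-end analysis pipeline: streams in, report bundle out.

Takes the four input streams (charts, SOC questionnaires, couple records,
pregnancy evaluations) plus analysis flags, and produces the full set of
published-table-shaped reports: source completeness, intention
concordance, intention-by-behavior, intention-stratified single-decrement
life tables with both sensitivity axes, the correct-use cascade, the
multiple-decrement classification life table, and reason-code frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import behavior_tables, correct_use, intentions, lifetables
from .chart_core import (
    CoupleCycle,
    CycleSource,
    DayRecord,
    RuleTable,
    classify_days,
    cycles_from_day_records,
    impute_cycle_length,
)
from .correct_use import (
    CorrectUseCycle,
    RecordingFidelity,
    TeacherAssessment,
    classify_cycle_correct_use,
    correct_use_table,
    couple_eligible,
)
from .intentions import IntentionLevel, SOCResponse, collapse_intentions
from .lifetables import (
    MonthAtRisk,
    ORDINAL_MONTH_DAYS,
    SensitivityCycle,
    multiple_decrement,
    round_half_up,
    sensitivity_grid,
)
from .pregnancy_classifier import (
    CrMSCategory,
    PregnancyEvaluation,
    classification_summary,
    classify_pregnancy,
)

__all__ = ["AnalysisFlags", "ReportBundle", "run_pipeline", "write_reports"]


@dataclass(frozen=True)
class AnalysisFlags:
    window_days: Optional[int] = 11
    strict_end_of_day: bool = True
    half_unit_correction: bool = False
    max_cycle_ordinal: int = 13
    max_month_ordinal: int = 12
    month_days: float = ORDINAL_MONTH_DAYS
    rule_table: RuleTable = field(default_factory=RuleTable.default)


@dataclass
class ReportBundle:
    sources: pd.DataFrame  # Fig-1-style cycle source breakdown
    concordance_matrix: pd.DataFrame
    concordance: dict
    behavior: pd.DataFrame
    behavior_excluded: int
    sensitivity: pd.DataFrame
    correct_use: pd.DataFrame
    classification_counts: pd.Series
    net_rates: pd.DataFrame
    reasons: pd.DataFrame
    completeness: dict

    def results_dict(self) -> dict:
        return {
            "sources": self.sources.to_dict(orient="records"),
            "concordance": self.concordance,
            "behavior": self.behavior.reset_index(names="intention").to_dict(orient="records"),
            "behavior_excluded": self.behavior_excluded,
            "sensitivity": self.sensitivity.to_dict(orient="records"),
            "correct_use": self.correct_use.to_dict(orient="records"),
            "classification_counts": self.classification_counts.to_dict(),
            "net_rates": self.net_rates.to_dict(orient="records"),
            "reasons": self.reasons.to_dict(orient="records"),
            "completeness": self.completeness,
        }


def run_pipeline(
    day_records: Iterable[DayRecord],
    soc_responses: Iterable[SOCResponse],
    fidelity: Iterable[RecordingFidelity],
    assessments: Iterable[TeacherAssessment],
    evaluations: Iterable[PregnancyEvaluation],
    flags: AnalysisFlags = AnalysisFlags(),
) -> ReportBundle:
    day_records = list(day_records)
    soc_responses = intentions.dedupe_responses(soc_responses)
    fidelity = list(fidelity)
    assessments = list(assessments)
    evaluations = list(evaluations)
    rules = flags.rule_table

    pregnancies = {(e.couple_id, e.cycle_index) for e in evaluations}

    # --- cycle universe -----------------------------------------------------
    chart_cycles = cycles_from_day_records(day_records)
    chart_keys = {(c.couple_id, c.cycle_index) for c in chart_cycles}
    soc_keys = {(r.couple_id, r.cycle_index) for r in soc_responses}
    for c in chart_cycles:
        if (c.couple_id, c.cycle_index) in pregnancies:
            c.pregnancy_in_cycle = True
        if (c.couple_id, c.cycle_index) in soc_keys:
            c.source = CycleSource.CHART_AND_SOC

    # cycles invisible in either stream show up as gaps in the per-couple
    # cycle numbering; their lengths are imputed from the woman's others
    known_max: dict[str, int] = {}
    for cid, idx in chart_keys | soc_keys:
        known_max[cid] = max(known_max.get(cid, 0), idx)
    observed_lengths: dict[str, list[int]] = {}
    for c in chart_cycles:
        observed_lengths.setdefault(c.couple_id, []).append(c.length_days)

    all_cycles: list[CoupleCycle] = list(chart_cycles)
    for cid, nmax in sorted(known_max.items()):
        for idx in range(1, nmax + 1):
            key = (cid, idx)
            if key in chart_keys:
                continue
            if key in soc_keys:
                source = CycleSource.SOC_ONLY
            else:
                source = CycleSource.IMPUTED
            lengths = observed_lengths.get(cid, [])
            length = impute_cycle_length(lengths) if lengths else 29
            all_cycles.append(
                CoupleCycle(
                    couple_id=cid,
                    cycle_index=idx,
                    length_days=length,
                    source=source,
                    pregnancy_in_cycle=key in pregnancies,
                )
            )
    all_cycles.sort(key=lambda c: (c.couple_id, c.cycle_index))

    sources = (
        pd.Series([c.source.value for c in all_cycles])
        .value_counts()
        .reindex([s.value for s in CycleSource], fill_value=0)
        .rename_axis("source")
        .rename("n_cycles")
        .reset_index()
    )

    # --- intentions ---------------------------------------------------------
    cci_window = intentions.build_couple_cycle_intentions(
        soc_responses, window_days=flags.window_days
    )
    cci_all = intentions.build_couple_cycle_intentions(soc_responses, window_days=None)
    try:
        conc = intentions.concordance_table(cci_window)
        concordance_matrix = conc.matrix
        concordance = {
            "concordant": conc.concordant,
            "total": conc.total,
            "excluded": conc.excluded,
            "percent": round_half_up(100.0 * conc.proportion, 1),
        }
    except intentions.IntentionError:
        concordance_matrix = pd.DataFrame(
            0, index=list(intentions.FOUR_GROUP_ORDER),
            columns=list(intentions.FOUR_GROUP_ORDER),
        )
        concordance = {"concordant": 0, "total": 0, "excluded": len(cci_window), "percent": None}

    reconciled_window = {
        (c.couple_id, c.cycle_index): c.reconciled for c in cci_window
    }
    reconciled_all = {(c.couple_id, c.cycle_index): c.reconciled for c in cci_all}

    # --- behavior -----------------------------------------------------------
    statuses = {
        (c.couple_id, c.cycle_index): classify_days(c, rules) for c in chart_cycles
    }
    barrier_flags = behavior_tables.barrier_withdrawal_flags(
        soc_responses,
        cycle_keys=[(c.couple_id, c.cycle_index) for c in all_cycles],
    )
    behaviors = [
        behavior_tables.compute_cycle_behavior(
            c,
            statuses[(c.couple_id, c.cycle_index)],
            barrier_or_withdrawal=barrier_flags.get((c.couple_id, c.cycle_index), False),
        )
        for c in chart_cycles
    ]
    intents_for_table = {
        (c.couple_id, c.cycle_index): reconciled_window.get((c.couple_id, c.cycle_index))
        for c in all_cycles
    }
    behavior_table, behavior_excluded = behavior_tables.intention_behavior_table(
        intents_for_table, behaviors
    )

    # --- single-decrement sensitivity grid ----------------------------------
    sens_cycles = []
    for c in all_cycles:
        key = (c.couple_id, c.cycle_index)
        level = reconciled_window.get(key)
        if level is None:
            level = reconciled_all.get(key)
        if level is None:
            continue
        sens_cycles.append(
            SensitivityCycle(
                couple_id=c.couple_id,
                ordinal=c.cycle_index,
                stratum=_sens_stratum(level),
                trying_hard_avoid=level is IntentionLevel.TRYING_HARD_AVOID,
                event=c.pregnancy_in_cycle,
                prospective=key in reconciled_window and reconciled_window[key] is not None,
                barrier_or_withdrawal=barrier_flags.get(key, False),
            )
        )
    sensitivity = sensitivity_grid(sens_cycles, max_ordinal=flags.max_cycle_ordinal)

    # --- correct use --------------------------------------------------------
    fid_by_couple: dict[str, list[RecordingFidelity]] = {}
    for f in fidelity:
        fid_by_couple.setdefault(f.couple_id, []).append(f)
    assess_by_key = {(a.couple_id, a.cycle_index): a for a in assessments}
    cu_cycles: list[CorrectUseCycle] = []
    for c in chart_cycles:
        key = (c.couple_id, c.cycle_index)
        if not couple_eligible(fid_by_couple.get(c.couple_id, [])):
            continue
        try:
            labels = classify_cycle_correct_use(
                c,
                statuses[key],
                assessment=assess_by_key.get(key),
                barrier_or_withdrawal=barrier_flags.get(key, False),
                strict_end_of_day=flags.strict_end_of_day,
            )
        except correct_use.IncompleteChartError:
            continue
        cu_cycles.append(
            CorrectUseCycle(
                couple_id=c.couple_id,
                cycle_index=c.cycle_index,
                ordinal=c.cycle_index,
                labels=frozenset(labels),
                pregnancy=c.pregnancy_in_cycle,
            )
        )
    cu_table = correct_use_table(cu_cycles)

    # --- pregnancy classification and multiple-decrement table --------------
    counts, reasons = classification_summary(evaluations)
    category_by_key = {
        (e.couple_id, e.cycle_index): classify_pregnancy(e).category for e in evaluations
    }
    non_crms_couples = {
        cid for (cid, _), cat in category_by_key.items() if cat is CrMSCategory.NON_CRMS
    }
    months: list[MonthAtRisk] = []
    by_couple: dict[str, list[CoupleCycle]] = {}
    for c in all_cycles:
        by_couple.setdefault(c.couple_id, []).append(c)
    for cid, cyc in by_couple.items():
        if cid in non_crms_couples:
            continue
        offset = 0
        event_day = None
        cause = None
        for c in cyc:
            if c.pregnancy_in_cycle:
                cat = category_by_key.get((cid, c.cycle_index), CrMSCategory.UNRESOLVED)
                cause = cat.value
                # event placed mid-cycle: conception day is not in the streams
                event_day = offset + c.length_days // 2
                break
            offset += c.length_days
        if event_day is not None:
            last = min(
                int(event_day // flags.month_days) + 1, flags.max_month_ordinal
            )
            months.extend(MonthAtRisk(cid, m) for m in range(1, last))
            months.append(MonthAtRisk(cid, last, cause))
        else:
            total = min(offset, 366)
            last = min(int(total // flags.month_days), flags.max_month_ordinal)
            months.extend(MonthAtRisk(cid, m) for m in range(1, last + 1))
    md = multiple_decrement(
        months,
        max_ordinal=flags.max_month_ordinal,
        half_unit_correction=flags.half_unit_correction,
    )
    net_rates = pd.DataFrame(
        [
            {
                "category": c,
                "n_pregnancies": int(counts.get(c, 0)),
                "net_rate_per_100": round_half_up(md.net_rates[c], 1),
            }
            for c in md.causes
        ]
        + [
            {
                "category": "NON_CRMS",
                "n_pregnancies": int(counts.get("NON_CRMS", 0)),
                "net_rate_per_100": float("nan"),
            }
        ]
    )

    completeness = {
        "n_couples": len({c.couple_id for c in all_cycles}) if all_cycles else 0,
        "n_cycles": len(all_cycles),
        "n_charted_cycles": len(chart_cycles),
        "n_charted_days": sum(c.length_days for c in chart_cycles),
        "n_pregnancies": len(evaluations),
        "cycles_missing_intention": sum(
            1
            for c in all_cycles
            if reconciled_window.get((c.couple_id, c.cycle_index)) is None
        ),
        "single_responder_cycles": sum(1 for c in cci_window if c.single_responder),
        "day_status_counts": _day_status_counts(statuses),
        "accounting_identity": md.accounting_identity(),
        "continuation_12mo": md.continuation,
    }

    return ReportBundle(
        sources=sources,
        concordance_matrix=concordance_matrix,
        concordance=concordance,
        behavior=behavior_table,
        behavior_excluded=behavior_excluded,
        sensitivity=sensitivity,
        correct_use=cu_table,
        classification_counts=counts,
        net_rates=net_rates,
        reasons=reasons,
        completeness=completeness,
    )


def _sens_stratum(level: IntentionLevel) -> str:
    group = collapse_intentions(level, "lifetable")
    return {"Conceive": "Conceive", "Avoiding": "Avoiding", "Abstain": "Abstain"}[group]


def _day_status_counts(statuses: dict) -> dict:
    counts = {"FERTILE": 0, "NON_FERTILE": 0, "UNKNOWN": 0}
    for seq in statuses.values():
        for s in seq:
            counts[s.status.value] += 1
    return counts


def write_reports(bundle: ReportBundle, outdir) -> dict[str, Path]:
    """Render the bundle as tab-delimited reports plus results.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=index)
        paths[name] = p

    _tsv("cycle_sources", bundle.sources)
    _tsv("intention_concordance", bundle.concordance_matrix, index=True)
    _tsv("intention_behavior", bundle.behavior, index=True)
    _tsv("lifetable_sensitivity", bundle.sensitivity)
    _tsv("correct_use", bundle.correct_use)
    _tsv("pregnancy_classification", bundle.net_rates)
    _tsv("classification_reasons", bundle.reasons)

    results = outdir / "results.json"
    with open(results, "w") as fh:
        json.dump(bundle.results_dict(), fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    paths["results"] = results
    return paths


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
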