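"""Seeded synthetic cohort generator with known ground truth.

Emulates the four input streams the pipeline consumes — daily charts,
start-of-cycle questionnaires, couple baselines, and pregnancy
evaluations — with the statistical structure the analysis assumes:
cycle-length variation, mucus build-up to a peak day, missing
observations, intention-conditioned intercourse with leakage onto fertile
days, day-specific conception probabilities indexed to the true ovulation
day, barrier/withdrawal cycles, late or missing questionnaire responses,
dropout, and one-year censoring.

Ground truth (true conception probabilities, true fertile windows, true
intentions) is retained beside the emitted records so estimators can be
checked for parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .chart_core import (
    CoupleCycle,
    CycleSource,
    DayRecord,
    RuleTable,
    classify_days,
    identify_peak,
    write_chart_file,
)
from .correct_use import ExitAnswer, RecordingFidelity, TeacherAssessment
from .intentions import IntentionLevel, SOCResponse, write_soc_file
from .pregnancy_classifier import PregnancyEvaluation, write_evaluation_file

__all__ = ["SimConfig", "SimCohort", "generate_cohort", "ground_truth_report", "write_cohort"]

_LEVELS = list(IntentionLevel)

_DEFAULT_MIX = {
    "TRYING_HARD_CONCEIVE": 0.02,
    "CONCEIVE": 0.04,
    "NEUTRAL": 0.05,
    "AVOID": 0.46,
    "TRYING_HARD_AVOID": 0.33,
    "ABSTAIN": 0.10,
}

# per-day intercourse probability by intention and perceived day status
_DEFAULT_RATES = {
    "TRYING_HARD_CONCEIVE": {"FERTILE": 0.45, "NON_FERTILE": 0.15, "UNKNOWN": 0.25},
    "CONCEIVE": {"FERTILE": 0.35, "NON_FERTILE": 0.15, "UNKNOWN": 0.20},
    "NEUTRAL": {"FERTILE": 0.15, "NON_FERTILE": 0.15, "UNKNOWN": 0.15},
    "AVOID": {"FERTILE": 0.05, "NON_FERTILE": 0.20, "UNKNOWN": 0.06},
    "TRYING_HARD_AVOID": {"FERTILE": 0.03, "NON_FERTILE": 0.20, "UNKNOWN": 0.04},
    "ABSTAIN": {"FERTILE": 0.004, "NON_FERTILE": 0.01, "UNKNOWN": 0.004},
}

_DEFAULT_FIDELITY = {
    "ALL_WITHOUT_EXCEPTION": 0.45,
    "NEARLY_ALL_RARE_EXCEPTION": 0.17,
    "NOT_ALL": 0.12,
    "MISSING": 0.26,
}


@dataclass
class SimConfig:
    """Generator parameters. The seed fully determines the cohort."""

    n_couples: int = 296
    seed: int = 0
    cycle_length_mean: float = 29.0
    cycle_length_sd: float = 3.0
    cycle_length_min: int = 21
    cycle_length_max: int = 42
    luteal_length_mean: float = 13.0
    luteal_length_sd: float = 1.5
    mucus_buildup_days: int = 5
    missing_observation_rate: float = 0.05
    intention_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    intention_stay_prob: float = 0.85
    intercourse_rates: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_RATES.items()}
    )
    # conception probability per intercourse day, ovulation-5 .. ovulation+1
    fecundability: tuple = (0.03, 0.07, 0.12, 0.20, 0.26, 0.30, 0.10)
    barrier_cycle_prob: float = 0.06
    barrier_attenuation: float = 0.2
    soc_mean_day: float = 4.0
    soc_late_prob: float = 0.08
    soc_nonresponse_f: float = 0.12
    soc_nonresponse_m: float = 0.22
    partner_discordance_prob: float = 0.08
    chart_missing_prob: float = 0.08
    soc_and_chart_missing_prob: float = 0.04
    fidelity_mix: dict = field(default_factory=lambda: dict(_DEFAULT_FIDELITY))
    assessment_ok_prob: float = 0.8
    nonstandard_chart_prob: float = 0.02
    eval_missing_prob: float = 0.12
    monthly_dropout_hazard: float = 0.025
    max_followup_days: int = 365
    pregnant_postpeak_days: int = 20

    def __post_init__(self) -> None:
        probs = (
            [self.missing_observation_rate, self.barrier_cycle_prob,
             self.barrier_attenuation, self.soc_late_prob, self.soc_nonresponse_f,
             self.soc_nonresponse_m, self.partner_discordance_prob,
             self.chart_missing_prob, self.soc_and_chart_missing_prob,
             self.assessment_ok_prob, self.nonstandard_chart_prob,
             self.eval_missing_prob, self.monthly_dropout_hazard,
             self.intention_stay_prob]
            + list(self.fecundability)
            + list(self.intention_mix.values())
            + list(self.fidelity_mix.values())
            + [p for v in self.intercourse_rates.values() for p in v.values()]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("config out of range: probabilities must lie in [0, 1]")
        if len(self.fecundability) != 7:
            raise ValueError("config out of range: fecundability vector must have length 7")
        if self.n_couples < 0:
            raise ValueError("config out of range: n_couples must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("scenario", None)
        if "fecundability" in raw:
            raw["fecundability"] = tuple(raw["fecundability"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["fecundability"] = list(self.fecundability)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimCohort:
    """Everything the pipeline reads, plus generator ground truth."""

    config: SimConfig
    cycles: list  # CoupleCycle, all sources
    day_records: list  # flat DayRecord stream (charted cycles only)
    soc_responses: list  # SOCResponse
    fidelity: list  # RecordingFidelity
    assessments: list  # TeacherAssessment
    evaluations: list  # PregnancyEvaluation
    baselines: pd.DataFrame
    truth: pd.DataFrame  # one row per generated cycle
    timelines: pd.DataFrame  # one row per couple


def _draw_level(rng: np.random.Generator, mix: dict) -> IntentionLevel:
    names = list(mix)
    p = np.asarray([mix[n] for n in names], dtype=float)
    p = p / p.sum()
    return IntentionLevel[names[rng.choice(len(names), p=p)]]


def _next_intention(
    rng: np.random.Generator, current: IntentionLevel, cfg: SimConfig
) -> IntentionLevel:
    if rng.random() < cfg.intention_stay_prob:
        return current
    return _draw_level(rng, cfg.intention_mix)


def _make_chart_days(
    rng: np.random.Generator,
    couple_id: str,
    cycle_index: int,
    length: int,
    peak: int,
    cfg: SimConfig,
) -> list[DayRecord]:
    """Observation pattern for one cycle (no intercourse yet)."""
    menses = min(5, length)
    bleed_codes = ["H", "M", "M", "L", "VL"]
    mucus_start = max(peak - cfg.mucus_buildup_days + 1, menses + 1)
    peak_type_start = max(peak - 2, mucus_start)
    days = []
    for d in range(1, length + 1):
        bleeding = bleed_codes[d - 1] if d <= menses else "none"
        if mucus_start <= d <= peak:
            discharge = "peak-type-mucus" if d >= peak_type_start else "non-peak-mucus"
        else:
            discharge = "dry"
        freq = "AD" if rng.random() < 0.8 else rng.choice(["x1", "x2", "x3"])
        if bleeding == "none" and rng.random() < cfg.missing_observation_rate:
            discharge, freq = "unobserved", "none"
        days.append(
            DayRecord(
                couple_id=couple_id,
                cycle_index=cycle_index,
                day_of_cycle=d,
                bleeding=bleeding,
                discharge=discharge,
                observation_frequency=str(freq),
                intercourse=False,
            )
        )
    return days


def _build_evaluation(
    rng: np.random.Generator,
    couple_id: str,
    cycle_index: int,
    cycle: CoupleCycle,
    statuses,
    barrier: bool,
    true_window: tuple[int, int],
    cfg: SimConfig,
) -> PregnancyEvaluation:
    """Derive structured pregnancy-review findings from generator truth."""
    acts = [
        (d, s) for d, s in zip(cycle.days, statuses) if d.intercourse
    ]
    fertile_acts = [(d, s) for d, s in acts if s.status.value == "FERTILE"]
    unknown_acts = [(d, s) for d, s in acts if s.status.value == "UNKNOWN"]
    ambiguous_acts = [
        (d, s) for d, s in acts if s.end_of_day_only and d.intercourse_end_of_day is not True
    ]
    if barrier and fertile_acts:
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            intercourse_on_known_fertile=True,
            fertile_day_type="other_fertile",
            barrier_or_withdrawal_on_fertile=True,
        )
    if rng.random() < cfg.eval_missing_prob:
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            evaluation_done=False,
            intercourse_on_known_fertile=None,
            fertile_day_type="unknown",
            info_sufficient=False,
        )
    if fertile_acts:
        peak_ish = any(
            d.discharge == "peak-type-mucus"
            or (cycle.peak_day is not None and 0 <= d.day_of_cycle - cycle.peak_day <= 3)
            for d, _ in fertile_acts
        )
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            intercourse_on_known_fertile=True,
            fertile_day_type="peak_type_or_count3" if peak_ish else "other_fertile",
        )
    if unknown_acts:
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            intercourse_on_known_fertile=None,
            fertile_day_type="unknown",
            achieving_behaviors=frozenset({"missed_observations_knowing"}),
        )
    if ambiguous_acts:
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            intercourse_on_known_fertile=False,
            fertile_day_type="none",
            end_of_day_ambiguous=True,
        )
    # conception without perceived fertile-day intercourse: the chart missed
    # the true window (peak-day noise) -> using-related, occasionally with a
    # contributory teaching deficiency
    in_true_window = any(
        true_window[0] <= d.day_of_cycle <= true_window[1] for d, _ in acts
    )
    if in_true_window:
        teaching = (
            frozenset({"followup_schedule"}) if rng.random() < 0.3 else frozenset()
        )
        if rng.random() < 0.5:
            return PregnancyEvaluation(
                couple_id=couple_id,
                cycle_index=cycle_index,
                intercourse_on_known_fertile=False,
                fertile_day_type="none",
                misinterpretation=True,
                teaching_deficiencies=teaching,
            )
        if teaching:
            return PregnancyEvaluation(
                couple_id=couple_id,
                cycle_index=cycle_index,
                intercourse_on_known_fertile=False,
                fertile_day_type="none",
                teaching_deficiencies=teaching,
            )
        return PregnancyEvaluation(
            couple_id=couple_id,
            cycle_index=cycle_index,
            intercourse_on_known_fertile=False,
            fertile_day_type="none",
            double_peak_missed=True,
        )
    return PregnancyEvaluation(
        couple_id=couple_id,
        cycle_index=cycle_index,
        intercourse_on_known_fertile=False,
        fertile_day_type="none",
    )


def generate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full cohort; byte-identical for identical config."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rules = RuleTable.default()

    cycles: list[CoupleCycle] = []
    day_records: list[DayRecord] = []
    soc: list[SOCResponse] = []
    fidelity: list[RecordingFidelity] = []
    assessments: list[TeacherAssessment] = []
    evaluations: list[PregnancyEvaluation] = []
    truth_rows: list[dict] = []
    timeline_rows: list[dict] = []
    baseline_rows: list[dict] = []

    fid_names = list(cfg.fidelity_mix)
    fid_p = np.asarray([cfg.fidelity_mix[k] for k in fid_names], dtype=float)
    fid_p = fid_p / fid_p.sum()
    fec = np.asarray(cfg.fecundability, dtype=float)

    for ci in range(cfg.n_couples):
        couple_id = f"C{ci + 1:04d}"
        female_age = float(np.clip(rng.normal(27.1, 4.5), 18, 40))
        male_age = float(np.clip(rng.normal(28.9, 5.6), 18, 55))
        baseline_rows.append(
            {
                "couple_id": couple_id,
                "female_age": round(female_age, 1),
                "male_age": round(male_age, 1),
                "intended_time_to_child_years": float(rng.choice([0.5, 1.5, 3.0, 5.0])),
                "motivation_positive_f": round(float(np.clip(rng.normal(3.3, 0.5), 1, 4)), 2),
                "motivation_positive_m": round(float(np.clip(rng.normal(3.3, 0.5), 1, 4)), 2),
            }
        )
        for partner in ("F", "M"):
            fidelity.append(
                RecordingFidelity(
                    couple_id=couple_id,
                    partner=partner,
                    exit_answer=ExitAnswer[fid_names[rng.choice(len(fid_names), p=fid_p)]],
                )
            )

        intention = _draw_level(rng, cfg.intention_mix)
        day_cursor = 0  # study day of current cycle start
        cycle_index = 0
        exit_reason = "completed_year"
        pregnancy_day: Optional[float] = None
        exit_day = cfg.max_followup_days

        while day_cursor < cfg.max_followup_days:
            cycle_index += 1
            if cycle_index > 1:
                intention = _next_intention(rng, intention, cfg)
            length = int(
                np.clip(
                    round(rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd)),
                    cfg.cycle_length_min,
                    cfg.cycle_length_max,
                )
            )
            luteal = int(np.clip(round(rng.normal(cfg.luteal_length_mean, cfg.luteal_length_sd)), 10, 16))
            ovulation = int(np.clip(length - luteal, 7, length - 8))
            peak = int(np.clip(ovulation + rng.integers(-1, 2), 7, length - 4))

            days = _make_chart_days(rng, couple_id, cycle_index, length, peak, cfg)
            chart_cycle = CoupleCycle(
                couple_id=couple_id,
                cycle_index=cycle_index,
                length_days=length,
                days=tuple(days),
                start_date=day_cursor,
                source=CycleSource.CHART_ONLY,
            )
            chart_cycle.peak_day = identify_peak(chart_cycle).day
            statuses = classify_days(chart_cycle, rules)

            rates = cfg.intercourse_rates[intention.token]
            barrier = (
                intention <= IntentionLevel.AVOID
                and rng.random() < cfg.barrier_cycle_prob
            )
            new_days = []
            for d, s in zip(chart_cycle.days, statuses):
                p = rates[s.status.value]
                sex = rng.random() < p
                eod: Optional[bool] = None
                if sex and s.end_of_day_only:
                    # end-of-day timing mostly unrecorded on this chart format
                    eod = True if rng.random() < 0.2 else None
                new_days.append(dataclasses.replace(d, intercourse=sex, intercourse_end_of_day=eod))
            days = new_days

            # conception from the true fertile window, ovulation-5..ovulation+1
            window_lo, window_hi = ovulation - 5, ovulation + 1
            p_days = []
            for d in days:
                if d.intercourse and window_lo <= d.day_of_cycle <= window_hi:
                    p = fec[d.day_of_cycle - window_lo]
                    if barrier:
                        p *= cfg.barrier_attenuation
                    p_days.append((d.day_of_cycle, p))
            p_no = float(np.prod([1.0 - p for _, p in p_days])) if p_days else 1.0
            p_cycle = 1.0 - p_no
            conceived = bool(p_days) and rng.random() < p_cycle
            conception_day = None
            if conceived:
                weights = np.asarray([p for _, p in p_days])
                conception_day = int(
                    p_days[rng.choice(len(p_days), p=weights / weights.sum())][0]
                )
                # lengthened post-peak phase: couple keeps charting past the
                # expected menses until pregnancy is recognized
                new_len = max(length, peak + cfg.pregnant_postpeak_days)
                for d in range(length + 1, new_len + 1):
                    days.append(
                        DayRecord(
                            couple_id=couple_id,
                            cycle_index=cycle_index,
                            day_of_cycle=d,
                            bleeding="none",
                            discharge="dry",
                            observation_frequency="AD",
                            intercourse=False,
                        )
                    )
                length = new_len

            # source completeness: some cycles lose their chart, SOC, or both
            u = rng.random()
            if u < cfg.soc_and_chart_missing_prob:
                chart_kept, soc_kept_possible = False, False
            elif u < cfg.soc_and_chart_missing_prob + cfg.chart_missing_prob:
                chart_kept, soc_kept_possible = False, True
            else:
                chart_kept, soc_kept_possible = True, True

            # SOC responses: truth intention, discordance shifts one partner
            # one step less achieving so the most-achieving rule recovers truth
            f_level, m_level = intention, intention
            if rng.random() < cfg.partner_discordance_prob:
                shifted = _LEVELS[max(0, intention.value - 1)]
                if rng.random() < 0.5:
                    f_level = shifted
                else:
                    m_level = shifted
            got_any_soc = False
            if soc_kept_possible:
                for partner, level, miss_p in (
                    ("F", f_level, cfg.soc_nonresponse_f),
                    ("M", m_level, cfg.soc_nonresponse_m),
                ):
                    if rng.random() < miss_p:
                        continue
                    if rng.random() < cfg.soc_late_prob:
                        completion = int(12 + rng.integers(0, 15))
                    else:
                        completion = int(np.clip(1 + rng.poisson(cfg.soc_mean_day - 1), 1, 11))
                    methods = set()
                    if cycle_index > 1 and truth_rows and truth_rows[-1]["couple_id"] == couple_id:
                        if truth_rows[-1]["barrier"] and rng.random() < 0.8:
                            methods.add("condom" if rng.random() < 0.7 else "withdrawal")
                    got_any_soc = True
                    soc.append(
                        SOCResponse(
                            couple_id=couple_id,
                            cycle_index=cycle_index,
                            partner=partner,
                            completion_day=completion,
                            intention=level,
                            prior_cycle_methods=frozenset(methods),
                        )
                    )

            if chart_kept:
                source = CycleSource.CHART_AND_SOC if got_any_soc else CycleSource.CHART_ONLY
                cycle = CoupleCycle(
                    couple_id=couple_id,
                    cycle_index=cycle_index,
                    length_days=length,
                    days=tuple(days),
                    start_date=day_cursor,
                    source=source,
                    pregnancy_in_cycle=conceived,
                    nonstandard_chart=bool(rng.random() < cfg.nonstandard_chart_prob),
                )
                cycle.peak_day = identify_peak(cycle).day
                day_records.extend(days)
            else:
                source = CycleSource.SOC_ONLY if got_any_soc else CycleSource.IMPUTED
                cycle = CoupleCycle(
                    couple_id=couple_id,
                    cycle_index=cycle_index,
                    length_days=length,
                    days=(),
                    start_date=day_cursor,
                    source=source,
                    pregnancy_in_cycle=conceived,
                )
            cycles.append(cycle)

            # teacher follow-up assessment near the cycle end
            ok = cfg.assessment_ok_prob
            assessments.append(
                TeacherAssessment(
                    couple_id=couple_id,
                    cycle_index=cycle_index,
                    consistent_observations=bool(rng.random() < ok),
                    peak_id_ok=bool(rng.random() < ok),
                    accurate_charting=bool(rng.random() < ok),
                )
            )

            n_true_fertile = window_hi - window_lo + 1
            truth_rows.append(
                {
                    "couple_id": couple_id,
                    "cycle_index": cycle_index,
                    "ordinal": cycle_index,
                    "start_day": day_cursor,
                    "length": length,
                    "ovulation_day": ovulation,
                    "peak_day_chart": chart_cycle.peak_day,
                    "true_window_lo": window_lo,
                    "true_window_hi": window_hi,
                    "n_true_fertile_days": n_true_fertile,
                    "intention": intention.token,
                    "barrier": barrier,
                    "true_conception_prob": p_cycle,
                    "conceived": conceived,
                    "conception_day": conception_day,
                    "chart_kept": chart_kept,
                }
            )

            if conceived:
                exit_reason = "pregnancy"
                pregnancy_day = day_cursor + conception_day
                exit_day = min(day_cursor + length, cfg.max_followup_days)
                if chart_kept:
                    evaluations.append(
                        _build_evaluation(
                            rng, couple_id, cycle_index, cycle,
                            classify_days(cycle, rules), barrier,
                            (window_lo, window_hi), cfg,
                        )
                    )
                else:
                    evaluations.append(
                        PregnancyEvaluation(
                            couple_id=couple_id,
                            cycle_index=cycle_index,
                            evaluation_done=False,
                            info_sufficient=False,
                        )
                    )
                day_cursor += length
                break

            day_cursor += length
            p_drop = 1.0 - (1.0 - cfg.monthly_dropout_hazard) ** (length / 30.44)
            if rng.random() < p_drop:
                exit_reason = "lost" if rng.random() < 0.5 else "stopped"
                exit_day = min(day_cursor, cfg.max_followup_days)
                break
        else:
            exit_day = cfg.max_followup_days
        if exit_reason == "completed_year":
            exit_day = cfg.max_followup_days

        timeline_rows.append(
            {
                "couple_id": couple_id,
                "analytic_start": 0,
                "exit_day": int(exit_day),
                "exit_reason": exit_reason,
                "pregnancy_day": (
                    int(pregnancy_day) if pregnancy_day is not None else None
                ),
                "n_cycles": cycle_index,
            }
        )

    return SimCohort(
        config=cfg,
        cycles=cycles,
        day_records=day_records,
        soc_responses=soc,
        fidelity=fidelity,
        assessments=assessments,
        evaluations=evaluations,
        baselines=pd.DataFrame(baseline_rows),
        truth=pd.DataFrame(truth_rows),
        timelines=pd.DataFrame(timeline_rows),
    )


def ground_truth_report(cohort: SimCohort, max_ordinal: int = 13) -> dict:
    """Exact generator truth for parameter-recovery assertions.

    True CP(k) per life-table intention stratum is computed from the stored
    per-cycle conception probabilities: at each ordinal the expected hazard
    is the mean true conception probability among that stratum's at-risk
    cycles, and CP is the complement of the product of survivals.
    """
    from .intentions import collapse_intentions

    truth = cohort.truth.copy()
    truth["stratum"] = [
        collapse_intentions(IntentionLevel[t], "lifetable") for t in truth["intention"]
    ]
    cp: dict[str, float] = {}
    for stratum, sub in truth.groupby("stratum"):
        surv = 1.0
        for ordinal in range(1, max_ordinal + 1):
            at = sub[sub["ordinal"] == ordinal]
            if len(at) == 0:
                continue
            surv *= 1.0 - float(at["true_conception_prob"].mean())
        cp[stratum] = 1.0 - surv

    charted = truth[truth["chart_kept"]]
    n_days = int(charted["length"].sum())
    n_true_fertile = int(charted["n_true_fertile_days"].sum())
    return {
        "true_cp": cp,
        "n_cycles": int(len(truth)),
        "n_pregnancies": int(truth["conceived"].sum()),
        "n_charted_days": n_days,
        "n_true_fertile_days": n_true_fertile,
    }


def write_cohort(cohort: SimCohort, outdir) -> dict[str, Path]:
    """Emit all four input streams in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "charts": outdir / "charts.tsv",
        "soc": outdir / "soc.tsv",
        "baselines": outdir / "baselines.tsv",
        "evaluations": outdir / "evaluations.tsv",
        "fidelity": outdir / "fidelity.tsv",
        "assessments": outdir / "assessments.tsv",
        "config": outdir / "scenario.yaml",
    }
    write_chart_file(cohort.day_records, paths["charts"])
    write_soc_file(cohort.soc_responses, paths["soc"])
    write_evaluation_file(cohort.evaluations, paths["evaluations"])
    cohort.baselines.to_csv(paths["baselines"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"couple_id": f.couple_id, "partner": f.partner, "exit_answer": f.exit_answer.value}
            for f in cohort.fidelity
        ]
    ).to_csv(paths["fidelity"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "couple_id": a.couple_id,
                "cycle_index": a.cycle_index,
                "consistent_observations": int(a.consistent_observations),
                "peak_id_ok": int(a.peak_id_ok),
                "accurate_charting": int(a.accurate_charting),
            }
            for a in cohort.assessments
        ]
    ).to_csv(paths["assessments"], sep="\t", index=False)
    cohort.config.to_yaml(paths["config"])
    return paths
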