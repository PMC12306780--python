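"""Rule engine assigning method pregnancy classifications.

Encodes the published outcome logic of the standard Creighton Model
pregnancy classification as explicit precedence rules over structured
evaluation findings. Precedence (first match wins for the primary
category):

1. barrier/withdrawal on fertile days            -> NON_CRMS
2. insufficient information                      -> UNRESOLVED
3. fertile-day intercourse or achieving behavior -> ACHIEVING
4. end-of-day-ambiguous conception only          -> UNRESOLVED
5. use errors (misinterpretation, missed double
   peak, multiple charting errors)               -> USING
6. contributory teaching deficiency              -> TEACHING
   (USING + TEACHING together collapse to USING_TEACHING)
7. all instructions followed, conception from
   outside the identified window                 -> METHOD
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "CrMSCategory",
    "PregnancyEvaluation",
    "Classification",
    "EvaluationError",
    "classify_pregnancy",
    "classification_summary",
    "read_evaluation_file",
    "write_evaluation_file",
]


class EvaluationError(ValueError):
    pass


class CrMSCategory(str, enum.Enum):
    ACHIEVING = "ACHIEVING"
    METHOD = "METHOD"
    USING = "USING"
    TEACHING = "TEACHING"
    USING_TEACHING = "USING_TEACHING"
    UNRESOLVED = "UNRESOLVED"
    NON_CRMS = "NON_CRMS"


TEACHING_DEFICIENCIES = frozenset(
    {
        "followup_schedule",
        "uncorrected_charting",
        "advanced_too_fast",
        "unclear_instructions",
        "yellow_stamp_protocol",
        "incomplete_documentation",
    }
)

ACHIEVING_BEHAVIORS = frozenset(
    {
        "negotiated_down",
        "special_occasion",
        "taking_chance",
        "actively_trying",
        "missed_observations_knowing",
        "inaccurate_charting_knowing",
    }
)

FERTILE_DAY_TYPES = frozenset({"peak_type_or_count3", "other_fertile", "none", "unknown"})
CHARTING_ERROR_LEVELS = frozenset({"none", "user_error", "multiple_significant"})


@dataclass(frozen=True)
class PregnancyEvaluation:
    """Structured findings from a pregnancy review."""

    couple_id: str
    cycle_index: int
    evaluation_done: bool = True
    intercourse_on_known_fertile: Optional[bool] = None
    fertile_day_type: str = "unknown"
    end_of_day_ambiguous: bool = False
    charting_errors: str = "none"
    misinterpretation: bool = False
    double_peak_missed: bool = False
    teaching_deficiencies: frozenset[str] = frozenset()
    achieving_behaviors: frozenset[str] = frozenset()
    barrier_or_withdrawal_on_fertile: Optional[bool] = None
    info_sufficient: bool = True
    external_documentation: bool = False

    def __post_init__(self) -> None:
        if self.fertile_day_type not in FERTILE_DAY_TYPES:
            raise EvaluationError(f"invalid fertile_day_type: {self.fertile_day_type!r}")
        if self.charting_errors not in CHARTING_ERROR_LEVELS:
            raise EvaluationError(f"invalid charting_errors: {self.charting_errors!r}")
        bad = set(self.teaching_deficiencies) - TEACHING_DEFICIENCIES
        if bad:
            raise EvaluationError(f"unknown teaching deficiencies: {sorted(bad)}")
        bad = set(self.achieving_behaviors) - ACHIEVING_BEHAVIORS
        if bad:
            raise EvaluationError(f"unknown achieving behaviors: {sorted(bad)}")
        if self.intercourse_on_known_fertile is False and self.fertile_day_type in (
            "peak_type_or_count3",
            "other_fertile",
        ):
            raise EvaluationError(
                "inconsistent evaluation: no fertile intercourse but fertile_day_type set"
            )
        if not self.evaluation_done and self.info_sufficient and not self.external_documentation:
            raise EvaluationError(
                "inconsistent evaluation: info_sufficient without evaluation or "
                "external documentation"
            )


@dataclass(frozen=True)
class Classification:
    category: CrMSCategory
    reasons: tuple[str, ...]


def classify_pregnancy(e: PregnancyEvaluation) -> Classification:
    """Assign the single primary category and its reason codes."""
    reasons: list[str] = []

    if e.barrier_or_withdrawal_on_fertile is True:
        reasons.append("barrier_or_withdrawal_on_fertile_days")
        return Classification(CrMSCategory.NON_CRMS, tuple(reasons))

    if not e.info_sufficient:
        if not e.evaluation_done:
            reasons.append("no_evaluation_insufficient_information")
        else:
            reasons.append("insufficient_information")
        return Classification(CrMSCategory.UNRESOLVED, tuple(reasons))

    achieving = False
    if e.intercourse_on_known_fertile is True:
        achieving = True
        if e.fertile_day_type == "peak_type_or_count3":
            reasons.append("intercourse_fertile_peak_type_or_count3")
        elif e.fertile_day_type == "other_fertile":
            reasons.append("intercourse_fertile_other_type")
        else:
            reasons.append("intercourse_fertile_no_day_details")
    if e.achieving_behaviors:
        # acknowledged achieving behavior is itself achieving-related
        achieving = True
        if e.end_of_day_ambiguous:
            reasons.append("intercourse_before_end_of_day")
        reasons.extend(sorted(f"behavior_{b}" for b in e.achieving_behaviors))
    if achieving:
        return Classification(CrMSCategory.ACHIEVING, tuple(reasons))

    if e.end_of_day_ambiguous:
        # e.g. unknown whether Peak+4 intercourse was end of day
        reasons.append("end_of_day_timing_unknown")
        return Classification(CrMSCategory.UNRESOLVED, tuple(reasons))

    using = False
    if e.misinterpretation:
        using = True
        reasons.append("misinterpreted_fertile_day_as_nonfertile")
    if e.double_peak_missed:
        using = True
        reasons.append("did_not_recognize_double_peak")
    if e.charting_errors == "multiple_significant":
        using = True
        reasons.append("multiple_significant_charting_errors")

    teaching = bool(e.teaching_deficiencies)
    if teaching:
        reasons.extend(sorted(f"teaching_{t}" for t in e.teaching_deficiencies))

    if using and teaching:
        return Classification(CrMSCategory.USING_TEACHING, tuple(reasons))
    if using:
        return Classification(CrMSCategory.USING, tuple(reasons))
    if teaching:
        return Classification(CrMSCategory.TEACHING, tuple(reasons))

    reasons.append("conception_outside_identified_fertile_window")
    return Classification(CrMSCategory.METHOD, tuple(reasons))


def classification_summary(
    pregnancies: Iterable[PregnancyEvaluation],
) -> tuple[pd.Series, pd.DataFrame]:
    """Counts per category and reason-code frequencies.

    USING_TEACHING pregnancies are echoed once in each of the using and
    teaching reason families (a pregnancy may carry several reasons).
    """
    counts = {c.value: 0 for c in CrMSCategory}
    reason_rows: list[dict] = []
    for e in pregnancies:
        cls = classify_pregnancy(e)
        counts[cls.category.value] += 1
        for r in cls.reasons:
            reason_rows.append({"category": cls.category.value, "reason": r})
    counts_series = pd.Series(counts, name="n_pregnancies")
    if reason_rows:
        freq = (
            pd.DataFrame(reason_rows)
            .value_counts(["category", "reason"])
            .rename("frequency")
            .reset_index()
            .sort_values(["category", "reason"], ignore_index=True)
        )
    else:
        freq = pd.DataFrame(columns=["category", "reason", "frequency"])
    return counts_series, freq


# ---------------------------------------------------------------------------
# Evaluation file I/O (tab-delimited)

_BOOL_FIELDS = {
    "evaluation_done",
    "end_of_day_ambiguous",
    "misinterpretation",
    "double_peak_missed",
    "info_sufficient",
    "external_documentation",
}
_OPT_BOOL_FIELDS = {"intercourse_on_known_fertile", "barrier_or_withdrawal_on_fertile"}
_SET_FIELDS = {"teaching_deficiencies", "achieving_behaviors"}

EVALUATION_COLUMNS = [f.name for f in fields(PregnancyEvaluation)]


def _ser(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, frozenset):
        return ";".join(sorted(value)) or "."
    return str(value)


def write_evaluation_file(evaluations: Iterable[PregnancyEvaluation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVALUATION_COLUMNS)
        for e in evaluations:
            writer.writerow([_ser(getattr(e, c)) for c in EVALUATION_COLUMNS])


def read_evaluation_file(path) -> list[PregnancyEvaluation]:
    out: list[PregnancyEvaluation] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != EVALUATION_COLUMNS:
            raise EvaluationError(f"{path}: bad or missing header: {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            kwargs = {}
            for col, token in zip(EVALUATION_COLUMNS, row):
                if col == "couple_id":
                    kwargs[col] = token
                elif col == "cycle_index":
                    kwargs[col] = int(token)
                elif col in _BOOL_FIELDS:
                    kwargs[col] = token == "1"
                elif col in _OPT_BOOL_FIELDS:
                    kwargs[col] = None if token == "." else token == "1"
                elif col in _SET_FIELDS:
                    kwargs[col] = frozenset() if token == "." else frozenset(token.split(";"))
                else:
                    kwargs[col] = token
            try:
                out.append(PregnancyEvaluation(**kwargs))
            except EvaluationError as exc:
                raise EvaluationError(f"{path}:{lineno}: {exc}") from exc
    return out
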