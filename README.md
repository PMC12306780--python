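# crmkit

Analysis toolkit for Creighton Model FertilityCare System (CrMS) cohort
data: daily fertility-chart classification, cycle-intention reconciliation
and concordance, intention-by-behavior tables, correct-use cascades,
single- and multiple-decrement pregnancy life tables, a rule engine for
CrMS pregnancy classification, and a seeded synthetic cohort generator
with known ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `crmkit.chart_core` | Chart data model; day-level FERTILE / NON_FERTILE / UNKNOWN classifier driven by a configurable `RuleTable`; peak-day identification (with double-peak annotation); cycle-length imputation; pregnancy surveillance flag. |
| `crmkit.intentions` | Six-level start-of-cycle intention scale; "most achieving" couple reconciliation; prospective-window filter; collapse schemes; 4×4 concordance table. |
| `crmkit.behavior_tables` | Cycle-level fertile-intercourse metrics; intention × behavior cross-tab; condom/withdrawal cycle flagging (union of partner reports shifted to the prior cycle, plus chart annotations). |
| `crmkit.correct_use` | Recording-fidelity eligibility; three-level evidence cascade (L3 ⊆ L2 ⊆ L1); five correct-use categories (two to conceive, three to avoid); teacher-assessment-to-cycle mapping. |
| `crmkit.lifetables` | Single-decrement cumulative pregnancy probabilities over ordinal cycles with a 2×2 sensitivity grid; multiple-decrement ordinal-month net rates on a shared all-use denominator; couple timelines. |
| `crmkit.pregnancy_classifier` | Deterministic precedence rules assigning ACHIEVING / METHOD / USING / TEACHING / USING_TEACHING / UNRESOLVED / NON_CRMS with reason codes. |
| `crmkit.synthetic_cohort` | Seeded generator of all four input streams (charts, questionnaires, baselines, pregnancy evaluations) plus exact ground truth. |
| `crmkit.pipeline` / `crmkit.cli` | End-to-end orchestration and the `crmkit` command-line interface. |

## CLI

```bash
# generate a synthetic cohort (defaults to the shipped paper-like scenario)
crmkit simulate --seed 7 --n-couples 100 --out scratch/cohort

# classify every charted day
crmkit classify-days --charts scratch/cohort/charts.tsv --out scratch/days.tsv

# intention concordance table
crmkit tabulate-intentions --soc scratch/cohort/soc.tsv --out scratch/conc.tsv

# the full report bundle (sources, concordance, behavior, life tables,
# correct use, pregnancy classification, reasons, results.json)
crmkit report-all --inputs scratch/cohort --out scratch/reports
```

All inputs and outputs are plain tab-delimited text (missing values
written as `.`); rule tables and simulation scenarios are versioned YAML
(`src/crmkit/data/`).

## Notes

- Day-classification rules are data (`RuleTable`), not code; the shipped
  default reconstructs standard published CrMS instructions (menses and
  mucus days fertile, count-of-three after a mucus patch, Peak+1..+3
  fertile, Peak+4 end-of-day-only, pre-peak dry days end-of-day-only).
- Intercourse without a recorded end-of-day time on end-of-day-only
  non-fertile days is "timing-ambiguous"; the strict flag (default)
  excludes such cycles from avoid-type correct use.
- The multiple-decrement table shares one all-use month denominator for
  every cause, so per-cause net rates plus continuation sum to 1 exactly;
  couples with non-CrMS pregnancies are removed entirely.
- Censoring exits at the end of the last complete ordinal unit by
  default; the Potter half-unit correction is available behind a flag.
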