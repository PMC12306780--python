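# Default "paper-like" scenario: a ~300-couple cohort followed up to one
# year, mostly avoiding pregnancy, with leakage of intercourse onto fertile
# days, late/missing questionnaires, barrier cycles, and dropout.
scenario: paper_like
n_couples: 296
seed: 0
cycle_length_mean: 29.0
cycle_length_sd: 3.0
cycle_length_min: 21
cycle_length_max: 42
luteal_length_mean: 13.0
luteal_length_sd: 1.5
mucus_buildup_days: 5
missing_observation_rate: 0.05
intention_mix:
  TRYING_HARD_CONCEIVE: 0.02
  CONCEIVE: 0.04
  NEUTRAL: 0.05
  AVOID: 0.46
  TRYING_HARD_AVOID: 0.33
  ABSTAIN: 0.10
intention_stay_prob: 0.85
fecundability: [0.03, 0.07, 0.12, 0.20, 0.26, 0.30, 0.10]
barrier_cycle_prob: 0.06
barrier_attenuation: 0.2
soc_mean_day: 4.0
soc_late_prob: 0.08
soc_nonresponse_f: 0.12
soc_nonresponse_m: 0.22
partner_discordance_prob: 0.08
chart_missing_prob: 0.08
soc_and_chart_missing_prob: 0.04
assessment_ok_prob: 0.8
nonstandard_chart_prob: 0.02
eval_missing_prob: 0.12
monthly_dropout_hazard: 0.025
max_followup_days: 365
pregnant_postpeak_days: 20
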