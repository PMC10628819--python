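# Synthetic-cohort configuration emulating the prospective validation dataset:
# 111 paired tests; no missing ACTH was reported there.
n_pairs: 111
seed: 0
correlation: 0.7
outcome_noise_sd: 73.4
acth_missing_rate: 0.0
start_date: "2021-10-01"
window_days: 365
marginals:
  prev_baseline_cortisol: {mean: 148.6, sd: 112.7, lower: 3.0, upper: 471.0}
  prev_baseline_acth: {mean: 29.9, sd: 37.2, lower: 1.0, upper: 276.0}
  prev_cortisol_30: {mean: 311.0, sd: 195.9, lower: 25.0, upper: 808.0}
  days_between: {mean: 483.0, sd: 280.0, lower: 86.0, upper: 1582.0}
  new_baseline_cortisol: {mean: 170.4, sd: 121.1, lower: 3.0, upper: 516.0}
  new_baseline_acth: {mean: 25.7, sd: 29.7, lower: 3.0, upper: 232.0}
group_proportions:
  sex: {male: 0.4054054, female: 0.5945946}                      # 45 / 66 of 111
  ai_type: {sufficient: 0.2882883, primary: 0.0090090, secondary: 0.1081081, tertiary: 0.5945946}
  steroid_route: {oral: 0.4234234, inhaler: 0.0090090, both: 0.3153153, none: 0.2522523}
  steroid_formulation: {hydrocortisone: 0.3063063, prednisolone: 0.0990991, both: 0.0180180, none: 0.5765766}
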