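# Default synthetic-cohort configuration emulating the development dataset:
# 258 paired tests; marginal mean/SD/range per candidate variable; subgroup
# proportions from the reported patient counts (n = 175 patients).
n_pairs: 258
seed: 0
correlation: 0.7
outcome_noise_sd: 73.4        # development RMSE of the generating model, nmol/L
acth_missing_rate: 0.0813953  # 21 / 258
start_date: "2016-08-01"
window_days: 1826
marginals:
  prev_baseline_cortisol: {mean: 186.0, sd: 109.9, lower: 2.0, upper: 664.0}
  prev_baseline_acth: {mean: 27.6, sd: 22.7, lower: 2.0, upper: 213.0}
  prev_cortisol_30: {mean: 360.4, sd: 177.2, lower: 12.0, upper: 826.0}
  days_between: {mean: 318.0, sd: 249.0, lower: 18.0, upper: 1379.0}
  new_baseline_cortisol: {mean: 205.6, sd: 131.3, lower: 2.0, upper: 836.0}
  new_baseline_acth: {mean: 28.5, sd: 27.5, lower: 1.0, upper: 276.0}
group_proportions:
  sex: {male: 0.4457143, female: 0.5542857}                      # 78 / 97 of 175
  ai_type: {sufficient: 0.0457143, primary: 0.0285714, secondary: 0.3028571, tertiary: 0.6228571}
  steroid_route: {oral: 0.3485714, inhaler: 0.0914286, both: 0.2685714, none: 0.2914286}
  steroid_formulation: {hydrocortisone: 0.32, prednisolone: 0.2971429, none: 0.3828571}
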