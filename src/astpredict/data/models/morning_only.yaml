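# Morning-cortisol-only model (fixed, parameter-wise shrunken coefficients).
# 30-minute cortisol = -54.476 + 325.134 * sqrt(new baseline cortisol / 100)
name: morning_only
intercept: -54.476
residual_sd: 110.3
pass_threshold: 430.0
terms:
  - variable: new_baseline_cortisol
    scale_divisor: 100.0
    power: 0.5
    coefficient: 325.134
    shrinkage_factor: 0.9987
    standard_error: 10.480
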