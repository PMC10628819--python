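# Previous-AST model (fixed, parameter-wise shrunken coefficients).
# 30-minute cortisol = -116.5 + 251.5 * sqrt(new baseline cortisol / 100)
#                      - 49.4 * (previous baseline cortisol / 100)
#                      + 714.3 * (previous 30-minute cortisol / 1000)
name: previous_ast
intercept: -116.5
residual_sd: 73.4
pass_threshold: 430.0
terms:
  - variable: new_baseline_cortisol
    scale_divisor: 100.0
    power: 0.5
    coefficient: 251.5
    shrinkage_factor: 0.997
    standard_error: 15.34
  - variable: prev_baseline_cortisol
    scale_divisor: 100.0
    power: 1.0
    coefficient: -49.4
    shrinkage_factor: 0.976
    standard_error: 7.11
  - variable: prev_cortisol_30
    scale_divisor: 1000.0
    power: 1.0
    coefficient: 714.3
    shrinkage_factor: 0.993
    standard_error: 48.51
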