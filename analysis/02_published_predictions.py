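"""Apply the two published models: worked examples and batch predictions.

Prints the worked-example predictions (the previous-AST model at new baseline
133 nmol/L under two previous-test contexts) and the baseline cortisol at
which the morning-only model predicts exactly the 430 nmol/L pass threshold,
then appends prediction columns to both cohort tables from step 01.
"""

import argparse
from pathlib import Path

from astpredict import (
    invert_single_covariate,
    predict,
    predict_frame,
    prepare_analysis_frame,
    published_models,
    read_cohort,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    models = published_models()
    prev, morning = models["previous_ast"], models["morning_only"]

    for prev_base, prev_30 in [(100, 200), (200, 400)]:
        p = predict(prev, {
            "new_baseline_cortisol": 133,
            "prev_baseline_cortisol": prev_base,
            "prev_cortisol_30": prev_30,
        })
        print(f"new baseline 133, previous ({prev_base}, {prev_30}) -> "
              f"predicted 30-min cortisol {p.point_display:.0f} nmol/L, "
              f"P(pass) = {p.pass_probability:.3f}")

    x = invert_single_covariate(morning, 430.0, "new_baseline_cortisol")
    print(f"morning-only model predicts exactly 430 nmol/L at baseline {x:.1f} nmol/L")

    for name in ("cohort_development", "cohort_validation"):
        frame = prepare_analysis_frame(read_cohort(RESULTS / f"{name}.csv"))
        out = predict_frame(prev, frame, prefix="prev_ast_")
        out = predict_frame(morning, out, prefix="morning_")
        out.to_csv(RESULTS / f"{name}_predictions.csv", index=False)
        print(f"wrote {name}_predictions.csv ({len(out)} rows)")


if __name__ == "__main__":
    main()
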