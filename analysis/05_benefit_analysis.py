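"""Quantify tests saved under the equivocal-range policy.

For each published model on the synthetic validation cohort: find the
prediction thresholds attaining 95% sensitivity (low) and 95% specificity
(high), report the equivocal range and the proportion of stimulation tests
the policy would save, and write a benefit curve over a grid of targets.
"""

import argparse
import json
from pathlib import Path

from astpredict import (
    benefit_curve,
    predict_frame,
    prepare_analysis_frame,
    published_models,
    read_cohort,
    two_threshold_policy,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
TARGETS = [0.80, 0.85, 0.90, 0.95, 0.99]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    frame = prepare_analysis_frame(read_cohort(RESULTS / "cohort_validation.csv"))
    y = frame["new_cortisol_30"].to_numpy()

    payload = {}
    for name, model in published_models().items():
        p = predict_frame(model, frame)["pred_point"].to_numpy()
        policy = two_threshold_policy(y, p, 0.95, 0.95, model.pass_threshold)
        payload[name] = {
            "low_threshold": policy.low_threshold,
            "high_threshold": policy.high_threshold,
            "attained_sensitivity": policy.sensitivity,
            "attained_specificity": policy.specificity,
            "proportion_saved": policy.proportion_saved,
        }
        print(f"{name}: equivocal range {policy.low_threshold:.0f} to "
              f"{policy.high_threshold:.0f} nmol/L -> saves "
              f"{policy.proportion_saved:.1%} of tests "
              f"(sens {policy.sensitivity:.2f}, spec {policy.specificity:.2f})")
        benefit_curve(y, p, TARGETS, TARGETS, model.pass_threshold).to_csv(
            RESULTS / f"benefit_curve_{name}.csv", index=False
        )

    (RESULTS / "benefit_policies.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print("wrote benefit_policies.json and benefit curves")


if __name__ == "__main__":
    main()
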