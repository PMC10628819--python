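"""Evaluate both published models on the synthetic cohorts.

Computes calibration (R^2, RMSE, slope, intercept) and discrimination (AUC at
the 430 nmol/L pass threshold) with percentile-bootstrap 95% CIs on the
development and validation cohorts from step 01, compares the two models by
the likelihood-ratio test, and runs leave-one-group-out cross-validation over
sex on the development cohort.
"""

import argparse
import json
from pathlib import Path

from astpredict import (
    CANDIDATES_NO_ACTH,
    DevelopmentConfig,
    compare_models,
    cross_validate_groups,
    performance_report,
    predict_frame,
    prepare_analysis_frame,
    published_models,
    read_cohort,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=3)
    parser.add_argument("--n-boot", type=int, default=1000)
    args = parser.parse_args()

    models = published_models()
    payload = {}
    for cohort_name in ("cohort_development", "cohort_validation"):
        frame = prepare_analysis_frame(read_cohort(RESULTS / f"{cohort_name}.csv"))
        frame = predict_frame(models["previous_ast"], frame, prefix="prev_ast_")
        frame = predict_frame(models["morning_only"], frame, prefix="morning_")
        y = frame["new_cortisol_30"]
        block = {}
        for model_name in ("previous_ast", "morning_only"):
            rep = performance_report(
                y, frame[f"{'prev_ast' if model_name == 'previous_ast' else 'morning'}_point"],
                n_boot=args.n_boot, seed=args.seed,
            )
            block[model_name] = rep.to_dict()
            print(f"{cohort_name} / {model_name}: R^2 {rep.r2:.3f} "
                  f"({rep.r2_ci[0]:.3f}-{rep.r2_ci[1]:.3f}), RMSE {rep.rmse:.1f}, "
                  f"slope {rep.calibration_slope:.2f}, AUC {rep.auc:.3f}")
        lr = compare_models(y, frame["morning_point"], frame["prev_ast_point"],
                            params_a=2, params_b=4)
        block["likelihood_ratio"] = {
            "statistic": lr.statistic, "df": lr.df, "p": lr.pvalue, "delta_r2": lr.delta_r2,
        }
        print(f"{cohort_name}: LR chi^2 = {lr.statistic:.1f} (df {lr.df}), "
              f"p = {lr.pvalue:.2e}, delta R^2 = {lr.delta_r2:.2f}")
        payload[cohort_name] = block

    dev_frame = prepare_analysis_frame(read_cohort(RESULTS / "cohort_development.csv"))
    cv = cross_validate_groups(
        dev_frame, "sex",
        DevelopmentConfig(n_bootstrap=50, seed=args.seed, candidate_variables=CANDIDATES_NO_ACTH),
        n_boot=min(args.n_boot, 500),
    )
    payload["cross_validation_sex"] = cv.to_dict()
    for g, rep in cv.groups.items():
        print(f"held-out {g} (n={cv.group_sizes[g]}): R^2 {rep.r2:.3f}, AUC {rep.auc:.3f}")

    (RESULTS / "validation_report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print("wrote validation_report.json")


if __name__ == "__main__":
    main()
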