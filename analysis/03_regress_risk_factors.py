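"""Regress the composite risk score and single factors from brain patterns.

Leave-one-out support-vector regression of the FCHDR score over all
subjects, the single-factor battery (blood pressure, age, cholesterol,
smoking), and leave-one-out classification of dichotomous diabetes, all
with permutation p-values.  MSE is on the z-normalized scale, so values
near 1 mean no improvement over predicting the mean.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_config import B_PERMUTATIONS, STUDY_CONFIG, STUDY_SEED

import pandas as pd

from riskmvpa.pipeline import RunConfig, run_pipeline


def main() -> None:
    config = RunConfig(out_dir="results/regression",
                       synthetic=STUDY_CONFIG,
                       analyses=("regress-factors", "diabetes-classify"),
                       B=B_PERMUTATIONS, seed=STUDY_SEED)
    bundle = run_pipeline(config)
    table = pd.DataFrame(bundle["factor_battery"])
    print(table.to_string(index=False,
                          float_format=lambda v: f"{v:.4f}"))
    diabetes = bundle["diabetes"]
    if "skipped" not in diabetes:
        print(f"diabetes classification: accuracy {diabetes['accuracy']:.3f} "
              f"(majority rate {diabetes['majority_rate']:.3f}, "
              f"p = {diabetes['p_accuracy']:.3f})")
    print("written to results/regression/")


if __name__ == "__main__":
    main()
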