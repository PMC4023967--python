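#!/usr/bin/env python
"""Train one all-inputs network and inspect what it learned.

Trains a 20-hidden-unit network on the full cohort (all 16 clinical
features, goal 0.001), saves the model, and ranks the inputs by their
summed absolute hidden-layer weights -- the study's proxy for which
clinical measures carry the mapping.
"""

import argparse
import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from gaitbalance.cohort import CohortParams, OUTCOME_NAMES, generate_cohort_frame  # noqa: E402
from gaitbalance.network import NetworkConfig, input_importance, save_model, train_lm  # noqa: E402
from gaitbalance.pipeline import GROUPINGS, select_inputs  # noqa: E402


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--hidden", type=int, default=20)
    parser.add_argument("--goal", type=float, default=0.001)
    parser.add_argument("--outdir", default="results")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    cohort = generate_cohort_frame(CohortParams(n_subjects=56, seed=args.seed))
    features = list(GROUPINGS["all"])
    X = select_inputs("all", cohort)
    Y = cohort[list(OUTCOME_NAMES)].to_numpy(float)

    cfg = NetworkConfig(n_inputs=16, n_hidden=args.hidden, n_outputs=3,
                        error_goal=args.goal, seed=args.seed)
    model, trace = train_lm(cfg, X, Y, x_columns=features,
                            y_columns=list(OUTCOME_NAMES))
    model_path = os.path.join(args.outdir, "model_all_inputs.json")
    save_model(model, model_path)

    scores, order = input_importance(model, input_names=features)
    importance = pd.DataFrame({
        "rank": range(1, 17),
        "feature": order,
        "abs_weight_sum": sorted(scores, reverse=True),
    })
    imp_path = os.path.join(args.outdir, "input_importance.csv")
    importance.to_csv(imp_path, index=False)

    print(f"trained {args.hidden}-hidden all-inputs network "
          f"(goal {args.goal}): stop={trace.stop_reason} after "
          f"{trace.epochs_used} epochs, final MSE {trace.mse[-1]:.4g}")
    print(f"model -> {model_path}")
    print(f"input ranking -> {imp_path}")
    print(importance.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
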