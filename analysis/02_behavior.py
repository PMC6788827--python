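#!/usr/bin/env python
"""Behavioral analyses: difficulty scaling and the confidence-seeking link.

From the simulated trial tables this script computes per-condition
summaries (accuracy, median RT, confidence, see-again proportion, inverse
efficiency), exports the 8-rows-per-participant frame used for mixed-model
fitting, and fits a logistic regression of see-again choices on
standardized confidence to verify the negative coupling the EEG analyses
presuppose.

Run after 01_simulate_study.py:  python analysis/02_behavior.py
"""

import json
from pathlib import Path

import pandas as pd
import statsmodels.api as sm

from confseek import behavior as bh
from confseek.study import load_trial_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    trials = load_trial_table(out / "trial_tables.csv")

    summary = bh.summarize(trials, by_participant=True)
    summary.to_csv(out / "behavior_condition_summary.csv", index=False)
    frames = [bh.export_model_frame(g)
              for _, g in trials.groupby("participant")]
    model_frame = pd.concat(frames, ignore_index=True)
    model_frame.to_csv(out / "behavior_model_frame.csv", index=False)

    group = summary.groupby(["mean_level", "var_level"])[
        ["acc_primary", "median_rt_ms", "mean_conf_z", "p_see_again"]
    ].mean().round(3)
    print("condition means (over participants):")
    print(group.to_string())

    free = trials[trials["trial_type"] == "free"]
    X = sm.add_constant(free["confidence_z"].to_numpy())
    fit = sm.Logit(free["see_again"].to_numpy(), X).fit(disp=0)
    beta, p = fit.params[1], fit.pvalues[1]
    print(f"\nlogistic see_again ~ confidence_z: beta = {beta:.3f}, "
          f"p = {p:.2e}")
    print("=> higher confidence, fewer see-again choices"
          if beta < 0 else "=> WARNING: expected negative coupling")

    (out / "behavior_confidence_seeking.json").write_text(json.dumps({
        "logit_beta_confidence": float(beta), "p_value": float(p),
        "n_free_trials": int(len(free)),
        "see_again_rate": float(free["see_again"].mean())}, indent=2) + "\n")


if __name__ == "__main__":
    main()
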