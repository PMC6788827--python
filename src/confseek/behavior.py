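"""Behavioral condition summaries and the mixed-model input frame.

Per design cell (mean level x variance level, optionally x color) this
module computes median correct-trial RT, primary and final accuracy, mean
standardized confidence (no-choice trials only, since seeing the stimulus
again changes the rating), the see-again proportion (free-choice trials
only), and the inverse efficiency score IES = median RT / p(correct) that
drives the between-block staircase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _cell_summary(cell: pd.DataFrame) -> dict:
    correct = cell[cell["primary_correct"] == 1]
    nochoice = cell[cell["trial_type"] == "no-choice"]
    free = cell[cell["trial_type"] == "free"]
    median_rt = float(correct["rt_ms"].median()) if len(correct) else np.nan
    acc = float(cell["primary_correct"].mean()) if len(cell) else np.nan
    return {
        "n_trials": len(cell),
        "median_rt_ms": median_rt,
        "acc_primary": acc,
        "acc_final": float(cell["final_correct"].mean()) if len(cell)
        else np.nan,
        "mean_conf_z": float(nochoice["confidence_z"].mean())
        if "confidence_z" in cell.columns and len(nochoice) else np.nan,
        "p_see_again": float(free["see_again"].mean()) if len(free)
        else np.nan,
        "ies": median_rt / acc if acc and len(correct) else np.nan,
    }


def summarize(trials: pd.DataFrame, by_color: bool = False,
              by_participant: bool = True) -> pd.DataFrame:
    """Condition summaries; empty cells yield NA entries."""
    keys = ["mean_level", "var_level"]
    if by_color:
        keys.append("color")
    if by_participant:
        keys = ["participant"] + keys
    rows = []
    for vals, cell in trials.groupby(keys, sort=True):
        vals = vals if isinstance(vals, tuple) else (vals,)
        rows.append(dict(zip(keys, vals)) | _cell_summary(cell))
    return pd.DataFrame(rows)


def staircase_ies(trials: pd.DataFrame) -> tuple[float, float]:
    """IES for the low-mean/low-variance and high-mean/high-variance cells
    (across all trials), the pair the staircase equates."""
    s = summarize(trials, by_participant=False).set_index(
        ["mean_level", "var_level"])
    return (float(s.loc[("low", "low"), "ies"]),
            float(s.loc[("high", "high"), "ies"]))


def export_model_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Eight rows (2 mean x 2 variance x 2 color) per participant for
    mixed-model fitting in an external statistics package.

    Difficulty-increasing dummies are included: ``mean_low`` (reference:
    high mean) and ``var_high`` (reference: low variability), so positive
    coefficients correspond to harder conditions.
    """
    frame = summarize(trials, by_color=True)
    frame["mean_low"] = (frame["mean_level"] == "low").astype(int)
    frame["var_high"] = (frame["var_level"] == "high").astype(int)
    cols = ["participant", "mean_level", "var_level", "color", "mean_low",
            "var_high", "p_see_again", "mean_conf_z", "acc_primary",
            "median_rt_ms"]
    return frame[cols].sort_values(
        ["participant", "mean_level", "var_level", "color"]
    ).reset_index(drop=True)
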