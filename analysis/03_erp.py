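#!/usr/bin/env python
"""ERP analyses at CPz: confidence and seeking contrasts, regression.

Regenerates the study EEG, forms condition-mean waveforms at electrode CPz
on correct trials (high vs low confidence from no-choice trials; see-again
vs respond from free-choice trials), runs 1-D within-subject cluster
permutation tests on the stimulus- and response-locked contrasts, and runs
the time-resolved single-trial regression (mean, variance, interaction,
confidence) with group-level sign-flip cluster statistics.

Run:  python analysis/03_erp.py [--seed 20260101]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from confseek import erp
from confseek import replication as rep
from confseek.cluster import cluster_permutation_1d
from confseek.preprocess import baseline_correct, median_split

ROOT = Path(__file__).resolve().parents[1]
ELECTRODE = "CPz"


def _contrast_waveforms(subs, contrast, alignment):
    highs, lows = [], []
    for sub in subs:
        ep = baseline_correct(sub.epochs[alignment], (-100.0, 0.0))
        tr = sub.trials
        if contrast == "confidence":
            sel = (tr["trial_type"] == "no-choice") \
                & (tr["primary_correct"] == 1)
            labels = median_split(
                tr.loc[sel, "confidence_z"].to_numpy()).label
        else:
            sel = (tr["trial_type"] == "free") \
                & (tr["primary_correct"] == 1)
            labels = np.where(tr.loc[sel, "see_again"] == 1, "low", "high")
        ep = ep.select_trials(sel.to_numpy())
        cpz = ep.channel(ELECTRODE)
        highs.append(ep.data[labels == "high", cpz].mean(axis=0))
        lows.append(ep.data[labels == "low", cpz].mean(axis=0))
        times = ep.times_ms
    return np.stack(highs), np.stack(lows), times


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20260101)
    args = ap.parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    subs = rep.simulate_replica_study(seed=args.seed, alpha1_p3=1.5)

    report = {}
    frames = []
    for contrast in ("confidence", "seeking"):
        for alignment in ("stimulus", "response"):
            high, low, times = _contrast_waveforms(subs, contrast, alignment)
            cset = cluster_permutation_1d(high, low, n_perm=1000, seed=42)
            sig = [
                {"p": c.p_value, "sign": c.sign,
                 "from_ms": float(times[c.extent[0]]),
                 "to_ms": float(times[c.extent[1]])}
                for c in cset.significant()]
            report[f"{contrast}_{alignment}"] = sig
            print(f"{contrast}, {alignment}-locked: "
                  + (", ".join(
                      f"cluster {s['from_ms']:.0f}-{s['to_ms']:.0f} ms "
                      f"(sign {s['sign']:+d}, p={s['p']:.3f})"
                      for s in sig) if sig else "no significant cluster"))
            frames.append(pd.DataFrame({
                "contrast": contrast, "alignment": alignment,
                "time_ms": times, "high": high.mean(axis=0),
                "low": low.mean(axis=0)}))
    pd.concat(frames, ignore_index=True).to_csv(
        out / "erp_waveforms.csv", index=False)

    # time-resolved regression, response-locked
    traces = []
    for sub in subs:
        ep = baseline_correct(sub.epochs["response"], (-100.0, 0.0))
        sel = (sub.trials["primary_correct"] == 1).to_numpy()
        traces.append(erp.timewise_regression(
            ep.select_trials(sel), sub.trials[sel], ELECTRODE))
    groups = erp.group_regression_clusters(traces, n_perm=1000, seed=43)
    reg_report = {}
    times = traces[0].index.to_numpy()
    for pred, cset in groups.items():
        sig = [{"p": c.p_value, "sign": c.sign,
                "from_ms": float(times[c.extent[0]]),
                "to_ms": float(times[c.extent[1]])}
               for c in cset.significant()]
        reg_report[pred] = sig
        print(f"regression ({pred}): "
              + (", ".join(f"{s['from_ms']:.0f}-{s['to_ms']:.0f} ms "
                           f"(p={s['p']:.3f})" for s in sig)
                 if sig else "no significant cluster"))
    (out / "erp_clusters.json").write_text(json.dumps(
        {"condition_contrasts": report, "timewise_regression": reg_report},
        indent=2) + "\n")


if __name__ == "__main__":
    main()
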