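#!/usr/bin/env python
"""Within-condition temporal-generalization decoding.

Trains sliding-window logistic spatial filters to decode (a) high vs low
confidence from correct no-choice trials and (b) see-again vs respond from
correct free-choice trials, on stimulus-locked (training capped at 400 ms)
and response-locked epochs, compares each true matrix against its
shuffled-label null with the 2-D cluster permutation test, and compares
peak post-response decoding against the closest-to-significance
pre-response region.

Run:  python analysis/04_decoding_within.py [--seed 20260101]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from confseek import replication as rep
from confseek.cluster import largest_uncorrected_cluster
from confseek.decoding import compare_peak_clusters

ROOT = Path(__file__).resolve().parents[1]


def _cluster_report(g):
    return [{"p": c.p_value, "sign": c.sign,
             "train_ms": [float(g.train_times_ms[c.extent[0][0]]),
                          float(g.train_times_ms[c.extent[0][1]])],
             "test_ms": [float(g.test_times_ms[c.extent[1][0]]),
                         float(g.test_times_ms[c.extent[1][1]])]}
            for c in g.significant()]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=20260101)
    args = ap.parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    subs = rep.simulate_replica_study(seed=args.seed)

    report = {}
    mats = {}
    for contrast in ("confidence", "seeking"):
        for alignment in ("stimulus", "response"):
            g = rep.decode_within_group(subs, contrast, alignment, seed=1)
            key = f"{contrast}_{alignment}"
            mats[key] = g
            sig = _cluster_report(g)
            report[key] = {"clusters": sig,
                           "grand_mean_az": float(g.true.mean()),
                           "peak_az": float(g.true.mean(axis=0).max())}
            print(f"{contrast}, {alignment}-locked: peak group Az "
                  f"{g.true.mean(axis=0).max():.3f}; "
                  + (f"{len(sig)} significant cluster(s), best p = "
                     f"{min(s['p'] for s in sig):.3f}" if sig
                     else "no significant cluster"))

    # post- vs pre-response decoding strength, matched pixel counts
    for contrast in ("confidence", "seeking"):
        pre = mats[f"{contrast}_stimulus"]
        post = mats[f"{contrast}_response"]
        ref = largest_uncorrected_cluster(pre.true, pre.null,
                                          element_p=0.01)
        if ref is None:
            print(f"{contrast}: no pre-response pixels pass the element "
                  "threshold; skipping peak comparison")
            continue
        sig_clusters = post.significant()
        cmp_px = (np.asarray(sig_clusters[0].members)
                  if sig_clusters else None)
        res = compare_peak_clusters(pre.true, np.asarray(ref.members),
                                    post.true, cmp_pixels=cmp_px)
        report[f"{contrast}_post_vs_pre"] = {
            "n_pixels": res["n_pixels"], "t": res["t"], "p": res["p"],
            "mean_az_pre": res["mean_ref"], "mean_az_post": res["mean_cmp"]}
        print(f"{contrast}: post vs pre decoding, {res['n_pixels']} px: "
              f"Az {res['mean_cmp']:.3f} vs {res['mean_ref']:.3f}, "
              f"t({res['df']}) = {res['t']:.2f}, p = {res['p']:.4f}")

    (out / "decoding_within.json").write_text(
        json.dumps(report, indent=2) + "\n")

    # grand-average matrices for inspection/plotting
    rows = []
    for key, g in mats.items():
        m = g.true.mean(axis=0)
        for i, tt in enumerate(g.train_times_ms):
            rows.append(pd.Series(m[i], index=g.test_times_ms,
                                  name=(key, float(tt))))
    pd.DataFrame(rows).to_csv(out / "decoding_within_matrices.csv")


if __name__ == "__main__":
    main()
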