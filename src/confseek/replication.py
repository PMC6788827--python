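"""Group-level decoding pipeline over a simulated study.

Convenience layer tying the simulator to the decoding chain: per subject it
selects the analysis trial set (confidence on correct no-choice trials,
information-seeking on correct free-choice trials, or the across-condition
train/test pair), baselines and artifact-screens the epochs, computes true
and shuffled-label null temporal-generalization matrices, and runs the
group 2-D cluster permutation test on their difference.

The default problem sizes here are desk-scale: 8 subjects x 5 blocks
(320 trials), 250 Hz, a 20 ms window step and tens of null/balance
iterations, so a full study analysis runs in minutes on one CPU while
retaining the statistical structure of the full-scale design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cluster import ClusterSet, cluster_permutation_2d
from .decoding import (DecodingConfig, null_tgm_across, null_tgm_within,
                       residualize, tgm_across, tgm_within)
from .epochs import EpochSet
from .preprocess import baseline_correct, median_split, reject_extreme
from .study import StudyConfig, Subject, simulate_study

SCALED_STUDY = StudyConfig(n_subjects=8, n_blocks=5, trials_per_block=64)

SCALED_DECODING = DecodingConfig(step_ms=20.0, k_folds=10, n_repeats=5,
                                 n_null_iters=20, n_balance_iters=50)

STIMULUS_TRAIN_MAX_MS = 400.0   # avoid post-response leakage on short RTs


@dataclass
class GroupDecoding:
    true: np.ndarray            # subjects x train-windows x test-windows
    null: np.ndarray
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    clusters: ClusterSet
    contrast: str
    alignment: str

    def significant(self, alpha: float = 0.05):
        return self.clusters.significant(alpha)


def _prepped(sub: Subject, alignment: str) -> EpochSet:
    ep = sub.epochs[alignment]
    baseline = (-100.0, 0.0)
    if alignment == "choice":
        # choice-locked epochs inherit the preresponse baseline; estimate it
        # from the earliest 100 ms available instead of re-baselining at 0
        baseline = (ep.times_ms[0], ep.times_ms[0] + 100.0)
    ep = baseline_correct(ep, baseline)
    ep, _ = reject_extreme(ep)
    return ep


def _confidence_set(sub: Subject, ep: EpochSet, strict_final: bool = False):
    tr = sub.trials.loc[ep.trial_index]
    sel = (tr["trial_type"] == "no-choice") & (tr["primary_correct"] == 1)
    if strict_final:
        sel &= tr["final_correct"] == 1
    ep = ep.select_trials(sel.to_numpy())
    labels = median_split(
        tr.loc[sel, "confidence_z"].to_numpy(), source="confidence")
    return ep, labels.label


def _seeking_set(sub: Subject, ep: EpochSet):
    # 'high' codes respond (declining the extra sample), the class that
    # behaves like high confidence, so across-condition transfer from a
    # confidence-trained filter lands above chance rather than below it
    tr = sub.trials.loc[ep.trial_index]
    sel = (tr["trial_type"] == "free") & (tr["primary_correct"] == 1)
    ep = ep.select_trials(sel.to_numpy())
    labels = np.where(tr.loc[sel, "see_again"] == 1, "low", "high")
    return ep, labels


def _maybe_residualize(ep: EpochSet, sub: Subject, factors):
    if factors is None:
        return ep
    return residualize(ep, sub.trials.loc[ep.trial_index], factors)


def decode_within_group(subs: list[Subject], contrast: str, alignment: str,
                        dcfg: DecodingConfig = SCALED_DECODING,
                        seed: int | None = 0, n_perm: int = 200,
                        residualize_factors=None) -> GroupDecoding:
    """Within-condition group decoding of 'confidence' or 'seeking'."""
    trues, nulls = [], []
    for i, sub in enumerate(subs):
        ep = _prepped(sub, alignment)
        ep = _maybe_residualize(ep, sub, residualize_factors)
        if contrast == "confidence":
            ep, labels = _confidence_set(sub, ep)
        elif contrast == "seeking":
            ep, labels = _seeking_set(sub, ep)
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        cfg = replace(dcfg,
                      seed=None if seed is None else seed + 1000 * i,
                      train_max_ms=STIMULUS_TRAIN_MAX_MS
                      if alignment == "stimulus" else dcfg.train_max_ms)
        true = tgm_within(ep, labels, cfg)
        null = null_tgm_within(ep, labels, cfg)
        trues.append(true.az)
        nulls.append(null.az)
    T, N = np.stack(trues), np.stack(nulls)
    clusters = cluster_permutation_2d(T, N, element_p=dcfg.element_p_2d,
                                      n_perm=n_perm, seed=seed)
    return GroupDecoding(true=T, null=N,
                         train_times_ms=true.train_times_ms,
                         test_times_ms=true.test_times_ms,
                         clusters=clusters, contrast=contrast,
                         alignment=alignment)


def decode_across_group(subs: list[Subject], alignment: str,
                        dcfg: DecodingConfig = SCALED_DECODING,
                        seed: int | None = 0, n_perm: int = 200,
                        residualize_factors=None) -> GroupDecoding:
    """Across-condition group decoding: train on high/low confidence from
    no-choice trials (correct on both decisions), test on see-again vs
    respond from free-choice correct trials."""
    trues, nulls = [], []
    for i, sub in enumerate(subs):
        ep = _prepped(sub, alignment)
        ep = _maybe_residualize(ep, sub, residualize_factors)
        ep_tr, lab_tr = _confidence_set(sub, ep, strict_final=True)
        ep_te, lab_te = _seeking_set(sub, ep)
        cfg = replace(dcfg,
                      seed=None if seed is None else seed + 1000 * i,
                      train_max_ms=STIMULUS_TRAIN_MAX_MS
                      if alignment == "stimulus" else dcfg.train_max_ms)
        true = tgm_across(ep_tr, lab_tr, ep_te, lab_te, cfg)
        null = null_tgm_across(ep_tr, lab_tr, ep_te, lab_te, cfg)
        trues.append(true.az)
        nulls.append(null.az)
    T, N = np.stack(trues), np.stack(nulls)
    clusters = cluster_permutation_2d(T, N, element_p=dcfg.element_p_2d,
                                      n_perm=n_perm, seed=seed)
    return GroupDecoding(true=T, null=N,
                         train_times_ms=true.train_times_ms,
                         test_times_ms=true.test_times_ms,
                         clusters=clusters, contrast="across",
                         alignment=alignment)


def simulate_replica_study(seed: int, alpha1_pe: float = 2.0,
                           alpha1_p3: float = 0.0,
                           alpha1_pe_difficulty: float = 0.0
                           ) -> list[Subject]:
    """Scaled study with a confidence-coupled Pe only (no stimulus-locked
    confidence component), optionally with a difficulty confound on the Pe."""
    eeg = replace(SCALED_STUDY.eeg, alpha1_pe=alpha1_pe,
                  alpha1_p3=alpha1_p3,
                  alpha1_pe_difficulty=alpha1_pe_difficulty)
    cfg = replace(SCALED_STUDY, eeg=eeg)
    return simulate_study(cfg, seed=seed)
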