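"""Epoch preprocessing and label derivation.

Baseline correction, realignment of epochs between event clocks (stimulus,
primary response, information-seeking choice) with optional retention of a
previously applied baseline, amplitude-threshold artifact rejection, block-
wise confidence z-scoring, and median splits with balanced tie handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .epochs import EpochSet

logger = logging.getLogger(__name__)

REJECT_THRESHOLD_UV = 200.0


@dataclass
class RejectionMask:
    keep: np.ndarray                 # bool per trial
    reason: np.ndarray               # 'none' | 'extreme_value'
    threshold_uv: float

    def to_frame(self, trial_index: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({"trial_index": trial_index, "keep": self.keep,
                             "reason": self.reason})


@dataclass
class SplitLabels:
    label: np.ndarray                # 'high' | 'low' per trial
    split_value: float
    source: str = "confidence"

    @property
    def is_high(self) -> np.ndarray:
        return self.label == "high"


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window_ms``."""
    lo, hi = window_ms
    if lo < epochs.times_ms[0] - 1e-9 or hi > epochs.times_ms[-1] + 1e-9:
        raise ValueError(f"baseline window {window_ms} outside epoch range "
                         f"[{epochs.times_ms[0]}, {epochs.times_ms[-1]}] ms")
    sel = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base,
                   baseline_window_ms=(float(lo), float(hi)))


def realign(epochs: EpochSet, event_offsets_ms: np.ndarray,
            new_window_ms: tuple[float, float], new_alignment: str,
            keep_baseline: bool = True) -> EpochSet:
    """Re-cut epochs on a new event clock.

    The sample at old time ``t`` appears at new time ``t - offset``; the new
    window is ``new_window_ms`` around each trial's offset.  Trials whose new
    window is not fully covered by the existing samples are dropped (and
    logged) rather than padded.  With ``keep_baseline`` the previously
    subtracted baseline is retained, matching the convention of analyzing
    response-locked activity against a prestimulus baseline.
    """
    offsets = np.asarray(event_offsets_ms, dtype=float)
    if offsets.shape != (epochs.n_trials,):
        raise ValueError("need one event offset per trial")
    if np.any(~np.isfinite(offsets)):
        raise ValueError("event offsets contain missing values")
    dt = epochs.dt_ms
    shift = offsets / dt
    if np.any(np.abs(shift - np.rint(shift)) > 1e-6):
        raise ValueError("event offsets must be multiples of the sample "
                         "interval")
    shift = np.rint(shift).astype(int)
    w0, w1 = new_window_ms
    n_win = int(round((w1 - w0) / dt)) + 1
    start_rel = int(round(w0 / dt))

    first = np.rint(epochs.times_ms[0] / dt).astype(int)
    starts = shift + start_rel - first
    ok = (starts >= 0) & (starts + n_win <= epochs.n_samples)
    if not ok.all():
        logger.info("realign to %s: dropping %d/%d trials whose window "
                    "exceeds the available samples", new_alignment,
                    int((~ok).sum()), epochs.n_trials)
    if not ok.any():
        raise ValueError("no trial's realigned window fits in the data")
    idx = np.flatnonzero(ok)
    data = np.stack([epochs.data[i, :, starts[i]:starts[i] + n_win]
                     for i in idx])
    return EpochSet(
        data=data,
        times_ms=(np.arange(n_win) + start_rel) * dt,
        channel_names=list(epochs.channel_names),
        srate_hz=epochs.srate_hz,
        alignment=new_alignment,
        trial_index=epochs.trial_index[idx],
        baseline_window_ms=epochs.baseline_window_ms if keep_baseline
        else None,
    )


def reject_extreme(epochs: EpochSet,
                   threshold_uv: float = REJECT_THRESHOLD_UV
                   ) -> tuple[EpochSet, RejectionMask]:
    """Drop trials containing any sample at or beyond ±threshold microvolts."""
    bad = np.any(np.abs(epochs.data) >= threshold_uv, axis=(1, 2))
    mask = RejectionMask(
        keep=~bad,
        reason=np.where(bad, "extreme_value", "none"),
        threshold_uv=threshold_uv,
    )
    if bad.all():
        raise ValueError("extreme-value rejection removed every trial")
    return epochs.select_trials(~bad), mask


def zscore_confidence(trials: pd.DataFrame, column: str = "confidence_abs",
                      out_column: str = "confidence_z") -> pd.DataFrame:
    """Standardize a confidence column within each participant x block.

    Uses the sample (n-1) standard deviation.  Degenerate blocks (fewer than
    two distinct ratings) get z = 0 and are flagged in
    ``<out_column>_flag``.
    """
    if column not in trials.columns:
        raise ValueError(f"{column} column required")
    out = trials.copy()
    grouped = out.groupby(["participant", "block"])[column]
    mean = grouped.transform("mean")
    sd = grouped.transform("std")          # ddof=1
    degenerate = ~(sd > 0) | sd.isna()
    z = (out[column] - mean) / sd.where(~degenerate, np.nan)
    out[out_column] = z.fillna(0.0)
    out[f"{out_column}_flag"] = np.where(degenerate, "degenerate", "ok")
    return out


def median_split(values: np.ndarray, source: str = "confidence"
                 ) -> SplitLabels:
    """Split at the sample median; ties alternate between classes.

    Values above the median are 'high', below are 'low'; values exactly at
    the median are assigned alternately, starting with whichever class is
    smaller, so the final imbalance never exceeds one.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("median split needs at least two distinct values")
    med = float(np.median(v))
    label = np.empty(v.size, dtype=object)
    label[v > med] = "high"
    label[v < med] = "low"
    ties = np.flatnonzero(v == med)
    n_high = int((v > med).sum())
    n_low = int((v < med).sum())
    for i, t in enumerate(ties):
        if n_high <= n_low:
            label[t] = "high"
            n_high += 1
        else:
            label[t] = "low"
            n_low += 1
    return SplitLabels(label=label.astype(str), split_value=med,
                       source=source)


def lowpass_for_plotting(epochs: EpochSet, cutoff_hz: float = 10.0
                         ) -> EpochSet:
    """Zero-phase 10 Hz low-pass used for waveform display only; all
    statistics run on the unfiltered data."""
    b, a = butter(4, cutoff_hz / (epochs.srate_hz / 2.0))
    return replace(epochs, data=filtfilt(b, a, epochs.data, axis=2))
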