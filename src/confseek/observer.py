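"""Stochastic observer: evidence, choices, confidence, information-seeking, RT.

The observer sees a stimulus with mean position C and element variance V and
accumulates a single Gaussian evidence sample

    e ~ Normal(C - 0.5, sigma(V)),        sigma(V) = sensitivity * sqrt(V)

so that a larger boundary distance |C - 0.5| or a smaller element variance
yields more reliable evidence.  The primary red/blue choice is sign(e);
confidence is a saturating monotone function of the evidence-to-noise ratio
|e| / sigma(V) — the observer discounts evidence drawn from a noisier
stimulus, so confidence falls with element variance just as accuracy does;
the decision to pay for an easier second look is made whenever confidence
(plus a per-participant bias and decision noise) falls below a threshold.  On see-again trials the
final decision combines the primary evidence with a fresh sample from the
easier stimulus; otherwise the final response repeats the primary one.
Response times follow a shifted log-normal whose location decreases with
evidence strength.

The task itself specifies no observer; this is the simplest generative model
that produces the behavioral structure the downstream analyses assume —
accuracy and RT lawfully scaling with difficulty, and confidence negatively
driving information-seeking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONFIDENCE_MAX, EASIER_C_SHIFT, EASIER_V_DROP


@dataclass(frozen=True)
class ObserverParams:
    sensitivity: float = 0.20        # noise scale: sigma = sensitivity*sqrt(V)
    confidence_gain: float = 0.8     # |e|/sigma -> confidence saturation rate
    confidence_noise: float = 0.25   # sd of noise added to gain*|e|/sigma
    seek_threshold: float = 28.0     # seek when noisy confidence falls below
    seek_bias_sd: float = 8.0        # between-participant bias on the threshold
    seek_noise_sd: float = 7.0       # trial-to-trial noise on the seek decision
    rt_shift_ms: float = 200.0       # log-normal shift
    rt_mu: float = 6.2               # log-normal location at zero evidence
    rt_evidence_slope: float = 5.0   # location decrease per unit |e|
    rt_sigma: float = 0.25           # log-normal scale
    rt_grid_ms: float = 4.0          # RTs snapped to the EEG sample grid
    choice_latency_mu: float = 6.65  # log of median response->choice latency
    choice_latency_sigma: float = 0.2

    def __post_init__(self) -> None:
        for name in ("sensitivity", "confidence_gain", "rt_sigma",
                     "rt_grid_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("confidence_noise", "seek_bias_sd", "seek_noise_sd",
                     "rt_shift_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def sigma(self, v: np.ndarray) -> np.ndarray:
        return self.sensitivity * np.sqrt(v)


def _confidence_from_evidence(abs_e: np.ndarray, sigma: np.ndarray,
                              params: ObserverParams,
                              rng: np.random.Generator) -> np.ndarray:
    """Noisy saturating map from evidence-to-noise ratio to the 1..50 scale."""
    snr = abs_e / np.maximum(sigma, 1e-9)
    drive = params.confidence_gain * snr
    drive = drive + params.confidence_noise * rng.standard_normal(abs_e.shape)
    conf = CONFIDENCE_MAX * np.tanh(np.maximum(drive, 0.0))
    conf = np.rint(conf).astype(int)
    return np.clip(conf, 1, CONFIDENCE_MAX)  # 0 is not a legal rating


def simulate_observer(design: pd.DataFrame, params: ObserverParams,
                      seed=None) -> pd.DataFrame:
    """Fill behavior columns of a design table.

    Adds: rt_ms, primary_correct, primary_choice, see_again (NA on
    no-choice trials), final_correct, confidence_raw, confidence_abs,
    choice_latency_ms.  Confidence z-scores are added separately by
    :func:`confseek.preprocess.zscore_confidence`.
    """
    rng = np.random.default_rng(seed)
    out = design.copy()
    n = len(out)
    c = out["c"].to_numpy(float)
    v = out["v"].to_numpy(float)
    signal = c - 0.5
    sigma = params.sigma(v)

    e = signal + sigma * rng.standard_normal(n)
    choice = np.where(e >= 0, 1, -1)            # +1 red, -1 blue
    truth = np.where(signal >= 0, 1, -1)
    primary_correct = (choice == truth).astype(int)

    # seek decision: only available on free-choice trials; driven negatively
    # by the internal confidence signal
    conf_internal = _confidence_from_evidence(np.abs(e), sigma, params, rng)
    bias = {p: params.seek_bias_sd * rng.standard_normal()
            for p in out["participant"].unique()}
    bias_arr = out["participant"].map(bias).to_numpy(float)
    seek_drive = (conf_internal + bias_arr
                  + params.seek_noise_sd * rng.standard_normal(n))
    wants_seek = seek_drive < params.seek_threshold
    is_free = (out["trial_type"] == "free").to_numpy()
    see_again = np.where(is_free, wants_seek.astype(float), np.nan)

    # final decision: resampled trials add an easier-stimulus evidence sample
    final_choice = choice.copy()
    resampled = is_free & wants_seek
    if resampled.any():
        idx = np.flatnonzero(resampled)
        c2 = c[idx] + np.where(c[idx] >= 0.5, 1.0, -1.0) * EASIER_C_SHIFT
        v2 = np.maximum(v[idx] - EASIER_V_DROP, 0.0)
        s2 = params.sigma(np.maximum(v2, 1e-6))
        e2 = (c2 - 0.5) + s2 * rng.standard_normal(len(idx))
        final_choice[idx] = np.where(e[idx] + e2 >= 0, 1, -1)
    final_correct = (final_choice == truth).astype(int)

    # the reported rating reflects the evidence behind the final decision
    final_abs_e = np.abs(e)
    if resampled.any():
        final_abs_e[idx] = np.abs(e[idx] + e2)
    conf_abs = conf_internal.copy()
    if resampled.any():
        # combined evidence e + e2 has noise sd sqrt(sigma^2 + s2^2)
        sigma_comb = np.sqrt(sigma[idx] ** 2 + s2**2)
        conf_abs[idx] = _confidence_from_evidence(final_abs_e[idx],
                                                  sigma_comb, params, rng)
    confidence_raw = final_choice * conf_abs  # sign +: sure red, -: sure blue

    rt = (params.rt_shift_ms
          + np.exp(params.rt_mu - params.rt_evidence_slope * np.abs(e)
                   + params.rt_sigma * rng.standard_normal(n)))
    rt = np.maximum(np.rint(rt / params.rt_grid_ms), 1) * params.rt_grid_ms

    latency = np.exp(params.choice_latency_mu
                     + params.choice_latency_sigma * rng.standard_normal(n))
    latency = np.maximum(np.rint(latency / params.rt_grid_ms), 1) \
        * params.rt_grid_ms

    out["rt_ms"] = rt
    out["confidence_internal"] = conf_internal  # pre-resampling confidence
    out["primary_choice"] = choice
    out["primary_correct"] = primary_correct
    out["see_again"] = see_again
    out["final_correct"] = final_correct
    out["confidence_raw"] = confidence_raw
    out["confidence_abs"] = conf_abs
    out["choice_latency_ms"] = latency
    return out
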