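"""Univariate ERP analyses at a single electrode.

Condition-mean waveforms for a binary split (confidence, or see-again vs
respond), and time-resolved single-trial regression: at every sample, the
EEG amplitude at the chosen electrode is regressed on stimulus mean level,
variance level, their interaction and binarized confidence, separately per
subject; the per-subject t traces then enter a group-level one-sample
cluster permutation test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import ClusterSet, cluster_permutation_values
from .epochs import EpochSet
from .preprocess import SplitLabels

DEFAULT_PREDICTORS = ("mean", "variance", "mean_x_variance", "confidence")


def condition_erp(epochs: EpochSet, labels: SplitLabels, electrode: str
                  ) -> dict[str, np.ndarray]:
    """Per-condition mean waveform (time,) at one electrode for one subject."""
    ch = epochs.channel(electrode)
    out: dict[str, np.ndarray] = {}
    for cond in ("high", "low"):
        sel = labels.label == cond
        if not sel.any():
            raise ValueError(f"no trials in condition {cond!r}")
        out[cond] = epochs.data[sel, ch, :].mean(axis=0)
    return out


def design_matrix(trials: pd.DataFrame,
                  predictors=DEFAULT_PREDICTORS) -> np.ndarray:
    """Intercept plus ±0.5-coded factors for the time-resolved regression.

    'confidence' is a median-split high/low code derived from confidence_z
    (or confidence_abs when z-scores are absent).
    """
    cols = [np.ones(len(trials))]
    mean_c = (trials["mean_level"] == "high").to_numpy(float) - 0.5
    var_c = (trials["var_level"] == "high").to_numpy(float) - 0.5
    for p in predictors:
        if p == "mean":
            cols.append(mean_c)
        elif p == "variance":
            cols.append(var_c)
        elif p == "mean_x_variance":
            cols.append(mean_c * var_c)
        elif p == "confidence":
            conf = trials.get("confidence_z", trials["confidence_abs"])
            conf = conf.to_numpy(float)
            cols.append((conf > np.median(conf)).astype(float) - 0.5)
        else:
            raise ValueError(f"unknown predictor {p!r}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix rank deficient for predictors "
                         f"{tuple(predictors)}")
    return X


def timewise_regression(epochs: EpochSet, trials: pd.DataFrame,
                        electrode: str,
                        predictors=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """Per-sample OLS t-values for each predictor, one subject.

    Returns a DataFrame indexed by time (ms) with one t-value column per
    predictor.
    """
    if len(trials) != epochs.n_trials:
        raise ValueError("trials table and epochs disagree on trial count")
    X = design_matrix(trials, predictors)
    n, p = X.shape
    if n <= p:
        raise ValueError("more predictors than trials")
    y = epochs.data[:, epochs.channel(electrode), :]     # trials x time
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y                             # p x time
    resid = y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    t = np.where(np.isfinite(t), t, 0.0)
    return pd.DataFrame(t[1:].T, index=epochs.times_ms,
                        columns=list(predictors))


def group_regression_clusters(traces: list[pd.DataFrame],
                              element_p: float = 0.05, n_perm: int = 1000,
                              seed=None) -> dict[str, ClusterSet]:
    """Cluster permutation of per-subject regression t traces against zero,
    separately for each predictor (sign-flip permutation across subjects)."""
    predictors = list(traces[0].columns)
    out = {}
    for j, pred in enumerate(predictors):
        stacked = np.stack([tr[pred].to_numpy() for tr in traces])
        out[pred] = cluster_permutation_values(stacked, element_p=element_p,
                                               n_perm=n_perm,
                                               seed=None if seed is None
                                               else seed + j)
    return out
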