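"""Sliding-window spatial-filter decoding and temporal generalization.

A logistic-regression spatial filter (linear derivation: one weight per
channel applied to the window-averaged signal) is trained to separate two
trial classes at each training window and evaluated — via the ROC area Az —
at every test window, yielding a train-time x test-time generalization
matrix.  Within-condition matrices use repeated stratified k-fold
cross-validation; across-condition matrices train on one contrast (high vs
low confidence, no-choice trials) and test on another (see-again vs respond,
free-choice trials) over many class-balanced subsamples.  Chance level is
estimated by rerunning the same pipeline on shuffled labels, and inference
on true-minus-null matrices uses 2-D cluster permutation
(:mod:`confseek.cluster`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_rel

from .epochs import EpochSet


@dataclass(frozen=True)
class DecodingConfig:
    window_ms: float = 106.0
    step_ms: float = 10.0
    k_folds: int = 10
    n_repeats: int = 100
    n_balance_iters: int = 1000
    n_null_iters: int = 1000
    element_p_2d: float = 0.01
    ridge_c: float = 1.0            # inverse L2 strength of the logistic fit
    train_max_ms: float | None = None  # optional cap on training-window end
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window and step must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")


@dataclass
class SpatialFilterModel:
    """Channel-weight vector projecting window-averaged EEG to a scalar."""

    weights: np.ndarray
    bias: float
    train_window: tuple[float, float] | None = None

    def project(self, features: np.ndarray) -> np.ndarray:
        """features: (..., n_channels) -> scalar component amplitude."""
        return np.asarray(features) @ self.weights + self.bias


@dataclass
class DecodingMatrix:
    az: np.ndarray                 # train-windows x test-windows
    train_times_ms: np.ndarray     # window centers
    test_times_ms: np.ndarray
    condition: str                 # 'within' | 'across'
    alignment: tuple[str, str]     # (train, test) epoch alignments

    def __post_init__(self) -> None:
        self.az = np.asarray(self.az, float)
        if self.az.shape != (len(self.train_times_ms),
                             len(self.test_times_ms)):
            raise ValueError("az shape does not match window axes")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("az", data=self.az)
            f.create_dataset("train_times_ms", data=self.train_times_ms)
            f.create_dataset("test_times_ms", data=self.test_times_ms)
            f.attrs["condition"] = self.condition
            f.attrs["alignment"] = list(self.alignment)

    @classmethod
    def load(cls, path) -> "DecodingMatrix":
        with h5py.File(path, "r") as f:
            return cls(az=f["az"][...],
                       train_times_ms=f["train_times_ms"][...],
                       test_times_ms=f["test_times_ms"][...],
                       condition=str(f.attrs["condition"]),
                       alignment=tuple(f.attrs["alignment"]))


# -- features -----------------------------------------------------------


def sliding_windows(epochs: EpochSet, cfg: DecodingConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged features.

    Returns ``(features, centers_ms)`` where features has shape
    (trials, channels, windows); each feature is the mean amplitude over a
    window of ``cfg.window_ms`` advanced in ``cfg.step_ms`` increments from
    the start of the epoch.
    """
    t = epochs.times_ms
    duration = t[-1] - t[0]
    if cfg.window_ms > duration + 1e-9:
        raise ValueError(f"window of {cfg.window_ms} ms exceeds the "
                         f"{duration} ms epoch")
    n_win = int(np.floor((duration - cfg.window_ms) / cfg.step_ms + 1e-9)) + 1
    feats = np.empty((epochs.n_trials, epochs.n_channels, n_win))
    centers = np.empty(n_win)
    for k in range(n_win):
        lo = t[0] + k * cfg.step_ms
        hi = lo + cfg.window_ms
        sel = (t >= lo - 1e-9) & (t < hi - 1e-9)   # half-open window
        feats[:, :, k] = epochs.data[:, :, sel].mean(axis=2)
        centers[k] = (lo + hi) / 2.0
    return feats, centers


def _train_window_mask(centers: np.ndarray, cfg: DecodingConfig
                       ) -> np.ndarray:
    if cfg.train_max_ms is None:
        return np.ones(centers.size, dtype=bool)
    return centers + cfg.window_ms / 2.0 <= cfg.train_max_ms + 1e-9


# -- classifier and scoring ---------------------------------------------


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "high")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return y


def _fit_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                  max_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """Ridge-penalized logistic regression by damped Newton iteration.

    Minimizes the negative log-likelihood plus ``lam/2 * ||w||^2`` (the
    intercept is not penalized).  Returns the (n_features + 1,) coefficient
    vector with the intercept last.
    """
    n, p = X.shape
    Xb = np.column_stack([X, np.ones(n)])
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, lam)
    pen[-1] = 0.0
    yf = y.astype(float)
    for _ in range(max_iter):
        eta = Xb @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = Xb.T @ (mu - yf) + pen * beta
        if np.abs(grad).max() < tol:
            break
        s = np.maximum(mu * (1.0 - mu), 1e-10)
        H = (Xb * s[:, None]).T @ Xb + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # backtracking keeps the penalized deviance non-increasing
        obj = -(yf @ eta - np.logaddexp(0.0, eta).sum()) \
            + 0.5 * (pen * beta**2).sum()
        alpha = 1.0
        for _ in range(20):
            cand = beta - alpha * step
            eta_c = Xb @ cand
            obj_c = -(yf @ eta_c - np.logaddexp(0.0, eta_c).sum()) \
                + 0.5 * (pen * cand**2).sum()
            if obj_c <= obj + 1e-12:
                break
            alpha *= 0.5
        beta = beta - alpha * step
    return beta


def train_classifier(features: np.ndarray, labels,
                     ridge_c: float = 1.0,
                     train_window: tuple[float, float] | None = None
                     ) -> SpatialFilterModel:
    """Fit the logistic spatial filter at one window.

    ``features`` is trials x channels (window-averaged amplitudes).  The
    maximum-likelihood logistic fit carries a small fixed L2 ridge
    (strength ``1/ridge_c``) so the filter stays defined on separable data;
    the fit is deterministic given its inputs.
    """
    y = _as_binary(labels)
    beta = _fit_logistic(np.asarray(features, float), y, lam=1.0 / ridge_c)
    return SpatialFilterModel(weights=beta[:-1], bias=float(beta[-1]),
                              train_window=train_window)


def az_score(projections: np.ndarray, labels) -> float:
    """Area under the ROC curve of scalar projections; ties count one half."""
    y = _as_binary(labels)
    r = rankdata(np.asarray(projections, float))
    n1, n0 = int(y.sum()), int((~y).sum())
    return float((r[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _az_columns(proj: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Az along axis 0 for every column of a (trials, ...) array."""
    flat = proj.reshape(proj.shape[0], -1)
    r = rankdata(flat, axis=0)
    n1, n0 = int(y.sum()), int((~y).sum())
    auc = (r[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return auc.reshape(proj.shape[1:])


# -- temporal generalization --------------------------------------------


def _fit_project(train_feats: np.ndarray, y_train: np.ndarray,
                 test_feats: np.ndarray, train_idx: np.ndarray,
                 ridge_c: float) -> np.ndarray:
    """Fit one filter per training window; project test trials at every
    test window.  Returns (n_test_trials, n_train_w, n_test_w)."""
    n_train_w = len(train_idx)
    out = np.empty((test_feats.shape[0], n_train_w, test_feats.shape[2]))
    for a, k in enumerate(train_idx):
        model = train_classifier(train_feats[:, :, k], y_train, ridge_c)
        out[:, a, :] = np.einsum("ncw,c->nw", test_feats, model.weights) \
            + model.bias
    return out


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    """Class-ratio-preserving random fold assignment; returns test-index
    arrays."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    return [np.array(sorted(f)) for f in folds]


def tgm_within(epochs: EpochSet, labels, cfg: DecodingConfig,
               condition: str = "within") -> DecodingMatrix:
    """Within-condition temporal generalization with repeated k-fold CV.

    For every repeat, trials are split into stratified folds; filters are
    fitted per training window on k-1 folds and held-out trials are
    projected at every test window.  Held-out projections are pooled over
    folds, scored with Az per matrix cell, and Az is averaged over repeats.
    Restrict trials (e.g. to correct responses) before calling.
    """
    y = _as_binary(labels)
    feats, centers = sliding_windows(epochs, cfg)
    train_idx = np.flatnonzero(_train_window_mask(centers, cfg))
    k = cfg.k_folds
    min_class = min(int(y.sum()), int((~y).sum()))
    if min_class < k:
        warnings.warn(f"only {min_class} trials in the smaller class; "
                      f"reducing folds from {k}", stacklevel=2)
        k = max(min_class, 2)
    rng = np.random.default_rng(cfg.seed)
    az_sum = np.zeros((len(train_idx), feats.shape[2]))
    for _ in range(cfg.n_repeats):
        pooled = np.empty((feats.shape[0], len(train_idx), feats.shape[2]))
        for test_ids in _stratified_folds(y, k, rng):
            train_mask = np.ones(len(y), dtype=bool)
            train_mask[test_ids] = False
            pooled[test_ids] = _fit_project(
                feats[train_mask], y[train_mask], feats[test_ids],
                train_idx, cfg.ridge_c)
        az_sum += _az_columns(pooled, y)
    return DecodingMatrix(az=az_sum / cfg.n_repeats,
                          train_times_ms=centers[train_idx],
                          test_times_ms=centers,
                          condition=condition,
                          alignment=(epochs.alignment, epochs.alignment))


def tgm_across(train_epochs: EpochSet, train_labels,
               test_epochs: EpochSet, test_labels,
               cfg: DecodingConfig, condition: str = "across"
               ) -> DecodingMatrix:
    """Across-condition generalization with repeated class balancing.

    Each iteration subsamples the training set to equal class counts and the
    test set to equal class counts, fits a filter per training window on the
    balanced training data, and scores the balanced test projections; Az is
    averaged over iterations.  Train and test trials must not overlap.
    """
    y_tr = _as_binary(train_labels)
    y_te = _as_binary(test_labels)
    if train_epochs.alignment == test_epochs.alignment and np.intersect1d(
            train_epochs.trial_index, test_epochs.trial_index).size:
        raise ValueError("training and test sets share trials")
    feats_tr, centers_tr = sliding_windows(train_epochs, cfg)
    feats_te, centers_te = sliding_windows(test_epochs, cfg)
    train_idx = np.flatnonzero(_train_window_mask(centers_tr, cfg))
    n_tr = min(int(y_tr.sum()), int((~y_tr).sum()))
    n_te = min(int(y_te.sum()), int((~y_te).sum()))
    if n_tr < 2 or n_te < 2:
        raise ValueError("fewer than 2 trials in a balanced class")
    rng = np.random.default_rng(cfg.seed)
    az_sum = np.zeros((len(train_idx), feats_te.shape[2]))
    for _ in range(cfg.n_balance_iters):
        sub_tr = np.concatenate([
            rng.choice(np.flatnonzero(y_tr), n_tr, replace=False),
            rng.choice(np.flatnonzero(~y_tr), n_tr, replace=False)])
        sub_te = np.concatenate([
            rng.choice(np.flatnonzero(y_te), n_te, replace=False),
            rng.choice(np.flatnonzero(~y_te), n_te, replace=False)])
        proj = _fit_project(feats_tr[sub_tr], y_tr[sub_tr],
                            feats_te[sub_te], train_idx, cfg.ridge_c)
        az_sum += _az_columns(proj, y_te[sub_te])
    return DecodingMatrix(az=az_sum / cfg.n_balance_iters,
                          train_times_ms=centers_tr[train_idx],
                          test_times_ms=centers_te,
                          condition=condition,
                          alignment=(train_epochs.alignment,
                                     test_epochs.alignment))


# -- null matrices ------------------------------------------------------


def null_tgm_within(epochs: EpochSet, labels, cfg: DecodingConfig
                    ) -> DecodingMatrix:
    """Chance-level matrix: labels shuffled per iteration, single-repeat CV
    decode per iteration, Az averaged over ``cfg.n_null_iters``."""
    y = _as_binary(labels)
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    acc = None
    for i in range(cfg.n_null_iters):
        y_perm = rng.permutation(y)
        sub = replace(cfg, n_repeats=1,
                      seed=int(rng.integers(2**31)))
        m = tgm_within(epochs, y_perm, sub, condition="within-null")
        acc = m.az if acc is None else acc + m.az
    return replace(m, az=acc / cfg.n_null_iters)


def null_tgm_across(train_epochs: EpochSet, train_labels,
                    test_epochs: EpochSet, test_labels,
                    cfg: DecodingConfig) -> DecodingMatrix:
    """Chance-level across-condition matrix: condition labels randomized per
    iteration, one balanced subsample per iteration, Az averaged."""
    y_tr = _as_binary(train_labels)
    y_te = _as_binary(test_labels)
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    acc = None
    for i in range(cfg.n_null_iters):
        sub = replace(cfg, n_balance_iters=1,
                      seed=int(rng.integers(2**31)))
        m = tgm_across(train_epochs, rng.permutation(y_tr),
                       test_epochs, rng.permutation(y_te), sub,
                       condition="across-null")
        acc = m.az if acc is None else acc + m.az
    return replace(m, az=acc / cfg.n_null_iters)


# -- controls -----------------------------------------------------------


def residualize(epochs: EpochSet, trials: pd.DataFrame,
                factors=("mean", "variance", "mean_x_variance")) -> EpochSet:
    """Regress nuisance factors out of every channel x sample, one subject.

    EEG amplitudes are replaced by OLS residuals of a regression on the
    requested factor codes (with intercept), computed independently at each
    electrode and time point — the difficulty-confound control.
    """
    from .erp import design_matrix
    if len(trials) != epochs.n_trials:
        raise ValueError("trials table and epochs disagree on trial count")
    X = design_matrix(trials, factors)
    flat = epochs.data.reshape(epochs.n_trials, -1)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    out = epochs.copy()
    out.data = resid.reshape(epochs.data.shape)
    return out


def compare_peak_clusters(matrices_ref: np.ndarray, ref_pixels: np.ndarray,
                          matrices_cmp: np.ndarray,
                          shape: tuple[int, int] | None = None,
                          cmp_pixels: np.ndarray | None = None) -> dict:
    """Paired comparison of decoding accuracy between two matrix regions.

    ``matrices_ref``/``matrices_cmp`` are subjects x T1 x T2 Az stacks.  The
    reference region is given explicitly (``ref_pixels``, (n, 2) indices,
    e.g. the closest-to-significance pre-response cluster).  In the
    comparison matrix a region is selected around the peak of the
    group-mean Az (restricted to ``cmp_pixels`` if given): either the same
    number of pixels as the reference, grown outward from the peak by
    distance (``shape=None``), or a fixed square (e.g. ``shape=(5, 5)``),
    clipped at matrix borders with a warning.  Subject-wise mean Az over
    each region enters a two-tailed paired t test (cmp minus ref).
    """
    ref = np.asarray(matrices_ref, float)
    cmp_ = np.asarray(matrices_cmp, float)
    ref_pixels = np.atleast_2d(np.asarray(ref_pixels, int))
    mean_cmp = cmp_.mean(axis=0)
    if cmp_pixels is not None:
        cmp_pixels = np.atleast_2d(np.asarray(cmp_pixels, int))
        vals = mean_cmp[cmp_pixels[:, 0], cmp_pixels[:, 1]]
        peak = tuple(cmp_pixels[int(np.argmax(vals))])
    else:
        peak = np.unravel_index(int(np.argmax(mean_cmp)), mean_cmp.shape)

    if shape is not None:
        h, w = shape
        r0, r1 = peak[0] - (h - 1) // 2, peak[0] + h // 2
        c0, c1 = peak[1] - (w - 1) // 2, peak[1] + w // 2
        if r0 < 0 or c0 < 0 or r1 >= mean_cmp.shape[0] \
                or c1 >= mean_cmp.shape[1]:
            warnings.warn("peak-centered square clipped at matrix border",
                          stacklevel=2)
        rr, cc = np.meshgrid(
            np.arange(max(r0, 0), min(r1, mean_cmp.shape[0] - 1) + 1),
            np.arange(max(c0, 0), min(c1, mean_cmp.shape[1] - 1) + 1),
            indexing="ij")
        sel = np.column_stack([rr.ravel(), cc.ravel()])
    else:
        n = ref_pixels.shape[0]
        grid = (cmp_pixels if cmp_pixels is not None
                else np.indices(mean_cmp.shape).reshape(2, -1).T)
        d2 = ((grid - np.asarray(peak)) ** 2).sum(axis=1)
        order = np.lexsort((grid[:, 1], grid[:, 0], d2))
        sel = grid[order[:min(n, grid.shape[0])]]

    ref_means = ref[:, ref_pixels[:, 0], ref_pixels[:, 1]].mean(axis=1)
    cmp_means = cmp_[:, sel[:, 0], sel[:, 1]].mean(axis=1)
    if np.allclose(cmp_means, ref_means):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(cmp_means, ref_means)
    return {"t": float(t), "p": float(p), "df": ref.shape[0] - 1,
            "mean_ref": float(ref_means.mean()),
            "mean_cmp": float(cmp_means.mean()),
            "peak": tuple(int(x) for x in peak), "pixels_cmp": sel,
            "n_pixels": int(sel.shape[0])}
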