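"""Cluster-based permutation inference for 1-D traces and 2-D matrices.

Within-subject differences are tested element-wise with a one-sample t
statistic; elements beyond the two-tailed critical value at the forming
threshold are grouped into contiguous clusters (1-D adjacency, or 8-neighbor
adjacency for decoding matrices), each scored by its mass — the sum of |t|
over its members.  Significance comes from the max-mass null distribution
obtained by randomly flipping the sign of each subject's difference (exact
enumeration when feasible, otherwise seeded Monte-Carlo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage, stats

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class Cluster:
    members: np.ndarray     # indices (1-D) or (n, 2) pixel coordinates (2-D)
    mass: float             # sum of |t| over members
    sign: int               # +1 positive cluster, -1 negative
    p_value: float = np.nan

    @property
    def extent(self) -> tuple:
        m = np.asarray(self.members)
        return (int(m.min()), int(m.max())) if m.ndim == 1 else \
            tuple((int(m[:, k].min()), int(m[:, k].max())) for k in range(2))


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    element_threshold_p: float
    n_permutations: int
    connectivity: str               # '1d-adjacent' | '2d-8neighbor'
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        return {
            "element_threshold_p": self.element_threshold_p,
            "n_permutations": self.n_permutations,
            "connectivity": self.connectivity,
            "clusters": [
                {"mass": c.mass, "sign": c.sign, "p_value": c.p_value,
                 "extent": c.extent,
                 "n_members": int(np.asarray(c.members).shape[0])}
                for c in self.clusters],
        }


def one_sample_t(diffs: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t over axis 0 (subjects)."""
    n = diffs.shape[0]
    m = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def _find_clusters(t: np.ndarray, t_crit: float) -> list[Cluster]:
    """Maximal contiguous supra-threshold regions, each sign separately."""
    clusters: list[Cluster] = []
    for sign in (1, -1):
        supra = (sign * t) > t_crit
        if t.ndim == 1:
            labeled, n = ndimage.label(supra)
        else:
            labeled, n = ndimage.label(supra, structure=_EIGHT_CONN)
        for lab in range(1, n + 1):
            where = np.nonzero(labeled == lab)
            members = where[0] if t.ndim == 1 else np.column_stack(where)
            mass = float(np.abs(t[where]).sum())
            clusters.append(Cluster(members=members, mass=mass, sign=sign))
    clusters.sort(key=lambda c: c.mass, reverse=True)
    return clusters


def _max_mass(t: np.ndarray, t_crit: float) -> float:
    best = 0.0
    for sign in (1, -1):
        supra = (sign * t) > t_crit
        if not supra.any():
            continue
        if t.ndim == 1:
            labeled, n = ndimage.label(supra)
        else:
            labeled, n = ndimage.label(supra, structure=_EIGHT_CONN)
        masses = ndimage.sum_labels(np.abs(t), labeled, np.arange(1, n + 1))
        if masses.size:
            best = max(best, float(masses.max()))
    return best


def _sign_flip_null(diffs: np.ndarray, t_crit: float, n_perm: int,
                    seed, enumerate_limit: int = 4096
                    ) -> tuple[np.ndarray, bool]:
    """Max cluster mass under random (or exhaustively enumerated) sign flips.

    The element-wise second moment is invariant to sign flips, so for each
    draw only the mean needs recomputation: t = s*mean / sqrt((ss - n*mean^2)
    / (n-1) / n) with ss fixed.
    """
    n_sub = diffs.shape[0]
    flat = diffs.reshape(n_sub, -1)
    ss = (flat**2).sum(axis=0)
    shape = diffs.shape[1:]

    exhaustive = 2**n_sub <= enumerate_limit
    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n_sub)))
    else:
        if n_perm < 100:
            warnings.warn(f"n_perm={n_perm} gives unstable permutation "
                          "p-values", stacklevel=3)
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n_sub))

    means = signs @ flat / n_sub                       # (draws, elements)
    var = np.maximum(ss[None, :] - n_sub * means**2, 0.0) / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = means / np.sqrt(var / n_sub)
    t_all = np.where(np.isfinite(t_all), t_all, 0.0)
    null = np.array([_max_mass(row.reshape(shape), t_crit)
                     for row in t_all])
    return null, exhaustive


def _p_values(clusters: list[Cluster], null: np.ndarray,
              exhaustive: bool) -> None:
    for c in clusters:
        b = int((null >= c.mass - 1e-12).sum())
        if exhaustive:
            c.p_value = b / null.size      # identity flip always counts
        else:
            c.p_value = (b + 1) / (null.size + 1)


def _cluster_permutation(diffs: np.ndarray, element_p: float, n_perm: int,
                         seed, connectivity: str) -> ClusterSet:
    n_sub = diffs.shape[0]
    if n_sub < 6:
        raise ValueError("cluster permutation needs at least 6 subjects")
    t_crit = stats.t.ppf(1.0 - element_p / 2.0, df=n_sub - 1)
    t_obs = one_sample_t(diffs)
    clusters = _find_clusters(t_obs, t_crit)
    null, exhaustive = _sign_flip_null(diffs, t_crit, n_perm, seed)
    _p_values(clusters, null, exhaustive)
    return ClusterSet(clusters=clusters, element_threshold_p=element_p,
                      n_permutations=null.size, connectivity=connectivity,
                      null_max_mass=null)


def cluster_permutation_1d(cond_a: np.ndarray, cond_b: np.ndarray,
                           element_p: float = 0.05, n_perm: int = 1000,
                           seed=None) -> ClusterSet:
    """Paired cluster test between two condition traces.

    ``cond_a`` and ``cond_b`` are subjects x time arrays (one value per
    subject per sample, e.g. condition-mean ERPs).
    """
    a, b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("conditions must be matching subjects x time arrays")
    return _cluster_permutation(a - b, element_p, n_perm, seed,
                                connectivity="1d-adjacent")


def cluster_permutation_values(values: np.ndarray, element_p: float = 0.05,
                               n_perm: int = 1000, seed=None) -> ClusterSet:
    """One-sample (against zero) cluster test on subjects x time values,
    e.g. per-subject regression t traces."""
    v = np.asarray(values, float)
    if v.ndim != 2:
        raise ValueError("expected a subjects x time array")
    return _cluster_permutation(v, element_p, n_perm, seed,
                                connectivity="1d-adjacent")


def cluster_permutation_2d(true: np.ndarray, null: np.ndarray,
                           element_p: float = 0.01, n_perm: int = 1000,
                           seed=None) -> ClusterSet:
    """Paired cluster test between true and null decoding matrices.

    ``true`` and ``null`` are subjects x train-windows x test-windows Az
    arrays; pixels are neighbors when cardinally or diagonally adjacent.
    """
    a, b = np.asarray(true, float), np.asarray(null, float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("matrices must be matching subjects x T1 x T2")
    return _cluster_permutation(a - b, element_p, n_perm, seed,
                                connectivity="2d-8neighbor")


def largest_uncorrected_cluster(true: np.ndarray, null: np.ndarray,
                                element_p: float = 0.01) -> Cluster | None:
    """Largest contiguous set of pixels passing the element threshold,
    uncorrected — the 'closest to significance' region of a matrix."""
    diffs = np.asarray(true, float) - np.asarray(null, float)
    t_crit = stats.t.ppf(1.0 - element_p / 2.0, df=diffs.shape[0] - 1)
    clusters = _find_clusters(one_sample_t(diffs), t_crit)
    if not clusters:
        return None
    return max(clusters, key=lambda c: (np.asarray(c.members).shape[0],
                                        c.mass))
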