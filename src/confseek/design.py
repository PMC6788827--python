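"""Task design: stimulus specifications, trial schedules, staircase, scoring.

The task is a speeded color-mean discrimination.  Each stimulus is eight
color values on the red-blue RGB path parameterized by a position C in
[0, 1] (0.5 is the category boundary; C < 0.5 blue, C > 0.5 red) with a
target element variance V.  Difficulty is manipulated 2 x 2 by the distance
of the mean from the boundary ("high" mean = far = easy) and by the element
variance.  On 75% of trials (free-choice) the observer may pay one point to
see an easier version of the stimulus again before the final decision; on
the remaining no-choice trials an immediate final response is forced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

# starting C levels, blue side (< 0.5); red side mirrors at 1 - C
C_LOW_MEAN = 0.474    # near the boundary -> hard
C_HIGH_MEAN = 0.450   # far from the boundary -> easy
V_LOW = 0.0333
V_HIGH = 0.1000

EASIER_C_SHIFT = 0.01      # resampled stimulus: mean moved away from boundary
EASIER_V_DROP = 0.0167     # ... and element variance reduced

# staircase on the low-mean C level: |IES gap| thresholds -> step sizes
STAIRCASE_THRESHOLDS = (100.0, 50.0, 10.0)
STAIRCASE_STEPS = (0.0025, 0.0012, 0.0005)

POINTS_CORRECT = 5
POINTS_ERROR = -5
POINTS_SEE_AGAIN = -1
POINTS_PER_POUND = 650
MAX_PAYOUT_GBP = 4.92

CONFIDENCE_MAX = 50  # rating scale runs -50 (sure blue) .. 50 (sure red), no 0


@dataclass(frozen=True)
class StimulusSpec:
    """Mean/variance specification of one eight-element color stimulus."""

    c: float                  # mean position on the red-blue path, in (0, 1)
    v: float                  # target variance of the eight element values
    n_elements: int = 8
    is_resample: bool = False  # easier "see again" version

    def __post_init__(self) -> None:
        if not 0.0 < self.c < 1.0:
            raise ValueError(f"C must lie strictly in (0, 1), got {self.c}")
        if self.v < 0.0:
            raise ValueError(f"V must be non-negative, got {self.v}")
        if self.n_elements < 2:
            raise ValueError("need at least two elements")

    @property
    def boundary_distance(self) -> float:
        return abs(self.c - 0.5)


def sample_stimulus(spec: StimulusSpec, seed=None, tol: float = 1e-3,
                    max_iter: int = 100) -> np.ndarray:
    """Draw element colors whose realized mean and variance match the spec.

    A pseudo-random draw is affinely rescaled to hit the target mean and
    variance exactly, then clamped to the valid color range [0, 1]; if
    clamping perturbed the moments beyond ``tol`` the draw is repeated.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_elements
    if spec.v == 0.0:
        return np.full(n, spec.c)
    for _ in range(max_iter):
        x = rng.uniform(size=n)
        sd = x.std(ddof=0)
        if sd < 1e-12:
            continue
        scale = np.sqrt(spec.v) / sd
        vals = spec.c + (x - x.mean()) * scale
        vals = np.clip(vals, 0.0, 1.0)
        if (abs(vals.mean() - spec.c) <= tol
                and abs(vals.var(ddof=0) - spec.v) <= tol):
            return vals
    raise ValueError(
        f"could not realize mean={spec.c}, var={spec.v} within [0, 1] "
        f"after {max_iter} attempts (variance too large for a mean this "
        f"close to 0 or 1)")


def make_easier(spec: StimulusSpec) -> StimulusSpec:
    """Easier resampled version: mean 0.01 farther from the boundary, variance
    reduced by 0.0167 (clipped at zero with a warning)."""
    shift = EASIER_C_SHIFT if spec.c > 0.5 else -EASIER_C_SHIFT
    v_new = spec.v - EASIER_V_DROP
    if v_new < 0.0:
        warnings.warn(f"easier variance {v_new:.4f} < 0; clipping to 0",
                      stacklevel=2)
        v_new = 0.0
    return replace(spec, c=spec.c + shift, v=v_new, is_resample=True)


# -- trial schedule -----------------------------------------------------


def make_design(n_blocks: int = 10, trials_per_block: int = 64,
                p_free: float = 0.75, seed=None, participant: int = 0,
                c_low: float = C_LOW_MEAN, c_high: float = C_HIGH_MEAN,
                ) -> pd.DataFrame:
    """Balanced pseudo-random trial schedule.

    Each block crosses mean level (high/low distance from the boundary),
    variance level (high/low), color (red/blue) and trial type (free-choice
    with probability ``p_free``, else no-choice), with exact per-cell counts
    inside every block and a seeded shuffle of trial order.

    Returns a trial table with design columns only; behavior columns are
    filled by :func:`confseek.observer.simulate_observer`.
    """
    n_free = p_free * trials_per_block
    n_nochoice = trials_per_block - n_free
    cells = 8  # 2 mean x 2 variance x 2 color
    if (n_free % cells or n_nochoice % cells
            or abs(n_free - round(n_free)) > 1e-9):
        raise ValueError(
            f"trials_per_block={trials_per_block} with p_free={p_free} does "
            f"not divide evenly over {cells} mean x variance x color cells "
            f"per trial type")
    rng = np.random.default_rng(seed)
    rows = []
    for block in range(1, n_blocks + 1):
        block_rows = []
        for trial_type, count in (("free", int(n_free) // cells),
                                  ("no-choice", int(n_nochoice) // cells)):
            for mean_level in ("high", "low"):
                for var_level in ("high", "low"):
                    for color in ("red", "blue"):
                        c_blue = c_high if mean_level == "high" else c_low
                        c = 1.0 - c_blue if color == "red" else c_blue
                        v = V_HIGH if var_level == "high" else V_LOW
                        block_rows += [(mean_level, var_level, color,
                                        trial_type, c, v)] * count
        order = rng.permutation(len(block_rows))
        for i, j in enumerate(order):
            rows.append((participant, block, i + 1) + block_rows[j])
    return pd.DataFrame(rows, columns=[
        "participant", "block", "trial", "mean_level", "var_level", "color",
        "trial_type", "c", "v"])


# -- staircase and scoring ----------------------------------------------


def staircase_update(ies_lowmean: float, ies_highvar: float,
                     c_low_current: float) -> float:
    """Between-block adjustment of the low-mean C level.

    The staircase compares inverse efficiency (median RT / p(correct))
    between the low-mean/low-variance and high-mean/high-variance cells.
    An absolute gap >= 100 / 50 / 10 moves C by 0.0025 / 0.0012 / 0.0005;
    smaller gaps leave it unchanged.  A positive gap (low-mean condition
    less efficient, i.e. harder) moves the level away from the boundary to
    ease it; a negative gap moves it toward the boundary.
    """
    if not (np.isfinite(ies_lowmean) and np.isfinite(ies_highvar)):
        raise ValueError("both inverse efficiency scores must be finite")
    if ies_lowmean <= 0 or ies_highvar <= 0:
        raise ValueError("inverse efficiency scores must be positive")
    d = ies_lowmean - ies_highvar
    step = 0.0
    for threshold, size in zip(STAIRCASE_THRESHOLDS, STAIRCASE_STEPS):
        if abs(d) >= threshold:
            step = size
            break
    if step == 0.0:
        return c_low_current
    # direction that increases |C - 0.5| when the low-mean cell is harder
    away = -1.0 if c_low_current < 0.5 else 1.0
    direction = away if d > 0 else -away
    return c_low_current + direction * step


def score_session(trials: pd.DataFrame,
                  max_payout_gbp: float = MAX_PAYOUT_GBP) -> dict:
    """Points and payout: +5 per correct final answer, -5 per error, -1 per
    see-again sample; 650 points convert to one pound, capped and floored."""
    if trials["final_correct"].isna().any():
        raise ValueError("final_correct must be filled before scoring")
    n_correct = int((trials["final_correct"] == 1).sum())
    n_error = int((trials["final_correct"] == 0).sum())
    n_seek = int((trials["see_again"] == 1).sum())
    points = (POINTS_CORRECT * n_correct + POINTS_ERROR * n_error
              + POINTS_SEE_AGAIN * n_seek)
    payout = min(max(points, 0) / POINTS_PER_POUND, max_payout_gbp)
    return {"points": points, "payout_gbp": payout}
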