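"""Forward EEG model: confidence-coupled components in correlated noise.

Each trial's multichannel signal is a sum of two spatiotemporal components
plus spatially and temporally correlated Gaussian noise:

* a stimulus-locked centroparietal positivity (P3-like), temporal kernel
  supported 300-600 ms after stimulus onset, whose single-trial amplitude
  *increases* with standardized confidence;
* a response-locked centroparietal positivity (Pe-like, the error
  positivity), kernel supported 250-700 ms after the primary response, whose
  amplitude *decreases* with confidence (low confidence -> large Pe).

The signal is synthesized once per trial on a continuous timeline and then
cut into stimulus-locked, response-locked and choice-locked epoch sets, so
realigning one view onto another clock reproduces the other view exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import montage
from .epochs import EpochSet

DEFAULT_WINDOWS = {
    "stimulus": (-100.0, 1000.0),
    "response": (-100.0, 700.0),
    "choice": (-700.0, 100.0),
}


@dataclass(frozen=True)
class TemporalKernel:
    """Gaussian bump restricted to a hard support interval (ms, unit peak)."""

    center_ms: float
    width_ms: float
    support_ms: tuple[float, float]

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        k = np.exp(-((t - self.center_ms) ** 2) / (2.0 * self.width_ms**2))
        lo, hi = self.support_ms
        return np.where((t >= lo) & (t <= hi), k, 0.0)


@dataclass(frozen=True)
class GenerativeEEGParams:
    srate_hz: float = 250.0
    alpha0: float = 4.0              # baseline component amplitude, uV
    alpha1_p3: float = 1.5           # confidence -> P3 amplitude, uV per z
    alpha1_pe: float = 2.0           # confidence -> Pe amplitude, uV per z
                                     # (enters negatively: low conf, big Pe)
    alpha1_pe_difficulty: float = 0.0  # optional difficulty -> Pe confound
    noise_sd: float = 6.0            # per-channel noise sd, uV
    noise_spatial_scale: float = 0.6  # correlation length on the unit disc
    noise_ar: float = 0.8            # lag-1 temporal autocorrelation
    p3_center: str = "CPz"
    pe_center: str = "CPz"
    topo_width: float = 0.35
    p3_kernel: TemporalKernel = field(
        default=TemporalKernel(450.0, 55.0, (300.0, 600.0)))
    pe_kernel: TemporalKernel = field(
        default=TemporalKernel(475.0, 90.0, (250.0, 700.0)))
    # column of standardized confidence the amplitudes couple to; the
    # session pipeline uses the pre-resampling internal confidence so the
    # Pe reflects the state at the time of the primary response
    coupling_column: str = "confidence_z"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.noise_ar < 1:
            raise ValueError("noise_ar must lie in [0, 1)")
        if not 300.0 <= self.p3_kernel.support_ms[0] <= self.p3_kernel.support_ms[1] <= 600.0:
            raise ValueError("P3 kernel support must lie within 300-600 ms")
        if not 250.0 <= self.pe_kernel.support_ms[0] <= self.pe_kernel.support_ms[1] <= 700.0:
            raise ValueError("Pe kernel support must lie within 250-700 ms")

    @property
    def p3_topography(self) -> np.ndarray:
        return montage.gaussian_topography(self.p3_center, self.topo_width)

    @property
    def pe_topography(self) -> np.ndarray:
        return montage.gaussian_topography(self.pe_center, self.topo_width)


def _difficulty_score(trials: pd.DataFrame) -> np.ndarray:
    """Symmetric difficulty code: +1 hardest (low mean, high variance),
    -1 easiest (high mean, low variance), 0 in between."""
    hard_mean = (trials["mean_level"] == "low").to_numpy(float) - 0.5
    hard_var = (trials["var_level"] == "high").to_numpy(float) - 0.5
    return hard_mean + hard_var


def component_amplitudes(trials: pd.DataFrame, params: GenerativeEEGParams
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial P3 and Pe amplitudes implied by the generative model."""
    conf_z = trials[params.coupling_column].to_numpy(float)
    amp_p3 = params.alpha0 + params.alpha1_p3 * conf_z
    amp_pe = (params.alpha0 - params.alpha1_pe * conf_z
              + params.alpha1_pe_difficulty * _difficulty_score(trials))
    return amp_p3, amp_pe


def _correlated_noise(n_trials: int, n_channels: int, n_samples: int,
                      params: GenerativeEEGParams,
                      rng: np.random.Generator) -> np.ndarray:
    burn = 50
    w = rng.standard_normal((n_trials, n_channels, n_samples + burn))
    if params.noise_ar > 0:
        scale = np.sqrt(1.0 - params.noise_ar**2)
        w = lfilter([scale], [1.0, -params.noise_ar], w, axis=-1)
    w = w[..., burn:]
    chol = np.linalg.cholesky(
        montage.spatial_correlation(params.noise_spatial_scale))
    return params.noise_sd * np.einsum("cd,ndt->nct", chol, w)


def simulate_eeg(trials: pd.DataFrame, params: GenerativeEEGParams,
                 seed=None, windows: dict | None = None
                 ) -> dict[str, EpochSet]:
    """Cut stimulus-, response- and choice-locked epochs from one signal.

    ``trials`` must contain rt_ms, choice_latency_ms and confidence_z (run
    :func:`confseek.preprocess.zscore_confidence` first).  Event latencies
    must sit on the sample grid so that the three views are sample-exact
    translations of each other.  Returned epochs are raw (no baseline).
    """
    for col in ("rt_ms", "choice_latency_ms", params.coupling_column):
        if col not in trials.columns:
            raise ValueError(f"trials table lacks required column {col!r}")
    windows = dict(DEFAULT_WINDOWS, **(windows or {}))
    dt = 1000.0 / params.srate_hz
    rt = trials["rt_ms"].to_numpy(float)
    latency = trials["choice_latency_ms"].to_numpy(float)
    offsets = {"stimulus": np.zeros(len(trials)), "response": rt,
               "choice": rt + latency}
    for name, off in offsets.items():
        if np.any(np.abs(off / dt - np.rint(off / dt)) > 1e-6):
            raise ValueError(
                f"{name} event latencies are not multiples of the sample "
                f"interval {dt} ms; align rt/choice latencies to the grid")

    # continuous support on the stimulus clock covering every requested cut
    lo = min(windows[a][0] + offsets[a].min() for a in windows)
    hi = max(windows[a][1] + offsets[a].max() for a in windows)
    i0, i1 = int(np.floor(lo / dt)), int(np.ceil(hi / dt))
    t_cont = np.arange(i0, i1 + 1) * dt
    n_trials, n_ch, n_t = len(trials), len(montage.CHANNEL_NAMES), len(t_cont)

    amp_p3, amp_pe = component_amplitudes(trials, params)
    sig = np.zeros((n_trials, n_ch, n_t))
    k_p3 = params.p3_kernel(t_cont)                      # same for all trials
    sig += amp_p3[:, None, None] * params.p3_topography[None, :, None] \
        * k_p3[None, None, :]
    k_pe = params.pe_kernel(t_cont[None, :] - rt[:, None])  # response clock
    sig += amp_pe[:, None, None] * params.pe_topography[None, :, None] \
        * k_pe[:, None, :]
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig += _correlated_noise(n_trials, n_ch, n_t, params, rng)

    trial_index = (trials.index.to_numpy() if trials.index.is_unique
                   else np.arange(n_trials))
    out: dict[str, EpochSet] = {}
    for alignment, (w0, w1) in windows.items():
        n_win = int(round((w1 - w0) / dt)) + 1
        cut = np.empty((n_trials, n_ch, n_win))
        for i in range(n_trials):
            start = int(round((offsets[alignment][i] + w0) / dt)) - i0
            if start < 0 or start + n_win > n_t:
                raise RuntimeError("epoch window extends beyond the "
                                   "simulated signal support")
            cut[i] = sig[i, :, start:start + n_win]
        out[alignment] = EpochSet(
            data=cut,
            times_ms=(np.arange(n_win) + round(w0 / dt)) * dt,
            channel_names=list(montage.CHANNEL_NAMES),
            srate_hz=params.srate_hz,
            alignment=alignment,
            trial_index=trial_index,
        )
    return out
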