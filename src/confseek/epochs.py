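"""Event-locked EEG epoch container with HDF5 round-trip.

An :class:`EpochSet` holds a trials x channels x samples amplitude array in
microvolts together with its time axis, alignment event (stimulus, response
or information-seeking choice), channel labels and the row keys linking each
epoch back to the behavioral trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

ALIGNMENTS = ("stimulus", "response", "choice")


@dataclass
class EpochSet:
    data: np.ndarray              # (n_trials, n_channels, n_samples), microvolts
    times_ms: np.ndarray          # (n_samples,), relative to the alignment event
    channel_names: list[str]
    srate_hz: float
    alignment: str                # one of ALIGNMENTS
    trial_index: np.ndarray       # (n_trials,), keys into the trial table
    baseline_window_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.trial_index = np.asarray(self.trial_index)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channel_names) != n_channels:
            raise ValueError("channel_names length does not match data")
        if self.times_ms.shape != (n_samples,):
            raise ValueError("times_ms length does not match data")
        if self.trial_index.shape != (n_trials,):
            raise ValueError("trial_index length does not match data")
        if len(np.unique(self.trial_index)) != n_trials:
            raise ValueError("trial_index entries must be unique")
        if self.alignment not in ALIGNMENTS:
            raise ValueError(f"alignment must be one of {ALIGNMENTS}")
        if n_samples > 1:
            dt = np.diff(self.times_ms)
            if np.any(dt <= 0):
                raise ValueError("times_ms must be strictly increasing")
            if not np.allclose(dt, dt[0], atol=1e-6):
                raise ValueError("times_ms must be uniformly spaced")

    # -- basics ---------------------------------------------------------

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.srate_hz

    def channel(self, name: str) -> int:
        """Index of a channel label."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``; errors if outside the epoch."""
        if t_ms < self.times_ms[0] - self.dt_ms / 2 or t_ms > self.times_ms[-1] + self.dt_ms / 2:
            raise ValueError(f"time {t_ms} ms outside epoch "
                             f"[{self.times_ms[0]}, {self.times_ms[-1]}] ms")
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def select_trials(self, mask_or_idx: np.ndarray) -> "EpochSet":
        """Subset of trials (boolean mask over rows or integer positions)."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, data=self.data[idx], trial_index=self.trial_index[idx])

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), trial_index=self.trial_index.copy())

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        """Write the container to an HDF5 file."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("channel_names",
                             data=np.array(self.channel_names, dtype="S"))
            f.create_dataset("trial_index", data=self.trial_index)
            f.attrs["alignment"] = self.alignment
            f.attrs["srate_hz"] = self.srate_hz
            if self.baseline_window_ms is not None:
                f.attrs["baseline_window_ms"] = list(self.baseline_window_ms)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            baseline = f.attrs.get("baseline_window_ms")
            return cls(
                data=f["data"][...].astype(float),
                times_ms=f["times_ms"][...],
                channel_names=[n.decode() for n in f["channel_names"][...]],
                srate_hz=float(f.attrs["srate_hz"]),
                alignment=str(f.attrs["alignment"]),
                trial_index=f["trial_index"][...],
                baseline_window_ms=None if baseline is None else tuple(baseline),
            )
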