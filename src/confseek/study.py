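"""End-to-end synthetic study generation.

Chains the design, observer, staircase and forward EEG model into complete
sessions: per block, a balanced schedule is drawn at the current C levels,
the observer acts on it, and (from the second block on) the inverse-
efficiency staircase nudges the low-mean C level to equate difficulty
between the low-mean/low-variance and high-mean/high-variance cells.
Confidence is z-scored per participant x block before the EEG is
synthesized, because the forward model couples component amplitudes to
standardized confidence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design as dsn
from .behavior import staircase_ies
from .epochs import EpochSet
from .forward import GenerativeEEGParams, simulate_eeg
from .observer import ObserverParams, simulate_observer
from .preprocess import zscore_confidence


@dataclass(frozen=True)
class StudyConfig:
    n_subjects: int = 15
    n_blocks: int = 10
    trials_per_block: int = 64
    p_free: float = 0.75
    run_staircase: bool = True
    c_low_bounds: tuple[float, float] = (0.400, 0.499)  # blue-side bounds
    observer: ObserverParams = field(default_factory=ObserverParams)
    eeg: GenerativeEEGParams = field(default_factory=GenerativeEEGParams)
    eeg_windows: dict | None = None
    simulate_eeg: bool = True


@dataclass
class Subject:
    trials: pd.DataFrame
    epochs: dict[str, EpochSet] | None
    staircase_log: list[dict]


def simulate_session(config: StudyConfig, seed, participant: int = 0
                     ) -> Subject:
    """One participant: block loop with staircase, then EEG synthesis."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seeds = ss.generate_state(2 * config.n_blocks + 1)
    c_low = dsn.C_LOW_MEAN
    lo, hi = config.c_low_bounds
    blocks = []
    log: list[dict] = []
    for b in range(config.n_blocks):
        block = dsn.make_design(
            n_blocks=1, trials_per_block=config.trials_per_block,
            p_free=config.p_free, seed=seeds[2 * b],
            participant=participant, c_low=c_low)
        block["block"] = b + 1
        block = simulate_observer(block, config.observer, seed=seeds[2 * b + 1])
        blocks.append(block)
        if config.run_staircase:
            ies_low, ies_high = staircase_ies(block)
            if np.isnan(ies_low) or np.isnan(ies_high):
                log.append({"block": b + 1, "c_low": c_low,
                            "update": "skipped (undefined IES)"})
                continue
            new = dsn.staircase_update(ies_low, ies_high, c_low)
            new = float(np.clip(new, lo, hi))
            log.append({"block": b + 1, "ies_gap": ies_low - ies_high,
                        "c_low_before": c_low, "c_low_after": new})
            c_low = new
    trials = pd.concat(blocks, ignore_index=True)
    trials = zscore_confidence(trials)
    trials = zscore_confidence(trials, column="confidence_internal",
                               out_column="confidence_internal_z")
    epochs = None
    if config.simulate_eeg:
        eeg = config.eeg
        if eeg.coupling_column == "confidence_z":
            eeg = dataclasses.replace(eeg,
                                      coupling_column="confidence_internal_z")
        epochs = simulate_eeg(trials, eeg, seed=seeds[-1],
                              windows=config.eeg_windows)
    return Subject(trials=trials, epochs=epochs, staircase_log=log)


def simulate_study(config: StudyConfig, seed) -> list[Subject]:
    """Independent sessions for ``config.n_subjects`` participants."""
    child_seeds = np.random.SeedSequence(seed).spawn(config.n_subjects)
    return [simulate_session(config, child_seeds[p], participant=p)
            for p in range(config.n_subjects)]


def save_trial_table(trials: pd.DataFrame, path) -> None:
    """CSV with one header row; NA as empty field."""
    trials.to_csv(path, index=False, na_rep="")


def load_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
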