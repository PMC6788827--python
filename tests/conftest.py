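import dataclasses

import numpy as np
import pytest

import confseek as cs
from confseek.forward import GenerativeEEGParams


@pytest.fixture(scope="session")
def small_session():
    """One simulated participant, 3 blocks, default parameters."""
    cfg = cs.StudyConfig(n_subjects=1, n_blocks=3, trials_per_block=64)
    return cs.simulate_session(cfg, seed=424242)


@pytest.fixture(scope="session")
def noisefree_session():
    """Deterministic forward model (no EEG noise), wide stimulus epoch so
    every response-locked window is covered by the stimulus-locked cut."""
    eeg = dataclasses.replace(GenerativeEEGParams(), noise_sd=0.0)
    cfg = cs.StudyConfig(
        n_subjects=1, n_blocks=2, trials_per_block=64, eeg=eeg,
        eeg_windows={"stimulus": (-200.0, 2200.0)})
    return cs.simulate_session(cfg, seed=90210)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
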