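"""Standard 32-channel 10-20 montage with schematic 2-D scalp coordinates.

Coordinates are an azimuthal-equidistant style projection of the standard
10-20 layout onto the unit disc (nose up, +y anterior, +x right).  They are
used only to parameterize smooth scalp topographies and spatially correlated
noise, so schematic positions are sufficient.
"""

from __future__ import annotations

import numpy as np

# name -> (x, y) on the unit disc
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.25, 0.82), "Fpz": (0.00, 0.85), "Fp2": (0.25, 0.82),
    "F7": (-0.68, 0.52), "F3": (-0.35, 0.45), "Fz": (0.00, 0.43),
    "F4": (0.35, 0.45), "F8": (0.68, 0.52),
    "FT7": (-0.78, 0.27), "FC3": (-0.38, 0.22), "FCz": (0.00, 0.21),
    "FC4": (0.38, 0.22), "FT8": (0.78, 0.27),
    "T7": (-0.85, 0.00), "C3": (-0.42, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.42, 0.00), "T8": (0.85, 0.00),
    "TP7": (-0.78, -0.27), "CP3": (-0.38, -0.22), "CPz": (0.00, -0.21),
    "CP4": (0.38, -0.22), "TP8": (0.78, -0.27),
    "P7": (-0.68, -0.52), "P3": (-0.35, -0.45), "Pz": (0.00, -0.43),
    "P4": (0.35, -0.45), "P8": (0.68, -0.52),
    "POz": (0.00, -0.64),
    "O1": (-0.25, -0.82), "Oz": (0.00, -0.85), "O2": (0.25, -0.82),
}

CHANNEL_NAMES: list[str] = list(_POSITIONS)


def channel_positions() -> np.ndarray:
    """(32, 2) array of schematic electrode coordinates, row order CHANNEL_NAMES."""
    return np.array([_POSITIONS[name] for name in CHANNEL_NAMES], dtype=float)


def gaussian_topography(center: str = "CPz", width: float = 0.35) -> np.ndarray:
    """Unit-norm Gaussian scalp map centered on an electrode.

    Parameters
    ----------
    center
        Electrode at the bump maximum.
    width
        Spatial standard deviation in coordinate (unit-disc) units.
    """
    pos = channel_positions()
    c = pos[CHANNEL_NAMES.index(center)]
    d2 = np.sum((pos - c) ** 2, axis=1)
    topo = np.exp(-d2 / (2.0 * width**2))
    return topo / np.linalg.norm(topo)


def spatial_correlation(length_scale: float = 0.6) -> np.ndarray:
    """Squared-exponential channel-by-channel noise correlation matrix."""
    pos = channel_positions()
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    corr = np.exp(-d2 / (2.0 * length_scale**2))
    # tiny jitter keeps the Cholesky factor well conditioned
    return corr + 1e-9 * np.eye(len(CHANNEL_NAMES))
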