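"""The 29-channel 10-20 recording montage used throughout the package.

Positions are 2-D azimuthal-equidistant projections of the standard 10-20
electrode locations (vertex at the origin, nose toward +y, units of
radians of arc from the vertex).  They are used only for relative
geometry: the forward model weights each channel by its distance to a
component's peak electrode.
"""

from __future__ import annotations

import numpy as np

#: Channel order of the recording cap (nasion-referenced, ground Fpz).
CHANNELS: tuple[str, ...] = (
    "F3", "F4", "Fz", "FC1", "FC2", "FC5", "FC6",
    "C3", "C4", "Cz", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6",
    "P3", "P4", "Pz", "P7", "P8",
    "PO3", "PO4", "POz", "PO7", "PO8",
    "O1", "Oz", "O2",
)

#: 2-D projected positions, radians of arc from the vertex.
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "F3": (-0.7198, +0.7609),
    "F4": (+0.7408, +0.7760),
    "Fz": (+0.0039, +0.7219),
    "FC1": (-0.3909, +0.2985),
    "FC2": (+0.4030, +0.3063),
    "FC5": (-1.2365, +0.2986),
    "FC6": (+1.2427, +0.3115),
    "C3": (-0.7885, -0.1403),
    "C4": (+0.8084, -0.1313),
    "Cz": (+0.0040, -0.0912),
    "T7": (-1.6498, -0.3140),
    "T8": (+1.6546, -0.2921),
    "CP1": (-0.3451, -0.4596),
    "CP2": (+0.3729, -0.4573),
    "CP5": (-1.0764, -0.6295),
    "CP6": (+1.0973, -0.6072),
    "P3": (-0.5797, -0.8616),
    "P4": (+0.6011, -0.8483),
    "Pz": (+0.0031, -0.7762),
    "P7": (-1.1199, -1.1356),
    "P8": (+1.1280, -1.1282),
    "PO3": (-0.4212, -1.1633),
    "PO4": (+0.4262, -1.1686),
    "POz": (+0.0023, -1.1109),
    "PO7": (-0.7577, -1.3474),
    "PO8": (+0.7660, -1.3435),
    "O1": (-0.3783, -1.4462),
    "Oz": (+0.0014, -1.4439),
    "O2": (+0.3844, -1.4448),
}


def position_array(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Stack channel positions into an (n_channels, 2) array."""
    return np.array([POSITIONS_2D[c] for c in channels], dtype=float)


def spatial_weights(peak_channel: str, spread: float,
                    channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Gaussian spatial profile exp(-d^2 / 2 s^2) around ``peak_channel``.

    ``spread`` is in the same (radian) units as the projected positions;
    the weight is 1 at the peak electrode and decays with squared 2-D
    distance.
    """
    if peak_channel not in POSITIONS_2D:
        raise KeyError(f"unknown electrode {peak_channel!r}")
    pos = position_array(channels)
    peak = np.array(POSITIONS_2D[peak_channel])
    d2 = np.sum((pos - peak) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * spread**2))
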