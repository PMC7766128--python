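"""Electrode montage: 31-channel 10-20 layout with approximate 2-D positions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel order of the 31-electrode 10-20 montage used throughout.
CHANNELS_31 = (
    "FP1", "FP2", "F7", "F3", "F4", "F8",
    "FC5", "FC3", "FC1", "FC2", "FC4", "FC6",
    "C3", "C1", "Cz", "C2", "C4",
    "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
    "P3", "P1", "Pz", "P2", "P4",
    "O1", "Oz", "O2",
)

# Approximate 2-D scalp coordinates (x: left->right, y: back->front), unit head.
_POSITIONS = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "FC5": (-0.62, 0.28), "FC3": (-0.37, 0.27), "FC1": (-0.13, 0.26),
    "FC2": (0.13, 0.26), "FC4": (0.37, 0.27), "FC6": (0.62, 0.28),
    "C3": (-0.50, 0.00), "C1": (-0.25, 0.00), "Cz": (0.00, 0.00),
    "C2": (0.25, 0.00), "C4": (0.50, 0.00),
    "CP5": (-0.62, -0.28), "CP3": (-0.37, -0.27), "CP1": (-0.13, -0.26),
    "CP2": (0.13, -0.26), "CP4": (0.37, -0.27), "CP6": (0.62, -0.28),
    "P3": (-0.40, -0.52), "P1": (-0.20, -0.51), "Pz": (0.00, -0.50),
    "P2": (0.20, -0.51), "P4": (0.40, -0.52),
    "O1": (-0.31, -0.95), "Oz": (0.00, -1.00), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel labels, sampling rate, and 2-D positions.

    The default montage is the 31-channel 10-20 arrangement at 500 Hz.
    """

    channel_names: tuple = CHANNELS_31
    sampling_rate: float = 500.0
    positions: dict = field(default_factory=lambda: dict(_POSITIONS))

    def __post_init__(self):
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(names) != 31:
            raise ValueError(f"montage must have exactly 31 channels, got {len(names)}")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        missing = [n for n in names if n not in self.positions]
        if missing:
            raise ValueError(f"positions missing for channels: {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        """Index of a channel label in the montage order."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def position_array(self) -> np.ndarray:
        """(n_channels, 2) array of scalp coordinates in montage order."""
        return np.array([self.positions[n] for n in self.channel_names], float)
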