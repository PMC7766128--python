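"""EEG recording container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import MontageSpec

EVENT_COLUMNS = ("onset_s", "duration_s", "label")


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="float64" if c != "label" else "object")
                         for c in EVENT_COLUMNS})


@dataclass
class EEGRecording:
    """Multichannel EEG: (n_channels, n_samples) float array in microvolts.

    ``events`` is a DataFrame with columns (onset_s, duration_s, label);
    timestamps are seconds from recording start, 0-based.
    """

    data: np.ndarray
    montage: MontageSpec
    events: pd.DataFrame = field(default_factory=empty_events)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def sfreq(self) -> float:
        return self.montage.sampling_rate

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        """1-D view of one channel by label."""
        return self.data[self.montage.index(name)]

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.montage, self.events.copy())

    def slice_seconds(self, start_s: float, end_s: float) -> np.ndarray:
        """Half-open sample slice [start_s, end_s) as a view."""
        i0 = int(round(start_s * self.sfreq))
        i1 = int(round(end_s * self.sfreq))
        if i0 < 0 or i1 > self.n_samples or i0 >= i1:
            raise ValueError(f"slice [{start_s}, {end_s}) outside recording")
        return self.data[:, i0:i1]
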