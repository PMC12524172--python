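"""In-memory containers for continuous and epoched magnetometer data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import SensorArray


@dataclass
class Recording:
    """Continuous multichannel recording (channels x samples, fT)."""

    data: np.ndarray
    sampling_rate: float
    array: SensorArray
    events: list[tuple[float, str]] = field(default_factory=list)
    bad_channels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[0], dtype=bool)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.bad_channels.shape[0] != self.data.shape[0]:
            raise ValueError("bad-channel mask length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    @property
    def good_channels(self) -> np.ndarray:
        return ~self.bad_channels

    def event_times(self, label: str) -> np.ndarray:
        return np.array([t for t, lab in self.events if lab == label])

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording carrying new channel data."""
        return replace(self, data=np.asarray(data, float),
                       bad_channels=self.bad_channels.copy(),
                       events=list(self.events))


@dataclass
class TrialSet:
    """Epoched data (trials x channels x samples) on a common time window.

    ``window = (w0, w1)`` is in seconds relative to the epoching event
    (``t0_definition``); samples follow the half-open convention
    ``[t0 + w0, t0 + w1)`` on the sample grid, so a 5-s window at 375 Hz is
    exactly 1875 samples.
    """

    data: np.ndarray
    sampling_rate: float
    array: SensorArray
    window: tuple[float, float]
    t0_definition: str = "movement offset"
    event_times: np.ndarray | None = None
    bad_trials: np.ndarray | None = None
    bad_channels: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.bad_trials is None:
            self.bad_trials = np.zeros(self.data.shape[0], dtype=bool)
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[1], dtype=bool)

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
    def times(self) -> np.ndarray:
        """Time axis relative to the epoching event (s)."""
        return self.window[0] + np.arange(self.n_samples) / self.sampling_rate

    @property
    def good_trials(self) -> np.ndarray:
        return ~self.bad_trials

    def good_data(self) -> np.ndarray:
        """Retained trials only, good channels only."""
        return self.data[~self.bad_trials][:, ~self.bad_channels]

    def sample_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice for a sub-window (s, relative to the event)."""
        i0 = int(round((window[0] - self.window[0]) * self.sampling_rate))
        i1 = int(round((window[1] - self.window[0]) * self.sampling_rate))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(f"window {window} outside trial span {self.window}")
        return slice(i0, i1)
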