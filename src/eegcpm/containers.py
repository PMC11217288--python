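"""In-memory containers for multi-subject regional and sensor time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionalTimeSeries:
    """Parcellated source-space time series.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_epochs, n_rois, n_samples)``,
        arbitrary units.
    fs
        Sampling rate in Hz.
    roi_names
        Ordered region labels, one per ROI.
    epoch_len_s
        Epoch duration in seconds; ``n_samples == round(epoch_len_s * fs)``.
    """

    data: np.ndarray
    fs: float
    roi_names: tuple[str, ...]
    epoch_len_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                "data must be (subjects, epochs, rois, samples); got shape "
                f"{self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")
        if self.data.shape[2] != len(self.roi_names):
            raise ValueError("roi_names length does not match the ROI axis")
        expected = round(self.epoch_len_s * self.fs)
        if self.data.shape[3] != expected:
            raise ValueError(
                f"samples axis ({self.data.shape[3]}) does not equal "
                f"round(epoch_len_s * fs) = {expected}"
            )
        self.roi_names = tuple(self.roi_names)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]


@dataclass
class SensorTimeSeries:
    """Sensor-space time series: ``(n_subjects, n_epochs, n_sensors, n_samples)``."""

    data: np.ndarray
    fs: float
    epoch_len_s: float
    sensor_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                "data must be (subjects, epochs, sensors, samples); got shape "
                f"{self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.sensor_names:
            self.sensor_names = tuple(
                f"sensor_{i:03d}" for i in range(self.data.shape[2])
            )
        self.sensor_names = tuple(self.sensor_names)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[2]
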