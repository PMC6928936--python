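"""Epoch container shared by every stage of the pipeline.

An :class:`EpochArray` is a (trials, time, channels) block of real-valued EEG
with its sampling rate, the time of the first sample, and channel labels.
Simulated trials are one second at 512 Hz (512 samples); evoked-potential
trials span -300..1000 ms (666 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochArray"]


@dataclass
class EpochArray:
    """Trials x time x channels EEG block.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_times, n_channels)
        Signal values (uV-scaled; arbitrary units for simulated data).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds (0.0 for simulated trials,
        -0.3 for evoked-potential trials).
    labels : list of str
        Channel names; length must equal the channel dimension.
    """

    data: np.ndarray
    fs: float = 512.0
    t0: float = 0.0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, time, channels); got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.labels = list(self.labels)
        if self.labels and len(self.labels) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[2]} channels"
            )

    # -- basic views ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds."""
        return self.t0 + np.arange(self.n_times) / self.fs

    def power(self) -> float:
        """Mean squared amplitude over all trials, samples and channels."""
        return float(np.mean(np.square(self.data, dtype=np.float64)))

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.fs, self.t0, list(self.labels))

    def select_trials(self, idx) -> "EpochArray":
        return EpochArray(self.data[np.asarray(idx)], self.fs, self.t0, list(self.labels))

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None

    def average(self) -> "EpochArray":
        """Trial average, returned as a single-trial EpochArray."""
        return EpochArray(self.data.mean(axis=0, keepdims=True), self.fs, self.t0,
                          list(self.labels))

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Write to an HDF5 container with datasets data/fs/t0/labels."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("fs", data=self.fs)
            f.create_dataset("t0", data=self.t0)
            f.create_dataset("labels", data=np.array(self.labels, dtype="S"))

    @classmethod
    def load(cls, path) -> "EpochArray":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                fs=float(f["fs"][()]),
                t0=float(f["t0"][()]),
                labels=[s.decode() for s in f["labels"][()]],
            )
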