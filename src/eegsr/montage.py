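"""Sensor montages: 64-channel scalp layouts and the named channel subsets.

The default montage is the Biosemi ActiveTwo 64-channel layout (10-10 naming),
with electrode positions projected onto the unit scalp sphere. Down-scaled
acquisitions are represented as named subsets of 32, 16, 8 and 4 channels:
the 32- and 16-channel sets follow the Biosemi 32/16 cap layouts, the 8- and
4-channel sets are evenly spread / central picks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorMontage", "build_montage", "default_montage", "write_sfp",
           "DEFAULT_SUBSET_SIZES"]

DEFAULT_SUBSET_SIZES = (32, 16, 8, 4)

# Evenly covering 8-channel pick and central 4-channel pick (the 4-channel set
# deliberately cannot cover the head boundary).
_SUBSET8 = ["F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2"]
_SUBSET4 = ["C1", "C2", "C3", "C4"]


@dataclass
class SensorMontage:
    """Labeled unit-sphere electrode positions with named channel subsets."""

    labels: list
    positions: np.ndarray  # (n, 3), unit vectors
    subsets: dict = field(default_factory=dict)  # size -> list of labels

    def __post_init__(self):
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms <= 0):
            raise ValueError("zero-length electrode position")
        # project onto the unit scalp sphere, direction preserved
        self.positions = self.positions / norms[:, None]
        for size, labs in self.subsets.items():
            self._validate_subset(size, labs)

    def _validate_subset(self, size, labs):
        labs = list(labs)
        if len(labs) != size:
            raise ValueError(f"subset declared size {size} but has {len(labs)} labels")
        missing = [l for l in labs if l not in self.labels]
        if missing:
            raise ValueError(f"subset labels not in montage: {missing}")
        if len(set(labs)) != len(labs):
            raise ValueError("duplicate labels in subset")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, labels) -> np.ndarray:
        return np.array([self.labels.index(l) for l in labels], dtype=int)

    def subset_labels(self, k: int) -> list:
        """Channel labels for a k-channel acquisition (k may equal the full set)."""
        if k == self.n_channels:
            return list(self.labels)
        if k not in self.subsets:
            raise ValueError(f"no {k}-channel subset declared "
                             f"(have {sorted(self.subsets)} and {self.n_channels})")
        return list(self.subsets[k])


def _positions_from_mne(name: str):
    import mne

    m = mne.channels.make_standard_montage(name)
    pos = m.get_positions()["ch_pos"]
    labels = list(m.ch_names)
    return labels, np.array([pos[c] for c in labels])


def _read_sfp(path):
    import mne

    m = mne.channels.read_custom_montage(path)
    pos = m.get_positions()["ch_pos"]
    labels = list(m.ch_names)
    return labels, np.array([pos[c] for c in labels])


def write_sfp(path, labels, positions) -> None:
    """Write a standard electrode-position text file (label x y z per line)."""
    with open(path, "w") as f:
        for lab, p in zip(labels, positions):
            f.write(f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\n")


def default_subsets(labels) -> dict:
    """Named subsets (32/16/8/4) for the Biosemi-64 label set."""
    labels32, _ = _positions_from_mne("biosemi32")
    labels16, _ = _positions_from_mne("biosemi16")
    subsets = {32: labels32, 16: labels16, 8: list(_SUBSET8), 4: list(_SUBSET4)}
    for size, labs in subsets.items():
        missing = [l for l in labs if l not in labels]
        if missing:
            raise ValueError(f"default {size}-channel subset not contained "
                             f"in montage: {missing}")
    return subsets


def build_montage(layout_file=None, subset_spec=None) -> SensorMontage:
    """Build a montage from an electrode-position text file (.sfp style).

    Parameters
    ----------
    layout_file : path or None
        Text file with one ``label x y z`` entry per electrode. ``None`` uses
        the bundled Biosemi-64 layout.
    subset_spec : dict or None
        Mapping ``size -> list of labels``. ``None`` installs the default
        32/16/8/4 subsets when the labels allow it.
    """
    if layout_file is None:
        labels, positions = _positions_from_mne("biosemi64")
    else:
        labels, positions = _read_sfp(layout_file)
    if subset_spec is None:
        try:
            subset_spec = default_subsets(labels)
        except ValueError:
            subset_spec = {}
    return SensorMontage(labels, positions, dict(subset_spec))


def default_montage() -> SensorMontage:
    """The Biosemi-64 montage with the default 32/16/8/4 subsets."""
    return build_montage()
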