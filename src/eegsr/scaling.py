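"""Spatial down-scaling and the interpolated low-resolution baseline.

A k-channel acquisition is emulated by keeping the montage's k-channel subset.
The low-resolution (LR) 64-channel data -- both the conventional comparison
method and the network input -- restores missing channels by inverse
geodesic-distance weighted averaging of the nearest retained electrodes, a
parameter-free linear interpolation on the scalp sphere. Retained channels
pass through unchanged.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochArray
from .montage import SensorMontage

__all__ = ["select_channels", "interpolate_lr", "interpolation_matrix"]


def select_channels(epochs: EpochArray, montage: SensorMontage, k: int) -> EpochArray:
    """Keep only the declared k-channel subset (data values unchanged)."""
    labels = montage.subset_labels(k)  # raises for undeclared k
    idx = [epochs.channel_index(l) for l in labels]
    return EpochArray(epochs.data[:, :, idx], epochs.fs, epochs.t0, labels)


def _geodesic(p, q):
    """Great-circle distance between unit vectors (rows of p vs rows of q)."""
    return np.arccos(np.clip(p @ q.T, -1.0, 1.0))


def interpolation_matrix(montage: SensorMontage, subset_labels,
                         n_neighbors: int = 4) -> np.ndarray:
    """Linear map W (full x subset) restoring all montage channels.

    Retained rows are unit rows (pass-through); each missing channel is an
    inverse-geodesic-distance weighted average of its ``n_neighbors`` nearest
    retained electrodes, weights normalized to sum to one. For very small
    subsets the neighbor count is capped at the subset size.
    """
    subset_labels = list(subset_labels)
    if not subset_labels:
        raise ValueError("subset is empty")
    n_neighbors = min(n_neighbors, len(subset_labels))
    if n_neighbors < 1:
        raise ValueError("need at least one neighbor")
    sub_idx = montage.index_of(subset_labels)
    full_pos = montage.positions
    sub_pos = full_pos[sub_idx]
    W = np.zeros((montage.n_channels, len(subset_labels)))
    retained = {j: i for i, j in enumerate(sub_idx)}
    d = _geodesic(full_pos, sub_pos)
    for ch in range(montage.n_channels):
        if ch in retained:
            W[ch, retained[ch]] = 1.0
            continue
        order = np.argsort(d[ch])[:n_neighbors]
        w = 1.0 / np.maximum(d[ch, order], 1e-12)
        W[ch, order] = w / w.sum()
    return W


def interpolate_lr(subset_epochs: EpochArray, montage: SensorMontage,
                   n_neighbors: int = 4) -> EpochArray:
    """Interpolate a channel subset back to the full montage (LR data).

    Output has all montage channels in montage order; retained channels are
    copied through, missing ones are convex combinations of their nearest
    retained neighbors.
    """
    missing = [l for l in subset_epochs.labels if l not in montage.labels]
    if missing:
        raise ValueError(f"subset labels not in montage: {missing}")
    W = interpolation_matrix(montage, subset_epochs.labels, n_neighbors)
    data = subset_epochs.data @ W.T
    return EpochArray(data, subset_epochs.fs, subset_epochs.t0, list(montage.labels))
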