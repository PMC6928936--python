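"""Array-gain minimum-variance beamformer scanning of a voxel grid.

The brain shell is scanned on a regular lattice (default 5 mm). For each
voxel the leadfield triplet (columns = unit x/y/z dipoles) is column-wise
unit-normalized -- the array-gain constraint -- and the beamformer output
power maximized over dipole orientation is

    P(v) = 1 / lambda_min( L(v)' C^-1 L(v) ),

the reciprocal of the smallest generalized eigenvalue of the projected
inverse covariance. Maps are normalized to unit maximum, thresholded
(0.3 for simulated single trials, 0.1 for evoked averages), and peaks are
local maxima of the active set over the 26-neighborhood, merged below a
minimum separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import cho_factor, cho_solve

from .containers import EpochArray
from .headmodel import HeadModel, compute_leadfield

__all__ = [
    "SourceGrid",
    "SourceMap",
    "build_source_grid",
    "compute_covariance",
    "agmv_scan",
    "normalize_threshold_detect",
    "localize",
]


@dataclass
class SourceGrid:
    """Regular lattice of scan points strictly inside the brain shell."""

    positions_mm: np.ndarray  # (V, 3)
    spacing_mm: float
    head: HeadModel

    @property
    def n_voxels(self) -> int:
        return self.positions_mm.shape[0]

    @property
    def positions_normalized(self) -> np.ndarray:
        """Voxel positions in scalp-normalized units (for the forward model)."""
        return self.positions_mm / self.head.scalp_radius_mm

    def lattice_indices(self) -> np.ndarray:
        """Integer lattice coordinates of each voxel (offset to start at 0)."""
        ijk = np.round(self.positions_mm / self.spacing_mm).astype(int)
        return ijk - ijk.min(axis=0)


@dataclass
class SourceMap:
    """Per-voxel beamformer power with normalization/threshold state."""

    grid: SourceGrid
    power: np.ndarray  # (V,), non-negative
    normalized: bool = False
    threshold: float | None = None
    active: np.ndarray | None = None  # boolean (V,)
    peaks: list = field(default_factory=list)  # [(position_mm (3,), amplitude)]

    @property
    def peak_positions(self) -> np.ndarray:
        if not self.peaks:
            return np.zeros((0, 3))
        return np.array([p for p, _ in self.peaks])

    @property
    def n_active(self) -> int:
        return 0 if self.active is None else int(self.active.sum())

    def to_frame(self):
        """Tabular view (x_mm, y_mm, z_mm, power, active) for CSV export."""
        import pandas as pd

        act = self.active if self.active is not None else np.zeros(self.grid.n_voxels, bool)
        return pd.DataFrame({
            "x_mm": self.grid.positions_mm[:, 0],
            "y_mm": self.grid.positions_mm[:, 1],
            "z_mm": self.grid.positions_mm[:, 2],
            "power": self.power,
            "active": act,
        })


def build_source_grid(head: HeadModel, spacing_mm: float = 5.0) -> SourceGrid:
    """Lattice voxels (multiples of the spacing, origin included) inside the brain."""
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    r_mm = head.brain_radius_mm
    if spacing_mm > 2 * r_mm:
        raise ValueError("spacing exceeds the brain diameter")
    n = int(np.floor(r_mm / spacing_mm))
    ax = np.arange(-n, n + 1) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pos = pos[np.linalg.norm(pos, axis=1) < r_mm]
    return SourceGrid(pos, float(spacing_mm), head)


def compute_covariance(epochs: EpochArray, window: tuple | None = None,
                       loading: float = 1e-3) -> np.ndarray:
    """Sample covariance over a time window, pooled over trials, plus loading.

    ``window`` is (t_start, t_end) in seconds against the epoch's time axis
    (inclusive of samples within); ``loading`` adds loading * trace/N to the
    diagonal, stabilizing single-trial covariances. Symmetric by construction.
    """
    t = epochs.times
    if window is None:
        mask = np.ones(epochs.n_times, bool)
    else:
        mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 2:
        raise ValueError("covariance window must contain at least 2 samples")
    X = epochs.data[:, mask, :]  # (trials, T, C)
    X = X - X.mean(axis=1, keepdims=True)
    n_eff = X.shape[0] * (X.shape[1] - 1)
    C = np.einsum("btc,btd->cd", X, X) / n_eff
    C = 0.5 * (C + C.T)
    if loading:
        C = C + loading * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
    return C


def agmv_scan(cov: np.ndarray, leadfield: np.ndarray, grid: SourceGrid) -> SourceMap:
    """Scan the grid with the array-gain minimum-variance beamformer.

    ``leadfield`` is (sensors, voxels, 3) as returned by
    :func:`eegsr.headmodel.compute_leadfield`. Columns are unit-normalized
    per voxel/orientation; the per-voxel power is the reciprocal smallest
    eigenvalue of L' C^-1 L (orientation maximizing output power).
    """
    S, V, _ = leadfield.shape
    if cov.shape != (S, S):
        raise ValueError("covariance does not match the leadfield sensor count")
    L = leadfield / np.linalg.norm(leadfield, axis=0, keepdims=True)
    try:
        cf = cho_factor(cov)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("covariance is singular; add diagonal loading") from e
    K = cho_solve(cf, L.reshape(S, V * 3)).reshape(S, V, 3)
    M = np.einsum("svi,svj->vij", L, K)
    lam = np.linalg.eigvalsh(M)[:, 0]  # smallest eigenvalue per voxel
    power = 1.0 / np.maximum(lam, np.finfo(float).tiny)
    return SourceMap(grid=grid, power=power)


def normalize_threshold_detect(smap: SourceMap, threshold: float = 0.3,
                               min_separation_mm: float = 20.0) -> SourceMap:
    """Normalize a map to unit maximum, threshold it, and detect peaks.

    Peaks are 26-neighborhood local maxima within the active set
    (power > threshold); peaks closer than ``min_separation_mm`` are merged,
    keeping the stronger one.
    """
    pmax = smap.power.max()
    if pmax <= 0:
        raise ValueError("cannot normalize an all-zero source map")
    power = smap.power / pmax
    active = power > threshold
    grid = smap.grid
    ijk = grid.lattice_indices()
    shape = tuple(ijk.max(axis=0) + 1)
    vol = np.full(shape, -np.inf)
    vol[tuple(ijk.T)] = power
    local_max = vol >= ndimage.maximum_filter(vol, size=3, mode="constant",
                                              cval=-np.inf)
    is_peak = local_max[tuple(ijk.T)] & active
    cand = np.flatnonzero(is_peak)
    cand = cand[np.argsort(power[cand])[::-1]]  # strongest first
    peaks = []
    for v in cand:
        p = grid.positions_mm[v]
        if all(np.linalg.norm(p - q) >= min_separation_mm for q, _ in peaks):
            peaks.append((p, float(power[v])))
    return SourceMap(grid=grid, power=power, normalized=True, threshold=threshold,
                     active=active, peaks=peaks)


def localize(epochs: EpochArray, montage, head: HeadModel, grid: SourceGrid | None = None,
             leadfield: np.ndarray | None = None, window: tuple | None = None,
             loading: float = 1e-3, threshold: float = 0.3,
             min_separation_mm: float = 20.0, n_terms: int = 100) -> SourceMap:
    """Covariance -> scan -> normalize/threshold/detect, for one trial set."""
    if grid is None:
        grid = build_source_grid(head)
    if leadfield is None:
        leadfield = compute_leadfield(grid.positions_normalized, montage, head, n_terms)
    cov = compute_covariance(epochs, window=window, loading=loading)
    raw = agmv_scan(cov, leadfield, grid)
    return normalize_threshold_detect(raw, threshold, min_separation_mm)
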