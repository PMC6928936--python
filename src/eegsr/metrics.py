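"""Sensor- and source-level evaluation metrics.

Sensor level: per-trial MSE and Pearson correlation against the reference
(noiseless) signal, evoked-component (N1/P2) amplitudes and latencies, their
summed absolute errors, and a pointwise paired t-test between conditions.

Source level: amplitude error within regions of interest around the reference
peaks, Euclidean localization error between matched peaks, focality
(reciprocal active-voxel count), and the error-source count (peaks present in
one map but missing in the other under a distance matching rule).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .containers import EpochArray

__all__ = [
    "ErpComponent",
    "MetricsReport",
    "N1_DEFAULT",
    "P2_DEFAULT",
    "mse",
    "pearson",
    "amplitude_error",
    "localization_error",
    "focality",
    "extract_erp",
    "sensor_component_errors",
    "error_source_count",
    "pointwise_ttest",
]


@dataclass
class ErpComponent:
    """Evoked-component search specification (window in seconds post-stimulus)."""

    name: str
    window: tuple
    polarity: str  # "negative" | "positive"

    def __post_init__(self):
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        if not self.window[0] < self.window[1]:
            raise ValueError("window must be increasing")


#: default N1/P2 search windows, consistent with auditory-evoked latencies
N1_DEFAULT = ErpComponent("N1", (0.040, 0.110), "negative")
P2_DEFAULT = ErpComponent("P2", (0.110, 0.220), "positive")


@dataclass
class MetricsReport:
    """Flat per-condition summary; serialize with to_dict()/pandas."""

    condition: str = ""
    mse: float = np.nan
    correlation: float = np.nan
    amplitude_error: float = np.nan
    localization_error: float = np.nan
    focality: float = np.nan
    latency_error: float = np.nan
    n_error_sources: float = np.nan
    n_significant_points: float = np.nan

    def to_dict(self):
        return asdict(self)


def _paired(reference, estimate):
    a = reference.data if isinstance(reference, EpochArray) else np.asarray(reference)
    b = estimate.data if isinstance(estimate, EpochArray) else np.asarray(estimate)
    if a.ndim == 2:
        a, b = a[None], b[None]
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def mse(reference, estimate) -> np.ndarray:
    """Per-trial mean squared error (averaged over time samples and channels)."""
    a, b = _paired(reference, estimate)
    return np.mean((a - b) ** 2, axis=(1, 2))


def pearson(reference, estimate) -> np.ndarray:
    """Per-trial Pearson correlation over pooled (time x channel) samples."""
    a, b = _paired(reference, estimate)
    a = a.reshape(a.shape[0], -1)
    b = b.reshape(b.shape[0], -1)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(a * a, axis=1))
    sb = np.sqrt(np.sum(b * b, axis=1))
    if np.any(sa == 0) or np.any(sb == 0):
        raise ValueError("constant trial: correlation undefined")
    return np.clip(np.sum(a * b, axis=1) / (sa * sb), -1.0, 1.0)


# ---------------------------------------------------------------------------
# source level
# ---------------------------------------------------------------------------

def _roi_max(smap, center_mm, radius_mm):
    d = np.linalg.norm(smap.grid.positions_mm - np.asarray(center_mm), axis=1)
    sel = d <= radius_mm
    if not sel.any():
        raise ValueError("empty ROI: no voxel within the radius")
    return float(smap.power[sel].max())


def amplitude_error(map_ref, map_est, roi_centers_mm=None,
                    roi_radius_mm: float = 20.0) -> float:
    """Mean |max normalized amplitude difference| over ROIs around reference peaks.

    Both maps are renormalized to unit maximum before comparison, so a
    uniformly rescaled estimate has zero error. ``roi_centers_mm`` defaults to
    the reference map's detected peaks.
    """
    if roi_centers_mm is None:
        roi_centers_mm = map_ref.peak_positions
    centers = np.atleast_2d(np.asarray(roi_centers_mm, dtype=float))
    if centers.size == 0:
        raise ValueError("no ROI centers: reference map has no peaks")
    pr = map_ref.power / map_ref.power.max()
    pe = map_est.power / map_est.power.max()
    ref_n = type(map_ref)(grid=map_ref.grid, power=pr)
    est_n = type(map_est)(grid=map_est.grid, power=pe)
    errs = [abs(_roi_max(ref_n, c, roi_radius_mm) - _roi_max(est_n, c, roi_radius_mm))
            for c in centers]
    return float(np.mean(errs))


def _greedy_match(pos_a, pos_b):
    """Greedy nearest pairing of two peak sets; returns index pairs."""
    pairs = []
    used_b = set()
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    for _ in range(min(len(pos_a), len(pos_b))):
        masked = d.copy()
        for i, j in pairs:
            masked[i, :] = np.inf
        for j in used_b:
            masked[:, j] = np.inf
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        if not np.isfinite(masked[i, j]):
            break
        pairs.append((i, j))
        used_b.add(j)
    return pairs


def localization_error(map_ref, map_est) -> float:
    """Mean Euclidean distance (mm) between greedily matched peak positions."""
    pa, pb = map_ref.peak_positions, map_est.peak_positions
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("both maps need at least one detected peak")
    pairs = _greedy_match(pa, pb)
    return float(np.mean([np.linalg.norm(pa[i] - pb[j]) for i, j in pairs]))


def focality(smap) -> float:
    """Reciprocal of the number of voxels above the map's threshold."""
    if smap.active is None:
        raise ValueError("map has not been thresholded")
    n = int(smap.active.sum())
    if n == 0:
        raise ValueError("no active voxels: focality undefined")
    return 1.0 / n


def error_source_count(map_ref, map_est, match_radius_mm: float = 20.0) -> int:
    """Peaks detected in one map with no counterpart within the radius in the other.

    Accepts SourceMaps or raw (n, 3) peak-position arrays.
    """
    pa = map_ref.peak_positions if hasattr(map_ref, "peak_positions") else np.atleast_2d(map_ref)
    pb = map_est.peak_positions if hasattr(map_est, "peak_positions") else np.atleast_2d(map_est)
    pa = pa.reshape(-1, 3)
    pb = pb.reshape(-1, 3)
    if len(pa) == 0 or len(pb) == 0:
        return len(pa) + len(pb)
    pairs = _greedy_match(pa, pb)
    matched = [(i, j) for i, j in pairs
               if np.linalg.norm(pa[i] - pb[j]) <= match_radius_mm]
    return (len(pa) - len(matched)) + (len(pb) - len(matched))


# ---------------------------------------------------------------------------
# evoked components
# ---------------------------------------------------------------------------

def extract_erp(average: EpochArray, component: ErpComponent, channel: str):
    """Amplitude (magnitude) and latency (ms) of an evoked component.

    ``average`` is a trial-averaged EpochArray (single trial dimension). The
    amplitude is the extremum of the matching polarity inside the search
    window; the latency is its time in ms post-stimulus. A flat-zero window
    yields zero amplitude at the window start.
    """
    if average.n_trials != 1:
        raise ValueError("pass a trial average (one trial); use .average()")
    t = average.times
    mask = (t >= component.window[0]) & (t <= component.window[1])
    if not mask.any():
        raise ValueError("component window outside the epoch")
    x = average.data[0, mask, average.channel_index(channel)]
    tw = t[mask]
    if np.all(x == 0):
        return 0.0, float(tw[0] * 1000.0)
    i = np.argmin(x) if component.polarity == "negative" else np.argmax(x)
    return float(abs(x[i])), float(tw[i] * 1000.0)


def sensor_component_errors(hr_erp: dict, d_erp: dict):
    """Summed absolute amplitude and latency errors over the N1 and P2 components.

    Inputs map component name -> (amplitude, latency_ms).
    Returns (amplitude_error, latency_error_ms).
    """
    amp_err = lat_err = 0.0
    for k in ("N1", "P2"):
        if k not in hr_erp or k not in d_erp:
            raise KeyError(f"missing component {k}")
        amp_err += abs(hr_erp[k][0] - d_erp[k][0])
        lat_err += abs(hr_erp[k][1] - d_erp[k][1])
    return amp_err, lat_err


# ---------------------------------------------------------------------------
# pointwise statistics
# ---------------------------------------------------------------------------

def pointwise_ttest(paired_a: EpochArray, paired_b: EpochArray,
                    downsample: int = 8, alpha: float = 0.01):
    """Paired t-test per retained time sample and channel (uncorrected).

    Trials are paired across the two inputs; the time axis is decimated by
    keeping every ``downsample``-th sample starting at the first (ceil(T/f)
    points). Returns a boolean mask (kept_samples, channels) of p < alpha;
    samples with zero within-pair variance are flagged non-significant.
    """
    a, b = _paired(paired_a, paired_b)
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")
    a = a[:, ::downsample, :]
    b = b[:, ::downsample, :]
    d = a - b
    degenerate = np.all(d == d[:1], axis=0)  # zero within-pair variance
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_rel(a, b, axis=0)
    mask = np.where(degenerate, False, p < alpha)
    return mask
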