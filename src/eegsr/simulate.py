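"""Simulated multichannel EEG: clean dipole trials plus SNR-controlled noise.

Two dipoles, one per hemisphere and far enough apart to localize separately,
drive the clean signal; each trial is one second at 512 Hz. The clean data
are normalized to unit mean-square power so that the signal-to-noise ratio is
exactly the reciprocal of the added noise power (and the sensor MSE of the
noisy data against the noiseless data equals 1/SNR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import EpochArray
from .headmodel import DipoleSource, HeadModel, three_shell_potential

__all__ = [
    "NoiseSpec",
    "SNR_GRID",
    "default_dipoles",
    "simulate_clean_trials",
    "add_noise",
    "one_over_f_noise",
    "random_spatial_mixing",
]

#: Signal-to-noise power ratios studied by default.
SNR_GRID = (100, 50, 10, 5, 1, 0.5, 0.1, 0.05, 0.01)

FS = 512.0
TRIAL_SAMPLES = 512


@dataclass
class NoiseSpec:
    """Additive noise description.

    ``kind`` is ``white_gaussian`` or ``brain_surrogate`` (1/f^alpha spectrum,
    low-frequency dominant, optionally spatially mixed across channels);
    ``snr`` is the target ratio of clean signal power to noise power.
    """

    kind: str = "white_gaussian"
    snr: float = 5.0
    spectral_exponent: float = 1.0
    spatial_mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("white_gaussian", "brain_surrogate"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def default_dipoles(n_samples: int = TRIAL_SAMPLES, fs: float = FS) -> list:
    """The default two-dipole configuration.

    One dipole per hemisphere at (+-0.55, 0, 0.35) scalp-normalized units with
    tangential (y-directed) orientations. The waveforms are amplitude-modulated
    8 Hz and 12 Hz sinusoids with distinct smooth envelopes, so the two sources
    are separable in time and space.
    """
    t = np.arange(n_samples) / fs
    env1 = np.sin(np.pi * t / t[-1]) ** 2
    env2 = np.sin(np.pi * np.minimum(2 * t / t[-1], 2 - 2 * t / t[-1]) / 1.0) ** 2
    w1 = env1 * np.sin(2 * np.pi * 8.0 * t)
    w2 = env2 * np.sin(2 * np.pi * 12.0 * t + 0.7)
    return [
        DipoleSource(position=(-0.55, 0.0, 0.35), orientation=(0.0, 1.0, 0.0), waveform=w1),
        DipoleSource(position=(0.55, 0.0, 0.35), orientation=(0.0, -1.0, 0.0), waveform=w2),
    ]


def simulate_clean_trials(dipoles, montage, head: HeadModel, n_trials: int = 1,
                          n_terms: int = 100, normalize_power: bool = True,
                          fs: float = FS) -> EpochArray:
    """Noiseless sensor trials: sum over dipoles of pattern x waveform.

    Every trial is identical before noise. With ``normalize_power`` the mean
    squared amplitude over all samples and channels is scaled to 1 (unless the
    signal is identically zero), so added noise power is interpretable as
    1/SNR.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not dipoles:
        raise ValueError("need at least one dipole")
    lengths = {len(d.waveform) for d in dipoles}
    if len(lengths) != 1:
        raise ValueError(f"dipole waveforms have mismatched lengths {sorted(lengths)}")
    n_samples = lengths.pop()
    trial = np.zeros((n_samples, montage.n_channels))
    for dip in dipoles:
        pattern = three_shell_potential(dip, montage, head, n_terms=n_terms)
        trial += np.outer(dip.waveform, pattern)
    if normalize_power:
        p = np.mean(trial**2)
        if p > 0:
            trial = trial / np.sqrt(p)
    data = np.broadcast_to(trial, (n_trials, n_samples, montage.n_channels)).copy()
    return EpochArray(data, fs=fs, t0=0.0, labels=list(montage.labels))


def one_over_f_noise(rng, shape, fs: float, alpha: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum along the time axis.

    ``shape`` is (..., n_times); spectra are shaped in the Fourier domain
    (DC removed), giving the low-frequency-dominant character of background
    EEG. Unit variance on average.
    """
    *lead, n = shape
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-alpha / 2.0)
    z = rng.standard_normal((*lead, freqs.size)) + 1j * rng.standard_normal((*lead, freqs.size))
    x = np.fft.irfft(z * amp, n=n, axis=-1)
    x /= x.std()
    return x


def random_spatial_mixing(n_channels: int, strength: float = 0.5,
                          seed: int = 0) -> np.ndarray:
    """Channel-mixing matrix interpolating identity -> random orthogonal.

    ``strength`` 0 leaves channels independent; 1 fully mixes them through a
    random orthogonal rotation (preserving total power).
    """
    from scipy.linalg import fractional_matrix_power
    from scipy.stats import ortho_group

    q = ortho_group.rvs(n_channels, random_state=np.random.default_rng(seed))
    m = np.real(fractional_matrix_power(q, strength))
    return m


def add_noise(clean: EpochArray, spec: NoiseSpec) -> EpochArray:
    """Return clean + noise with an exact empirical signal-to-noise ratio.

    The noise realization is independent per trial; it is scaled so that the
    measured power ratio P(clean)/P(noise), pooled over all trials, samples
    and channels, equals ``spec.snr`` exactly.
    """
    p_clean = clean.power()
    if p_clean <= 0:
        raise ValueError("clean input has zero power; SNR is undefined")
    rng = np.random.default_rng(spec.seed)
    shape = clean.data.shape  # (trials, time, channels)
    if spec.kind == "white_gaussian":
        noise = rng.standard_normal(shape)
    else:
        noise = one_over_f_noise(
            rng, (shape[0], shape[2], shape[1]), clean.fs, spec.spectral_exponent
        ).transpose(0, 2, 1)
        if spec.spatial_mixing is not None:
            noise = noise @ np.asarray(spec.spatial_mixing).T
    p_noise = np.mean(noise**2)
    noise *= np.sqrt(p_clean / (spec.snr * p_noise))
    return EpochArray(clean.data + noise, clean.fs, clean.t0, list(clean.labels))
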