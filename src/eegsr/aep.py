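"""Synthetic auditory-evoked-potential (AEP) datasets.

Emulates the structure of a 64-channel auditory oddball-free AEP recording:
trials span -300..1000 ms at 512 Hz (666 samples), two dipoles in bilateral
temporal cortex drive a biphasic waveform whose negative lobe is the N1
(~70 ms) and positive lobe the P2 (~140 ms), with per-trial latency and
amplitude jitter, on top of low-frequency-dominant (1/f) background noise.
The generator returns the clean and noisy data plus its ground-truth
parameters, so component extraction and source localization can be scored
against a known answer. It does not attempt to reproduce any specific
subject's recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochArray
from .headmodel import DipoleSource, HeadModel, three_shell_potential
from .simulate import NoiseSpec, one_over_f_noise

__all__ = ["AepComponentSpec", "gen_aep_trials", "estimate_snr"]

FS = 512.0
T0 = -0.3
N_SAMPLES = 666


@dataclass
class AepComponentSpec:
    """N1/P2 lobe timing and relative size, with per-trial jitter.

    Latencies/widths in seconds; amplitudes in the ratio observed at the
    vertex (P2 slightly larger than N1). ``latency_jitter`` is the standard
    deviation of a common per-trial shift; ``amplitude_jitter`` the relative
    spread of per-component gains. ``target_n1_uv`` scales the clean data so
    the noiseless trial average has that N1 magnitude at the reference
    channel.
    """

    n1_latency: float = 0.070
    n1_width: float = 0.015
    n1_amplitude: float = 5.0
    p2_latency: float = 0.140
    p2_width: float = 0.025
    p2_amplitude: float = 6.0
    #: std of the per-trial, per-hemisphere latency shift (s). Independent
    #: jitter across hemispheres decorrelates the bilateral sources, which is
    #: both realistic and what makes them separable for a minimum-variance
    #: beamformer (perfectly coherent bilateral sources cancel).
    latency_jitter: float = 0.005
    #: relative std of the per-trial, per-hemisphere, per-component gain.
    amplitude_jitter: float = 0.15
    reference_channel: str = "CPz"
    target_n1_uv: float = 5.0
    dipole_positions: tuple = ((-0.63, -0.20, 0.12), (0.63, -0.20, 0.12))
    dipole_orientations: tuple = ((0.0, 1.0, 0.0), (0.0, 1.0, 0.0))

    def __post_init__(self):
        for lat in (self.n1_latency, self.p2_latency):
            if not (0.0 < lat < 1.0):
                raise ValueError("component latencies must lie within 0-1000 ms")


def _biphasic(t, spec: AepComponentSpec, shift=0.0, g_n1=1.0, g_p2=1.0):
    n1 = -spec.n1_amplitude * g_n1 * np.exp(
        -0.5 * ((t - spec.n1_latency - shift) / spec.n1_width) ** 2)
    p2 = spec.p2_amplitude * g_p2 * np.exp(
        -0.5 * ((t - spec.p2_latency - shift) / spec.p2_width) ** 2)
    w = n1 + p2
    w[t < 0] = 0.0  # pre-stimulus interval carries noise only
    return w


def gen_aep_trials(montage, head: HeadModel, n_trials: int = 932,
                   component_spec: AepComponentSpec | None = None,
                   noise: NoiseSpec | None = None, seed: int = 0,
                   n_terms: int = 100):
    """Generate clean and noisy AEP-like trials.

    Returns ``(clean, noisy, truth)`` where ``truth`` records the dipoles,
    per-trial jitters and the applied scale. ``noise.snr`` is the ratio of
    post-stimulus signal power to noise power; the empirical post/pre-stimulus
    power ratio of the noisy data estimates ``1 + snr``.
    """
    spec = component_spec or AepComponentSpec()
    noise = noise or NoiseSpec(kind="brain_surrogate", snr=1.2, seed=seed)
    rng = np.random.default_rng(seed)
    t = T0 + np.arange(N_SAMPLES) / FS

    dipoles = []
    patterns = []
    ref = None
    for pos, ori in zip(spec.dipole_positions, spec.dipole_orientations):
        dip = DipoleSource(position=pos, orientation=ori, waveform=np.ones(N_SAMPLES))
        pattern = three_shell_potential(dip, montage, head, n_terms=n_terms)
        # orient so the N1 lobe is negative at the reference (vertex) channel
        ref = montage.labels.index(spec.reference_channel)
        if pattern[ref] < 0:
            dip.orientation = -dip.orientation
            pattern = -pattern
        dipoles.append(dip)
        patterns.append(pattern)

    n_dip = len(patterns)
    shifts = rng.normal(0.0, spec.latency_jitter, size=(n_trials, n_dip))
    gains = np.clip(rng.normal(1.0, spec.amplitude_jitter,
                               size=(n_trials, n_dip, 2)), 0.2, None)
    clean = np.zeros((n_trials, N_SAMPLES, montage.n_channels))
    for i in range(n_trials):
        for k, pattern in enumerate(patterns):
            w = _biphasic(t, spec, shifts[i, k], gains[i, k, 0], gains[i, k, 1])
            clean[i] += np.outer(w, pattern)

    # scale so the noiseless trial average hits the target N1 magnitude at ref
    avg_ref = clean.mean(axis=0)[:, ref]
    n1_mag = np.abs(avg_ref[(t >= 0.04) & (t <= 0.11)].min())
    scale = spec.target_n1_uv / n1_mag if n1_mag > 0 else 1.0
    clean *= scale

    post = t >= 0.0
    p_sig = np.mean(clean[:, post, :] ** 2)
    nz = one_over_f_noise(rng, (n_trials, montage.n_channels, N_SAMPLES), FS,
                          noise.spectral_exponent if noise.kind == "brain_surrogate" else 0.0
                          ).transpose(0, 2, 1)
    if noise.kind == "brain_surrogate" and noise.spatial_mixing is not None:
        nz = nz @ np.asarray(noise.spatial_mixing).T
    nz *= np.sqrt(p_sig / (noise.snr * np.mean(nz ** 2)))

    labels = list(montage.labels)
    clean_ep = EpochArray(clean, fs=FS, t0=T0, labels=labels)
    noisy_ep = EpochArray(clean + nz, fs=FS, t0=T0, labels=labels)
    truth = {
        "dipoles": dipoles,
        "latency_shifts": shifts,
        "amplitude_gains": gains,
        "scale": scale,
        "component_spec": spec,
        "snr": noise.snr,
    }
    return clean_ep, noisy_ep, truth


def estimate_snr(epochs: EpochArray) -> float:
    """Post-/pre-stimulus power ratio minus one (signal-to-noise estimate).

    The pre-stimulus interval contains only noise, the post-stimulus interval
    signal plus noise, so post/pre - 1 estimates the signal-to-noise power
    ratio. Trial averaging over N trials divides the noise power by N, hence
    the amplitude SNR of an N-trial average grows like sqrt(N).
    """
    t = epochs.times
    pre = t < 0.0
    post = t >= 0.0
    if not pre.any() or not post.any():
        raise ValueError("epoch must contain both pre- and post-stimulus samples")
    p_pre = np.mean(epochs.data[:, pre, :] ** 2)
    p_post = np.mean(epochs.data[:, post, :] ** 2)
    if p_pre <= 0:
        raise ValueError("zero pre-stimulus power")
    return float(p_post / p_pre - 1.0)
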