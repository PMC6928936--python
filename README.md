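# eegsr — EEG spatial super-resolution

`eegsr` studies whether a convolutional network can recover high-density
(64-channel) EEG from a low-density recording. It is aimed at EEG
methodologists who want to quantify, under controlled conditions, what a
learned channel up-sampler preserves — at the sensor level (waveforms,
evoked components) and at the source level (beamformer localization) — and
how it compares with plain spatial interpolation.

The package contains the whole study apparatus, no external data required:

* **Forward simulation** — a three-concentric-shell spherical head model
  (brain/skull/scalp, relative radii 0.87/0.92/1.0, conductivities
  1/0.0125/1) with the classical Legendre-series dipole solution; two
  hemispheric dipoles drive one-second 64-channel trials at 512 Hz, plus
  white Gaussian or 1/f "brain-like" noise scaled to an exact SNR grid
  (100 … 0.01).
* **Down-scaling** — Biosemi-style 32/16/8/4-channel subsets; the
  low-resolution (LR) baseline restores missing channels by inverse
  geodesic-distance interpolation of the nearest retained electrodes.
* **Super-resolution (SR) network** — an encoder (3 convolutions, 13×5
  kernels, 64 filters, stride 2), decoder (3 transposed convolutions, 13×9,
  64 filters, stride-2 up-sampling) and integration head (13×5/64 then
  7×1/1, stride 1) with *linear* activations, He initialization, MSE loss
  and Adam (lr 5·10⁻⁴), trained LR→HR for a fixed epoch budget keyed to the
  SNR. Implemented in pure NumPy (im2col + BLAS), bit-reproducible from the
  seed.
* **Source analysis** — an array-gain minimum-variance beamformer,
  P(v) = 1/λ_min(L̃ᵀC⁻¹L̃) on a 5 mm grid, with normalized, thresholded maps
  and peak detection.
* **Metrics** — per-trial MSE and Pearson correlation against the noiseless
  ground truth; source amplitude error, localization error, focality
  (reciprocal active-voxel count) and error-source counts; N1/P2 amplitude
  and latency extraction with pointwise paired t-tests for the synthetic
  auditory-evoked (AEP) regime (666-sample trials, −300…1000 ms).

## Worked example

```python
import numpy as np, eegsr

montage = eegsr.default_montage()
head = eegsr.HeadModel()

clean = eegsr.simulate_clean_trials(eegsr.default_dipoles(), montage, head, n_trials=200)
noisy = eegsr.add_noise(clean, eegsr.NoiseSpec(snr=5.0, seed=11))        # HR
lr = eegsr.interpolate_lr(eegsr.select_channels(noisy, montage, 16), montage)

(tr, va, te), = eegsr.split_trials(200, eegsr.SplitSpec(seed=1, n_repeats=1))
cfg = eegsr.SRConfig(max_epochs=80, batch_size=4, patch_len=64, seed=3)
model = eegsr.SRNetwork(cfg)
eegsr.train_sr(model, lr.select_trials(tr[:32]), noisy.select_trials(tr[:32]), cfg)
sr = eegsr.apply_sr(model, lr.select_trials(te[:24]))

ct = clean.select_trials(te[:24])
for name, est in [("HR", noisy.select_trials(te[:24])), ("LR", lr.select_trials(te[:24])), ("SR", sr)]:
    print(name, "mse %.4f corr %.4f" % (eegsr.mse(ct, est).mean(), eegsr.pearson(ct, est).mean()))
```

prints (one-CPU run, ~9 minutes of training):

```
HR mse 0.1997 corr 0.9130
LR mse 0.1700 corr 0.9110
SR mse 0.0571 corr 0.9830
```

Read: the noisy 64-channel data (HR) sit at the 1/SNR = 0.2 noise floor; the
interpolated 16-channel baseline (LR) is slightly better in MSE but *worse*
in correlation; the network output (SR) track the noiseless signal far more
closely on both measures — it has learned to undo the interpolation error
*and* to suppress noise. At the source level the story is sharper: an
array-gain beamformer on SR trials finds exactly the two simulated dipoles
(focality ≈ 0.05), while interpolated LR trials yield only spurious peaks:

```python
grid = eegsr.build_source_grid(head, 5.0)
lf = eegsr.compute_leadfield(grid.positions_normalized, montage, head)
smap = eegsr.localize(sr.select_trials([0]), montage, head, grid, lf)
print(len(smap.peaks), smap.peak_positions)   # 2  [[-55. 0. 35.] [50. 0. 35.]]
```

(the true sources sit at (±55, 0, 35) mm; one peak lands on the exact voxel,
the other one grid step away).

A `click` CLI mirrors the stages (`eegsr simulate | simulate-aep | downscale |
train | apply | localize | evaluate | run`); `eegsr run config.yaml --out dir`
executes the full pipeline from a YAML config and persists every artifact.

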