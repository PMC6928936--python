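# Methods

## Volume conductor and forward solution

The head is three concentric spheres — brain, skull, scalp — with relative
radii (0.87, 0.92, 1.0) and relative conductivities (1, 0.0125, 1). Positions
are scalp-normalized; `scalp_radius_mm` (default 100 mm, the model's own
scale choice since only relative radii are defined) converts source-space
distances to millimetres, so the brain radius is 87 mm.

For spherical geometry the dipole forward problem is solved exactly by a
Legendre series: the free-medium dipole potential is expanded about the
origin, and each harmonic degree n is propagated through the shells by a
5×5 linear system expressing continuity of potential and radial current at
the two interfaces and zero radial current at the scalp (insulating air).
A boundary-element discretization would add numerical error on spheres
without adding generality, which is why the series is used. Truncation is at
100 terms by default; terms decay like (r_dipole)^n (scalp radius 1), so for
sources at radius ≤ 0.8 the truncation error is below 1e-9. The solver is
validated against the closed-form homogeneous-sphere potential (all
conductivities equal), an algebraically independent expression obtained by
summing the series' generating functions; agreement is required at 1e-6
relative over all sensors and is ~1e-15 in practice. Sensor potentials are
always average-referenced.

Electrode positions come from the standard Biosemi-64 (10-10 naming) layout,
projected to the unit sphere; `.sfp`-style text layouts are also accepted.
Channel subsets: Biosemi-32 and Biosemi-16 label sets, an evenly spread
8-channel set {F3, F4, C3, C4, P3, P4, O1, O2}, and a deliberately central
4-channel set {C1, C2, C3, C4} that cannot cover the head boundary.

## Simulated trials and noise

Two dipoles, one per hemisphere at (±0.55, 0, 0.35) with tangential
(y-directed) orientations, drive amplitude-modulated 8 Hz and 12 Hz
sinusoids with distinct envelopes — far enough apart to be separable by a
beamformer, close enough in character to evoked activity to be meaningful.
The exact configuration behind the original study is shown only graphically,
so these defaults are stand-ins, chosen once and fully configurable; several
reported quantities (notably the interpolation error of the LR baseline) are
sensitive to this choice — see Limitations.

Clean trials are identical across repetitions and normalized to unit
mean-square power, so that after adding noise scaled to a signal-to-noise
power ratio δ the HR-versus-noiseless MSE is exactly 1/δ. The SNR grid is
{100, 50, 10, 5, 1, 0.5, 0.1, 0.05, 0.01}; the measured power ratio is exact
by construction (noise is rescaled to the empirical clean power). Noise is
white Gaussian or a "brain-like" surrogate: per-channel Gaussian noise shaped
to a 1/f^α spectrum (α = 1 by default, giving the low-frequency dominance of
resting EEG), optionally mixed across channels by a fractional power of a
random orthogonal matrix. A real resting-state recording cannot be shipped;
the surrogate reproduces its spectral character but not its spatial
covariance structure or artifacts, so conclusions about real brain noise
transfer only qualitatively.

## Down-scaling and the LR baseline

A k-channel acquisition keeps the declared subset. The low-resolution
baseline (also the network input) restores each missing channel as an
inverse geodesic-distance weighted average of its 4 nearest retained
electrodes (3 for the 4-channel subset), weights normalized to one —
parameter-free, linear, and exact on retained channels. Spherical-spline or
Laplacian interpolation is deliberately out of scope: the baseline is meant
to be the simplest linear scheme.

## Super-resolution network

Input and output are (time × 64 channels) epochs. Architecture: encoder of
three 13×5 (time × channel) convolutions, 64 filters, stride 2 in both axes;
decoder of three 13×9 transposed convolutions, 64 filters, stride-2
up-sampling; integration head of a 13×5/64-filter stride-1 convolution
followed by 7×1/1-filter — 2,241,473 parameters. All activations are linear
(y = x): EEG is unbounded in both signs, and saturating or one-sided
nonlinearities destroy the regression; the network is then an affine
operator end to end, which is also exploited by the linearity tests.
Transposed convolutions introduce checkerboard patterns; the integration
convolutions smooth them and crop the output to the input length. The time
axis is reflect-padded to a multiple of 8 before the encoder, so any length
≥ 8 works (512 for simulated, 666 for evoked trials).

Training: elementwise MSE toward the *noisy* HR data, He initialization,
Adam at learning rate 5e-4 (β = 0.9/0.999). The stopping rule is a fixed
epoch budget keyed to the condition — 40 (SNR 100, 50), 80 (10, 5),
150 (1), 200 (0.5, 0.1), 500 (0.05, 0.01), 300 for evoked data — with one
epoch meaning one pass over the training trials (the budget counts of 40-500
only make sense as passes, not minibatch steps). Validation loss is recorded
but never triggers stopping. Splits are 64/16/20% train/val/test
(floor-rounded: 1000 → 640/160/200, 932 → 596/150/186), five seeded repeats.

The implementation is pure NumPy: im2col + single-threaded BLAS GEMMs with
hand-derived backward passes (transposed convolution realized as the adjoint
of a strided convolution, so forward/backward share one pair of kernels).
Gradients are verified against central finite differences. Runs are
bit-reproducible from the seed on one thread.

### Problem sizes (desk scale)

A full forward pass of one 512×64 trial costs ~29 GFLOP, so the package's
default experiment sizes are chosen for a single CPU: training uses 32
trials with random 64-sample temporal patches (the network is fully
convolutional, so filters learned on patches apply at any length — the same
patch-training argument used throughout image super-resolution), batch size
4, keeping the 80-epoch SNR-5 schedule; evaluation applies the trained
network to full-length held-out trials. With these sizes the SNR-5 training
run takes ~12 minutes and reaches the error floor set by the task itself (see
Limitations); larger training sets sharpen nothing qualitative here because
the clean signal is identical across trials and only the noise realizations
differ. `scripts/acceptance.py` states its sizes as constants at the top.

## Beamformer

Scanning grid: a regular lattice (default 5 mm) of points strictly inside
the brain shell (22,119 voxels at 5 mm/87 mm). For each voxel the leadfield
triplet is column-wise unit-normalized (the array-gain constraint, which
removes the depth bias of unit-gain minimum variance), and the output power
maximized over orientation is P(v) = 1/λ_min(L̃ᵀC⁻¹L̃). The covariance is the
pooled sample covariance over a time window (whole trial for simulated data;
the N1-P2 window for evoked averages) with diagonal loading 1e-3 × trace/N —
needed because a single 512-sample trial gives a marginally conditioned
64×64 covariance. Maps are normalized to unit maximum and thresholded at 0.3
(simulated single trials) or 0.1 (evoked averages); peaks are 26-neighborhood
local maxima in the active set, merged below 20 mm separation. A detection is
"correct" when it has a counterpart within 20 mm — the matching radius is a
package convention (the original criterion is unstated).

## Evaluation metrics

Sensor level, per test trial: MSE against the noiseless signal, averaged
over time and channels (one value per trial; per-channel values are a
straightforward variation), and the Pearson correlation over pooled
time × channel samples. Source level, on correct-detection trials: amplitude
error = mean over sources of |max normalized power in a 20 mm ROI around each
reference peak, reference minus estimate| (maps renormalized first, so
global scale is irrelevant); localization error = Euclidean distance between
greedily matched peak positions, in mm; focality = 1/(number of active
voxels); error sources = peaks without a 20 mm-matched counterpart, counted
in both directions. Evoked components: N1 = most negative sample in
40-110 ms, P2 = most positive in 110-220 ms (windows configurable, chosen to
bracket typical auditory latencies of ~65-75 and ~130-156 ms); amplitude
reported as magnitude, latency in ms; condition errors are the summed
absolute differences over both components. The pointwise comparison keeps
every 8th sample (84 of 666) and applies an uncorrected paired t-test per
sample and channel at p < 0.01; zero-variance pairs are flagged
non-significant. No multiple-comparison correction, by design.

## Synthetic evoked (AEP) generator

Trials are 666 samples (−300…1000 ms at 512 Hz). Two dipoles at bilateral
temporal positions (±0.63, −0.20, 0.12) — anatomy-plausible stand-ins for
auditory cortices, not subject-specific — drive a biphasic waveform: a
negative Gaussian lobe (N1, peak 70 ms, σ 15 ms) and a positive one
(P2, 140 ms, σ 25 ms) with N1:P2 amplitude ratio 5:6, matching typical
vertex magnitudes. Dipole signs are flipped if needed so the N1 is negative
at CPz. Jitter is independent per trial *and per hemisphere*: a latency
shift (σ 5 ms) and per-component gains (σ 15%). The hemispheric independence
matters methodologically: two perfectly coherent bilateral sources are the
textbook failure case of minimum-variance beamforming (their summed field
mimics a single midline source and the filter cancels them), whereas
trial-to-trial hemispheric asymmetry — which real evoked data have —
decorrelates the sources enough that a covariance pooled over single trials
in the N1-P2 window localizes both auditory-cortex stand-ins to within a few
millimetres. Evoked *averages* of near-coherent sources remain degenerate
for this beamformer by construction. The clean data are scaled so the noiseless trial
average has the target N1 magnitude (5 units) at CPz. Background noise is
the 1/f surrogate scaled so post-stimulus signal power / noise power equals
the configured SNR (default 1.2, the regime where averaging is obligatory);
the post/pre-stimulus power ratio of the data then estimates 1 + SNR, and
the amplitude SNR of an N-trial average grows like √N. The pre-stimulus
interval carries noise only. The generator returns its ground truth (dipoles,
jitters, scale) for scoring.

## Numerical and degenerate-input conventions

Exact SNR scaling (noise rescaled to measured powers); average reference
subtracted inside the forward solver; central dipoles handled by the n = 1
limit of the series (orientation-independent); correlation of a constant
trial is an error, not NaN; a flat evoked window reports zero amplitude at
the window start; all-zero source maps refuse normalization; covariance
windows need ≥ 2 samples; the beamformer power is invariant to covariance
scale by construction. Ties in peak merging resolve toward the stronger
peak, ordered by descending power.

## Design choices that were genuinely open

* "Simple linear interpolation" is under-specified; inverse geodesic-distance
  weighting over 4 neighbors was fixed a priori as the most parameter-free
  reading.
* "Iteration" in the stopping schedule is read as a full epoch; the counts
  (40-500) are implausibly small as minibatch steps.
* Batch size (8) and padding ("same" zero padding; reflect padding of the
  time axis to a multiple of 8) are unstated upstream and documented here.
* The array-gain constraint is realized as unit-norm leadfield columns with
  the orientation handled by the generalized eigenvalue solution.
* Diagonal loading 1e-3, ROI radius and peak-matching radius 20 mm are
  package conventions, fixed before evaluation and used consistently.

## Known limitations

* **Configuration sensitivity of the LR baseline.** With the default deep-ish
  tangential dipoles, inverse-distance interpolation of a 16-channel subset
  is *good* (test MSE ≈ 0.17 at SNR 5 against unit-power signal). Published
  values for the equivalent condition (LR MSE ≈ 0.87) evidently stem from a
  configuration whose topographies interpolate far worse (more superficial
  sources and/or boundary-heavy error). Consequently the SR-over-LR MSE
  improvement here is ~3× rather than ~20×: the SR error floor
  (≈ 0.05-0.06) is set by the noise the network must reproduce on retained
  channels when trained toward noisy HR, and that floor is close to the LR
  error itself. The correlation ordering (SR > HR > LR) and all source-level
  contrasts (SR localizes both dipoles on every trial; interpolated LR never
  localizes a correct source) are insensitive to this and reproduce cleanly.
* The network is linear end to end; it cannot out-perform the optimal linear
  estimator of the clean signal, and its advantage is exactly the learned
  spatio-temporal regularization.
* Spherical geometry only; no realistic anatomy, no real recordings, no
  artifact model; the brain-noise surrogate has no physiologic spatial
  structure unless a mixing matrix is supplied.
* Single-trial beamformer covariances rest on heavy diagonal loading; with
  64 channels and 512 samples the loading choice (1e-3) matters for map
  smoothness and hence focality. Focality itself (a reciprocal suprathreshold
  voxel count) is the most volatile quantity in the pipeline: it varies by a
  factor of a few between statistically equivalent training runs through the
  spatial structure of the SR residual, while MSE, correlation and amplitude
  error are stable.
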