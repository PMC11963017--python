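# Methods

## Model

`spdwave` implements an end-to-end trainable pipeline for predicting
subject-level outcomes from multichannel EEG, together with the non-deep
Riemannian pipeline it generalizes.  The layer graph is fixed across
variants:

```
raw windows (E x C x T_s)
  -> complex Gabor wavelet convolution (F kernels, shared length L)
  -> pooling into symmetric PSD feature matrices (covariance, optional PLV)
  -> trainable shrinkage        X -> (1-a) X + a (Tr X / p) I
  -> BiMap                      X -> W X W^T
  -> ReEig                      eigenvalue floor
  -> LogMap                     vect(Log X - Log X_ref), running reference
  -> fully connected head       (optional hidden layers, GELU, BN, dropout)
```

### Wavelet front-end

A Gabor wavelet `phi_f(t) = (2 pi sigma_t^2)^{-1/2} exp(-t^2/(2 sigma_t^2))
exp(2 i pi f t)` acts as a band-pass filter at center frequency `f` with
spectral width `sigma_f = 1/(2 pi sigma_t)`.  Both `f` and `sigma_t` are
trainable; they are optimized as `log f` and `log sigma_t`, which enforces
positivity by construction.  After every optimizer step `f` is clamped to
`[0.1 Hz, 0.45 fs]` and `sigma_t` to `[3 ms, support/4]`.

All kernels in a bank share one discrete support length so all frequencies
produce equal-length outputs and cross-frequency covariance blocks are
well-defined.  The default support covers three standard deviations of the
widest envelope (`L = 2 ceil(3 sigma_max fs) + 1`, 99.7% of the Gaussian
mass).  A wider five-sigma support would make the classical 1–64 Hz bank
(`sigma_t = 1.11 s` at 1 Hz) longer than a 10 s window at 125 Hz, i.e. the
default configuration could not process its own standard windows, so three
sigma is the package default and the constant is configurable.

Convolution is computed in the frequency domain ("valid" region only, so
covariance estimates never see boundary transients).  The kernel gradient is
the cross-correlation of input and upstream gradient; it is accumulated in
the frequency domain so the backward pass needs only `F` inverse FFTs.

Morlet initialization uses base-2 log-spaced frequencies and the
constant-cycles rule `sigma_t = n_cycles/(2 pi f)` with `n_cycles = 7`, the
classical convention (1–64 Hz at eighth-octave resolution gives 49
wavelets).  For the *random* initialization used in the recovery and
profiling studies, center frequencies are drawn log-uniformly in 3–40 Hz
with two-cycle envelopes: a broad initial passband lets a wavelet sense
band-limited structure several octaves away, and the envelope narrows during
training when the data reward localization.  The exact initialization
constants are exposed as configuration.

### Pooling

Covariance blocks are `C_ij = Re(X_i X_j^H)/T` — the Hermitian form, so the
`i = j` diagonal is non-negative classical band power (the printed plain
transpose form is available behind a flag for audit, but it does not yield
non-negative power).  The phase-locking value divides each analytic sample
by its modulus (guarded by `eps = 1e-12`) and averages the unit phasor
differences; entries lie in `[0, 1]` with unit diagonal.  Matrices are
averaged arithmetically over the E windows of a sample before the geometric
layers — a mean of PSD matrices is PSD, and one SPD object per sample keeps
the running reference well-defined.  In the joint layout the per-frequency
signals are stacked into an `(F C) x (F C)` block covariance, creating an
explicit cross-frequency representation; PLV matrices are always
per-frequency.

### Geometry

Shrinkage uses the identity-target form, which preserves the trace (total
band power) exactly and shrinks the eigenvalue spread; the strength is a
sigmoid-squashed scalar initialized near zero (raw −4, alpha ≈ 0.02).  BiMap
weights are initialized semi-orthogonal by QR and optimized unconstrained by
default; an optional flag projects them back onto the Stiefel manifold after
each step.  ReEig floors eigenvalues at `max(1e-4 x mean diagonal, 1e-10)` —
a batch-scale-relative threshold, since an absolute one would be meaningless
across power scales.  The final ReEig and LogMap share one diagonalization.

The tangent projection uses a running log-Euclidean reference with momentum
`theta = 0.9`, initialized from the first training batch (not the identity):
the mean covariance is dominated by volume-conduction structure, and
centering on it turns tangent coordinates into power ratios relative to
background.  The update lives entirely in the log domain,
`log_ref <- (1-theta) mean_b Log(X_b) + theta log_ref`, and the reference is
frozen at evaluation.  `vect` scales off-diagonals by `sqrt 2` so it is a
Frobenius isometry and tangent distances equal log-Euclidean distances (a
printed integer factor 2 would break the isometry).  Each feature slot owns
its shrinkage strength, BiMap and reference.

### Variants

| variant | bank | features | layout | BiMap | head |
|---|---|---|---|---|---|
| baseline | Morlet-49, fixed | covariance | per-frequency | PCA subspace | ridge (GCV) |
| G1 | Morlet-49, fixed | covariance | per-frequency | Q = C−1 | linear |
| G1P | as G1 | + PLV | per-frequency | Q = C−1 / ⌈C/2⌉ | linear |
| G2 | as G1 | covariance | per-frequency | Q = C−1 | 32-unit hidden |
| G3 | F = 10, trainable | covariance | joint | 64 → 32 | 64, 32 hidden |
| G3P | as G3 | + PLV | joint + per-freq | 64 → 32 / ⌈C/2⌉ | 64, 32 hidden |
| G3FB | F = 10, trainable | covariance | per-frequency | ⌈C/2⌉ | 64, 32 hidden |

PLV slots and the frequency-specific blocks of G3FB use a stronger BiMap
reduction (`Q = ceil(C/2)`) than covariance slots: with per-frequency
tangent vectors the head input grows as `F q(q+1)/2`, and the reduction
keeps every variant below 100 k parameters at C = 21, F = 10.  G2's hidden
layer is a single 32-unit block.  Classification heads emit unnormalized
logits; the softmax lives in the cross-entropy loss.  Regression uses mean
squared error on internally z-scored targets (the scale is stored with the
model and undone at prediction).

The baseline mirrors the classical pipeline: Morlet-49 covariances,
projection onto the principal subspace of the mean training covariance
(rank repair), log-Euclidean tangent vectors about the mean, and ridge with
generalized cross-validation over 100 log-spaced penalties in
`[1e-5, 1e5]`.

### Optimization

No autodiff framework ships in this package's dependency set, so the
package includes a compact reverse-mode engine (`spdwave.autodiff`) with
hand-written adjoints for dense algebra, elementwise functions, the
symmetric eigendecomposition and the convolution front-end; every adjoint is
gradient-checked against central finite differences in the test suite.

Training uses Adam with parameter groups: head/geometry at `1e-3`, wavelet
center frequencies at `5e-2` and envelope widths at `lr_f / 5` by default.
Two rate choices matter.  First, Adam's per-parameter normalization is what
makes wavelet migration possible at all: the loss gradient with respect to a
far-off center frequency is orders of magnitude smaller than head gradients,
but its *direction* is informative, and Adam steps by sign consistency
rather than magnitude.  Second, when envelope widths learn as fast as center
frequencies on weakly localized tasks, wavelets can cover an informative
band by broadening instead of centering on it; the recovery studies
therefore use equal rates only on tasks whose noise structure penalizes
width.  Early stopping monitors a held-out 20% validation split with
patience 100 (defaults: 300 epochs, batch 32); the best-validation
parameters are restored unless a study needs the fully converged bank.

Windows (default E = 10 windows of T = 10 s, uniform random starts, overlap
allowed) are redrawn every epoch as data augmentation when the wavelets are
trainable.  For frozen banks the wavelet features are deterministic given
the windows, so they are computed once from a fixed draw and cached —
re-convolving 49 fixed kernels every epoch would dominate runtime with no
information gain.  Evaluation always uses a fixed per-recording draw.

## Synthetic data

The generator embodies the assumption under which tangent-space regression
on covariances is statistically consistent: `K` stationary band-limited
sources `s(t)` (Gaussian noise band-passed around a center frequency, scaled
to a per-subject power drawn log-normally), mixed linearly to `C` sensors
(`x = A s + noise`), with the outcome linear in the source log powers
(`y = beta^T log p + eps`, or a logistic draw on the same predictor for
binary tasks).  Sources are filtered noise rather than pure tones so
phase-locking between mixed channels is non-degenerate.  The background is
1/f-shaped noise plus white sensor noise, both unit-normalized before
scaling, so the sensor covariance identity
`Sigma = A diag(p) A^T + (sd_bg^2 + sd_w^2) I` holds for every seed.

The **alpha task** (binary, the Berger-effect toy problem) shifts the log
power of a 10 Hz occipital source by `delta` (default 1.0 natural-log
units) in class 1.  Two non-discriminative rhythms at 6 and 16 Hz share the
alpha source's spatial pattern and fluctuate strongly across subjects
(log-power SD 1.0), emulating individual theta/beta variability.  Because
they are spatially collinear with the alpha source, spatial filtering cannot
remove them — only spectral localization can, which makes the task a sharp
probe of wavelet learning: the class-separability landscape peaks at
~10 Hz and falls off steeply toward both distractors.  The 1/f background
(SD 1.0 per channel) additionally penalizes overly broad envelopes.

What the generator does *not* emulate: realistic lead fields, artifacts,
non-stationary bursts, non-sinusoidal waveforms, cross-frequency coupling.
Passing tests therefore demonstrate correctness of the computation and the
expected behavior under the stated generative model, not performance on real
recordings.

## Validation studies and problem sizes

The acceptance suite and `scripts/acceptance.py` run the same studies:

* **Geometry oracles** — 200 random SPD/symmetric matrices per primitive
  against scipy dense linear algebra; trace preservation to 1e-10, vect
  isometry to 1e-12, geometric decay of the running reference at rate theta.
* **Rank repair** — shrinkage + BiMap on rank C−3 covariances (C = 10),
  100/100 trials must come out strictly positive definite.
* **Corrected t-test** — exact agreement with the hand-coded
  Nadeau–Bengio statistic; calibration over 200 null comparisons (two
  seed-independent copies of the same model, K = 10 splits of 40 subjects):
  empirical type-I error at alpha = 0.05 must stay ≤ 0.10.
* **Alpha recovery** — 5 random initializations of the two-wavelet
  trainable model on the alpha task (n = 200, 60 s at 125 Hz, C = 8,
  delta = 1.0); at least 4 runs must place a wavelet within ±1.5 Hz of
  10 Hz, with the class power ratio peaking at that wavelet.  Runs use
  E = 5 windows of 4 s and 150 epochs — the reduced study protocol that
  keeps a five-seed battery in single-digit minutes on one CPU.
* **Consistency** — baseline and G1 on the linear log-power regression
  (n = 300, 3 sources, C = 6, 40 s at 160 Hz — the rate keeps the full
  1–64 Hz bank below Nyquist): both reach test R² > 0.8 on one 80/20 split
  and their predictions correlate r > 0.8.  The two models share one
  wavelet transform.
* **Profile** — bank sizes {1, 2, 3, 5, 15}, 3 repetitions, 100 subjects,
  60 epochs; the smallest size within one SD of the F = 15 mean must be
  ≤ 3 on the single-band task.

## Numerical choices

* Eigendecomposition adjoints use safe reciprocals of eigenvalue gaps
  (coupling zeroed below 1e-12); degenerate spectra can optionally be
  jittered.
* PLV modulus guard 1e-12; PLV diagonals are set to exactly 1 in the
  functional API.
* The `vect` symmetry check uses a relative tolerance of 1e-6.
* Ridge GCV grid: `np.logspace(-5, 5, 100)` exactly.
* All randomness flows through `numpy.random.Generator` seeded from a
  single integer; two runs with the same seed are bit-identical.

## Known limitations

* The NumPy autodiff engine is single-threaded and eager; it is sized for
  the lightweight models here (tens of thousands of parameters), not for
  large deep architectures.
* Wavelet migration over many octaves needs hundreds of epochs; on tasks
  with very diffuse spectral information the profile's one-SD selection
  rule inherits the noise of few repetitions.
* EDF reading supports homogeneous sampling rates only.
* The semi-orthogonality projection is a retraction, not a true Riemannian
  optimizer step.
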