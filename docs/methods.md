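# Methods

`haradapt` personalizes a wearable-sensor human activity recognition (HAR)
model for a new, unlabeled user by unsupervised domain adaptation. The
labeled recordings of a small *source* group of subjects and the unlabeled
recordings of one *target* subject are mapped into a shared linear
subspace in which their class-conditional distributions align, and a
nearest-neighbour classifier trained on the projected source predicts the
target's activities.

## Signal model

Recordings are 20 Hz, 10-channel time series from a thigh-worn node: one
muscle-deformation air-pressure channel (an airbag over the rectus
femoris, kPa), a 3-axis accelerometer (g), a 3-axis gyroscope (deg/s) and
on-chip-fused Euler angles (degrees). The pressure transducer is linear
over its 0.5–4.5 V output span, which maps onto 0–40 kPa:

    a = (b − 0.5) × 10      (b in volts, a in kPa)

Voltages outside the span are converted anyway but warned about. Each
per-sample-labeled recording is cut into 2 s windows (40 samples) with
50 % overlap. A window is kept only if all 40 samples share one label
(purity rule); mixed or unlabeled windows are dropped and counted. Windows
are half-open `[start, start+40)` with 0-based starts at multiples of 20.

## Feature bank

Each window yields a fixed vector, channel-major: 13 statistics for the
pressure channel and 19 for each inertial channel, so d = 13 + 9×19 = 184
by default. Conventions for quantities the feature names alone do not pin
down (all recorded in `features.py`):

* FFT DC component |X(0)|/N; spectral entropy (nats) of the normalized
  one-sided power spectrum excluding DC; energy as mean signal power.
* Single-level orthonormal Haar decomposition; the wavelet features are
  the detail-coefficient sum, the detail sum of squares, and the detail
  fraction of total squared coefficients. The cascade depth is
  configurable; level 1 divides the 40-sample window evenly and keeps the
  transform hand-checkable (the transform is implemented in-package — a
  two-tap filter pair — because no wavelet library is a runtime
  dependency).
* Strict sign-change counts for zero/mean crossings; population-moment
  skewness and excess kurtosis, both defined as 0 for a constant window;
  linear-interpolation quantiles for the IQR.

The advertised dimensionality of the original feature set (226) is not
reproducible from any integral per-channel count of the published feature
list; d is therefore derived from the configuration and carried in the
output metadata. Dropping the pressure channel is a pure configuration
toggle (d = 171) used for the with/without-muscle-pressure comparison.

## Subspace learning and pseudo-labels

Features are z-scored per row over the pooled source+target columns (the
setting is transductive — both domains are available when the projection
is learned; a per-domain variant would be a one-line change and was not
needed). PCA reduces to k = min(128, d, n−1) dimensions via a dense
eigendecomposition of the sample covariance with a fixed sign convention
(largest-magnitude entry of each eigenvector positive), making every
downstream solve bit-reproducible.

The supervised locality preserving projection (SLPP) pulls same-class
samples together. With binary same-class similarity S, degree matrix
D (D_ii = Σ_j S_ij) and graph Laplacian L = D − S, the projection P solves

    X_l D X_lᵀ p = λ (X_l L X_lᵀ + I) p

over the labeled stack X_l, keeping the m (default k) eigenvectors of the
largest eigenvalues. Both matrices are symmetrized and the right side gets
an unconditional 1e−8 ridge; a failed factorization escalates the ridge to
1e−6 with a warning rather than crashing.

Target samples are then scored two ways in the projected space:

* **Nearest class prototype (NCP)** — softmax over negative Euclidean
  distances to the per-class source means (stable max-shifted softmax).
* **Structured prediction (SP)** — Lloyd's K-means on the projected
  target, centers initialized at the source prototypes; each cluster keeps
  the class of its initializing prototype (never re-matched), empty
  clusters freeze at their initialization, max 100 iterations, center-shift
  tolerance 1e−6, fully deterministic. The same softmax is applied against
  the final centers.

The combined score is the element-wise maximum of the two probability
rows; the pseudo-label is its argmax with ties broken to the lowest class
index. The combined row is intentionally not renormalized. The full
improved-pseudo-label pass runs: PCA on pooled data → SLPP on source only
→ provisional labels → SLPP refit on source ∪ pseudo-labeled target →
final labels. All targets are labeled; an optional confidence threshold is
deliberately not applied (label-all is the simplest reading of the
combination rule, and selectivity would leave some targets undefined).

## Joint-probability adaptation

With one-hot source labels Ys (ns×C) and current target pseudo-labels
Yt (nt×C), define Ns = Ys/ns, Nt = Yt/nt and the cross-class expansions
Fs (each class column repeated C−1 times) and Ft (for each class c, all
non-c columns in ascending class order), scaled to Ms, Mt. The block
kernels

    Rmin = [[NsNsᵀ, −NsNtᵀ], [−NtNsᵀ, NtNtᵀ]]     (same-class, minimized)
    Rmax = [[MsMsᵀ, −MsMtᵀ], [−MtMsᵀ, MtMtᵀ]]     (cross-class, maximized)

are positive semi-definite by construction (each is a Gram matrix of a
stacked signed coupling). The adaptation map A (d×p) solves

    (X (Rmin − μ Rmax) Xᵀ + λI) a = η X H Xᵀ a,     H = I − (1/n)·1

taking the p *trailing* (smallest-η) eigenvectors — the minimizing
direction of the objective — with the same symmetrize+ridge policy as
SLPP. μ = λ = 0.1. The F̂t block order (ascending class index excluding c)
is a convention; only consistency between the Ms and Mt blocks matters.

The driver alternates: iteration 1 assigns improved pseudo-labels;
iterations 2..T (default T = 10) rebuild Rmin/Rmax, re-solve for A, train
a 1-nearest-neighbour classifier on AᵀXs and relabel AᵀXt. Only the
labels cross from the pseudo-label stage into the adaptation loop (a flag
to reuse the SLPP subspace exists but defaults off, matching the
labels-only data flow of the algorithm). A class absent from the current
pseudo-labels simply contributes zero coupling columns (warned, never
imputed). Per-iteration label history and the same-class joint-MMD trace
are recorded as diagnostics.

### Choice of p

The generalized eigenvectors are scatter-whitened (AᵀXHXᵀA = I), so every
retained direction carries unit variance regardless of how much class
structure it holds. Beyond roughly the number of discriminative directions
the label couplings can support, additional components are whitened noise
that dilutes nearest-neighbour distances: with oracle labels on a shifted
synthetic cohort, accuracy is 1.00 for p ≤ 20 but collapses to 0.59 at
p = 100. The default is therefore p = min(20, d, n−1). Very small cohorts
(n ≲ 150) benefit from p ≈ 5–10; p is an exposed knob.

## Evaluation harness

Metrics follow the binary definitions (accuracy, recall = TP/(TP+FN),
precision = TP/(TP+FP), F as their harmonic mean) applied one-vs-rest per
class and macro-averaged; overall accuracy is the fraction correct. Macro
aggregation is the convention under which the published per-class
confusion matrices reproduce their printed mean accuracies exactly under
equal class counts. A class with no predicted positives gets precision 0
(warned). Per-subject metrics are computed first and then averaged across
target subjects (F per subject before the mean, which is why a summary
row's F can differ slightly from the harmonic mean of its printed
precision/recall).

Baselines: KNN/SVM/decision-tree (scikit-learn, standardization fit inside
each training split) under two protocols — OS (trained on the pooled
source group; target labels touched only for scoring) and SS (trained on
the target's own labeled data, scored out-of-fold under stratified 10-fold
CV; the fold count drops with a warning when a class has fewer members).

The group experiment splits subjects 3 source / 4 target by seed, keeps 10
random segments per class per target (70 total), scores every model per
target and averages. The source-size sweep holds out test subjects and
reports mean ± std of adapted accuracy over random source subsets of each
size.

## Synthetic cohort

The generator emulates the study's setting (7 subjects, 7 activities,
~1900 two-second segments at the default 40 segments per class per
subject) without its private recordings. Each activity is a per-channel
template — baseline + sinusoid with harmonic weights + Gaussian noise.
Postural classes differ in Euler baselines and pressure level with
near-zero gyro; walk/run/stairs differ in fundamental (1.2 / 2.5 / 1.0 Hz),
amplitude and pressure loading; up vs down stairs differ in Euler-pitch
sign and harmonic phase (stride asymmetry). The harmonic phase is locked
to the fundamental's random per-bout phase so the waveform shape (not just
its position) is class-characteristic.

Inter-subject shift is an affine per-channel gain/offset plus a global
frequency warp, drawn once per subject; one difficulty scalar multiplies
all three sigmas. This family was chosen because it is a plausible model
of anatomy/placement/intensity differences and is largely correctable by
a linear subspace method — exactly the regime the adaptation targets.
The sigmas (gain 0.40, offset 2.2 channel-scale units, frequency 0.15,
each per unit difficulty; frozen in `synthetic_data.py`) were calibrated
**once** so that at difficulty 1
a source-trained raw-feature 1-NN loses ≥ 10 accuracy points versus the
zero-shift case (0.998 → 0.885 across calibration seeds, with the adapted
model at 0.960), and then frozen.

What the generator does **not** emulate: biomechanical gait detail,
airbag/muscle contact physics, sensor drift, within-subject
non-stationarity, label noise, or transitional movements. A green test on
synthetic data therefore establishes the pipeline's correctness and its
qualitative transfer behaviour under affine+frequency shift — not the
absolute accuracies reported on the original private recordings, which
are out of reach by construction.

## Numerical conventions

* Eigenvector sign: largest-|entry| positive, everywhere.
* Ridge 1e−8 added unconditionally to every generalized right-hand side;
  escalated to 1e−6 with a warning on factorization failure.
* Argmax ties: lowest class index, everywhere.
* Zero-variance feature rows normalize to 0, never NaN.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived seeds stay below 2³¹.

## Known limitations

* The default p is tuned for cohort-scale problems; tiny problems
  (n ≲ 150) can lose a few points to whitened-noise directions.
* The SS baseline with only 10 segments per class has high variance, as
  expected for self-trained models on little data.
* Absolute published accuracies are not reproducible (private data); the
  package instead verifies every recomputable printed quantity and the
  qualitative transfer ordering.
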