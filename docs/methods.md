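# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate conventions

All coordinates are millimetres in patient AC–PC space. The canonical
storage frame puts the posterior commissure (PC) at the origin with x the
laterality magnitude (positive toward the implanted side), y positive
anterior and z positive dorsal. The mid-commissural (MCP) convention is
accepted in every file format and converted on load; the two frames differ
by a pure y-translation of half the AC–PC length, so conversion is exact
and involutive. Right-hemisphere landmark sets are pooled with left ones by
reflecting laterality to its magnitude (x → |x|), an idempotent operation
that touches only x.

## The landmark referential

Eighteen named landmarks per hemisphere (AC, A, B, C, D, PA2, PM2, PP2,
BAT, BPT, CH, PA1, PM1, PP1, PA3, FMT, Pculm, Plat, in that fixed order)
form the patient-specific referential. They are defined on planes derived
from three anchor points — A (lateral third-ventricle border at the
mid-commissural level), B (highest thalamic point above A) and C, the
midpoint of [AB] — which yields testable consistency constraints: AC and A
lie on z = 0; B and D share A's parasagittal plane; D and the six
putaminal/thalamic/habenular points of the "Z_C" group lie on z = Z_C; the
PA1/PM1/PP1 group on z = Z_C − 5; PA3 and FMT on z = Z_C − 10; and
Pculm/Plat share PM1's coronal plane. `validate_landmark_set` reports every
constraint whose residual exceeds a tolerance τ (default 1.0 mm — about
twice the per-axis observer noise, so honest rater scatter does not trip
validation; generated data are checked at τ = 10⁻⁶ mm). The feature vector
concatenates the 18 points' (x, y, z) in canonical order: 54 values.
Redundant coordinates (C is determined by A and B) are retained; filtering
is a model-side concern.

## Observer variability

Repeated segmentations of the same hemisphere are paired — same rater
across two sessions for the intra-observer law, different raters for inter
— and for each (landmark, axis) the per-measurement sigma is estimated as
sd(paired signed differences)/√2, since a difference of two independent
readings carries twice the single-reading variance. This is the parameter
of the additive Gaussian noise law needed downstream; the mean absolute
paired distance per (landmark, axis) and its grand mean ± SD are reported
alongside as the conventional descriptive summary (note the mean absolute
difference of a centred Gaussian pair is σ√2·√(2/π) ≈ 1.13 σ, so the two
summaries differ by design, not by error).

## Metamodels

Features and each target axis are centred and scaled to unit variance
inside every fit (parameters stored with the model; predictions
de-standardized on output). A fixed-width Gaussian kernel over raw
millimetre coordinates would otherwise couple the kernel width to landmark
scale. All kernel widths and SVR tube widths below are therefore in
standardized units.

**Kernel ridge (RKHS).** The loss (1/n) Σ (F(Xᵢ) − yᵢ)² + λ‖F‖²_H over
F(x) = Σ αᵢ K(x, Xᵢ) has the closed form α = (K + nλI)⁻¹ y; the n·λ shift
keeps λ dimensionless with respect to cohort size. The solve uses a
symmetric positive-definite factorization; at λ = 0 with duplicated inputs
the system is singular and a conditioning error is raised rather than a
least-squares fallback.

**ε-insensitive SVR.** One model per output axis. The standard dual —
maximise −½βᵀKβ − ε‖β‖₁ + yᵀβ over β = α − α* with Σβ = 0 and |βᵢ| ≤ C —
is solved by sequential minimal optimization (libsvm via scikit-learn);
support inputs, dual coefficients and the bias are extracted into the model
object, and Karush–Kuhn–Tucker residuals (dual sum, box violation, duals on
points strictly inside the tube) are measured at fit time and stored for
audit. `fit_svr_axis` defaults to an unbounded solve at tolerance 1e−8 for
small-instance precision; the cohort-scale `SVRRegressor` wrapper defaults
to tolerance 1e−4 with a 20 000-iteration SMO budget, ample for cohorts of
a few hundred samples while keeping repeated cross-validation fits cheap
(`max_iter=-1` restores the exact solve). An independent dense-QP solve of
the same dual serves as a cross-check in the test suite; it is never the
implementation.

**Feed-forward network.** Architecture 54 → 256 → 128 → 64 → 3, ReLU hidden
activations, linear output, squared-error loss, Adam with learning rate
1e−3, 500 epochs, full batch below 512 samples, no weight decay by default.
The seed is mandatory and fixes initialisation and shuffling, making
training bit-reproducible single-threaded. Fitted weights are stored
explicitly and prediction is a plain numpy forward pass, so serialized
models are self-contained.

## Hyperparameter search and validation

The grid defaults span under- to over-fitting on standardized features:
σ ∈ {0.5, 1, 2, 4, 8}·√54 (squared distances between standardized
54-vectors concentrate near 2·54), λ ∈ {1e−4 … 1} log-spaced,
ε ∈ {0, 0.05, 0.1, 0.2}, C ∈ {0.1, 1, 10, 100}. Search is exhaustive,
scored by grouped-CV mean 3-D error; ties break toward maximal
regularization (larger λ, then larger ε, smaller C, larger σ). Grouped CV
defaults to leave-one-patient-out; an `n_splits` option partitions sorted
patients into contiguous grouped blocks instead, which is what the
larger-cohort analyses use for hyperparameter selection (10 blocks).
During the search, features are standardized once over the search data so
Gaussian Gram matrices can be precomputed per σ and shared across folds;
the winning parameters are then applied to models that re-standardize on
their own training sets. SMO runs in the search use a bounded iteration
budget — ranking cells does not need the exact optimum — and the selected
cell is always refit exactly.

Outer validation is always leave-one-patient-out: both hemispheres of the
held-out patient leave the training fold together, so a model is never
scored on the mirror image of a hemisphere it saw. Errors are per lead:
the 3-D Euclidean distance plus per-axis absolute errors, aggregated as
mean ± SD with the n−1 convention (a single value reports SD 0 with a
flag). Nested per-fold re-optimization of the grid is available but off in
the shipped analyses; with 29 leads the added cost buys little and the
default grids are stable across folds.

Greedy forward feature selection for the kernel-ridge model adds, at each
step, the feature minimizing grouped-CV error, stopping below a 1% relative
improvement; the kernel width adapts to the subset size as σ ∝ √k. It is a
reasonable stand-in for an unspecified selection procedure, not a canonical
algorithm; selected subsets should be read as cohort-specific outcomes.

## Augmentation and uncertainty propagation

Augmentation enlarges a training set with `factor` noisy replicas per
sample: independent Gaussian noise per (landmark, axis) with the
variability model's σ added to the features, targets copied unperturbed.
Held-out folds are never augmented; the CV driver augments inside each
fold only, and the test suite audits this with a spying model. By
convention augmentation uses the inter-observer law (the spread between
raters is what new data would carry) and confidence intervals default to
the intra-observer law (the irreducible uncertainty of one rater's
placement); both are overridable. Noise is independent across landmarks
and axes — no covariance structure is modelled.

`predict_with_ci` Monte-Carlo perturbs one feature vector n_mc times,
predicts each replica, and reports the unperturbed-input prediction with
per-axis empirical quantile half-widths: half the distance between the
(1−ℓ)/2 and (1+ℓ)/2 quantiles at nominal level ℓ. Quantile intervals are
preferred over ±1.96·sd because they stay honest for nonlinear models; for
an affine model they converge to the analytic Gaussian interval, which is
the calibration check in the test suite. The scalar summary is the mean of
the three per-axis half-widths, and is labelled as such wherever reported.

## Lead geometry

A lead is reconstructed from its distal tip A and a point J just proximal
to the contacts; (A, J) are treated as given inputs. Any point at arc
distance D from the tip is M = D·u + A with u the unit vector from A to J.
Contact centres sit at D = tip_to_first_contact_center + k·(contact_length
+ gap), distal first. The default geometry is the Medtronic 3389 lead
(1.28 mm diameter, 1.5 mm contacts); the inter-contact gap (0.5 mm) and the
tip-to-first-centre offset (1.5 mm = half a contact plus 0.75 mm) are
explicit configuration, not hidden constants, because they are reconstructed
from imaging artifacts rather than read from a datasheet. For bipolar
stimulation the target convention is the midpoint of the two active
contacts. d1 is the contact-centre-to-target distance; d2 =
‖(T − L) × u‖/‖u‖ is the minimal axis-to-target distance, so d2 ≤ d1 is an
identity whenever the compared contact lies on the axis.

## The synthetic cohort generator

Six latent anatomical dimensions per hemisphere drive everything, sampled
from truncated normals (mm): AC–PC length ~ N(26, 1.5) on [22, 30],
third-ventricle half-width ~ N(3.5, 0.8) on [1.5, 6], thalamic height ~
N(16, 1.5) on [12, 20], thalamic AP extent ~ N(28, 2) on [22, 34],
putaminal lateral offset ~ N(22, 1.5) on [18, 26], putaminal AP extent ~
N(30, 2) on [24, 36]; a patient-level global scale ~ N(1, 0.03) multiplies
the length latents, and hemispheres share a patient's draw up to an
asymmetry perturbation (sd 0.4 mm) of the ventricular, thalamic-height and
putaminal-laterality latents. Landmarks are placed by fixed affine rules of
the latents (documented in `latents_to_landmarks`) that satisfy every
referential constraint exactly; in particular Z_C is half the thalamic
height.

The true functional target is a version-pinned smooth map ("v1"):

    x = 11.0 + 0.8·v3 + a·1.5·sin(thal_height/5)
    y = 0.30·acpc + a·2.0·(put_ap − 30)²/50
    z = 0.7 + 0.45·(thal_height − 16) + a·0.8·sin(put_lat/4)

with amplitude a = 1 by default; a = 0 reduces it to an affine map
(verified by regression in the tests). It rides on the two classical
predictors — ventricle width for laterality, AC–PC length for y — plus
nonlinear terms in the thalamic and putaminal latents, so multi-landmark
kernel methods have something to gain over a one-landmark linear rule;
its constants put cohort target medians near (14, 8, 1) mm PC-origin, the
region where effective contacts cluster. The map is invented by necessity:
the real anatomy-to-effective-target relation is the unobservable clinical
ground truth.

Observed data add two noise processes: per-coordinate Gaussian observer
noise (default σ = 0.6 mm, the magnitude of inter-rater landmark
variability) on the features, and per-axis Gaussian implantation noise
(default σ = 0.75 mm, giving a ≈1.3 mm median 3-D offset between the
implanted contact and the true target — the scale of unavoidable surgical
scatter) on the targets. Three segmentation campaigns (rater 1 twice,
rater 2 once) give the repeated readings for variability estimation. Lead
trajectories run dorsally along a jittered double-oblique direction with
the implanted contact placed at the contact-1 (0-based) arc distance, so
reconstructed contact centres reproduce the implanted positions exactly.
All randomness flows from one master seed through named SeedSequence
streams; the generator is a pure function of its config.

What the generator does *not* emulate: anisotropic or landmark-specific
observer noise (real raters are worse on some structures, e.g. posterior
thalamic borders), correlated segmentation errors, imaging distortion near
the metal artifact, true nucleus geometry, and any systematic relation
between anatomy and surgical approach. Passing tests therefore demonstrate
the correctness and statistical behaviour of the pipeline, not clinical
accuracy on real cohorts.

## Problem sizes and numerical choices

The shipped analyses use the 15-patient / 29-lead cohort shape of a typical
single-centre series; recovery checks use 100 noiseless patients, at which
size the kernel metamodels should (and do, per the tests) reach
sub-half-millimetre LOOCV error against a baseline several times larger.
Monte-Carlo intervals use 2 000 draws per query (40 000 where a 5%
quantile-accuracy check needs them). CSV files store full-precision floats
and are re-read with round-trip parsing, so write/read cycles are
bit-exact; model JSON round-trips reproduce RKHS/SVR predictions exactly
and network predictions to 1e−6. Reports embed the seed, configuration
echo and software version, and contain no timestamps, so identical
invocations are byte-identical.

## Known limitations

* With 29 leads the network is heavily over-parameterised and behaves like
  a regularised mean; its value appears only with augmentation or larger
  cohorts.
* Augmentation gains are modest and seed-dependent at this cohort size —
  expected, since replicas add no new anatomical information, only a
  smoothing prior matched to the observer noise.
* The greedy feature-selection procedure and the synthetic target map are
  package choices, not reproductions of any clinical pipeline; absolute
  error levels on synthetic cohorts are not comparable to errors on
  patient data.
* Observer noise is modelled as independent and homoscedastic across
  landmarks and axes.
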