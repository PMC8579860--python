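# vimtarget

Landmark-based prediction of the clinically effective deep-brain-stimulation
(DBS) target for essential tremor.

The classical surgical target for tremor — the ventro-intermedius nucleus of
the thalamus (Vim) and the adjacent posterior subthalamic area — is invisible
on routine 1.5 T MRI, so it is traditionally located by linear rules of thumb
on one or two anatomical references (third-ventricle width for laterality,
AC–PC length for the antero-posterior axis). This package implements a
multi-landmark, nonlinear alternative: a patient-specific referential of 18
MRI-visible landmarks per hemisphere whose coordinates, concatenated into a
54-value feature vector, are regressed onto the position of the active
stimulation contact of previously implanted patients with optimal outcomes.

It is written for researchers in computational neuroanatomy and stereotactic
targeting who want a tested, reproducible implementation of the full
analysis: the landmark referential with its consistency constraints, three
regression metamodels, observer-noise data augmentation with uncertainty
propagation, lead-trajectory geometry with placement-accuracy statistics,
and grouped leave-one-patient-out validation. Because clinical MRI cohorts
of this kind cannot be shared, the package ships a synthetic-anatomy
generator so every stage runs end to end without any external data.

## The model

Each hemisphere contributes a pair (X, Y): the feature vector
X ∈ ℝ⁵⁴ of landmark coordinates in AC–PC space (PC at the origin, x =
laterality magnitude, y anterior, z dorsal) and the target Y ∈ ℝ³, the
centre of the active contact. Three metamodels F: ℝ⁵⁴ → ℝ³ are fitted:

* **Kernel ridge regression (RKHS)** — F(x) = Σᵢ αᵢ K(x, Xᵢ) with the
  Gaussian kernel K(x, y) = exp(−‖x−y‖²/2σ²), coefficients minimizing
  (1/n) Σᵢ (F(Xᵢ) − Yᵢ)² + λ‖F‖²_H, solved in closed form as
  α = (K + nλI)⁻¹ y, one model per output axis.
* **ε-insensitive support vector regression (SVR)** — F(x) =
  Σᵢ (αᵢ − αᵢ*) K(x, Xᵢ) + b, the dual coefficients solving the standard
  SVR quadratic program (box constraints at C, duals summing to zero),
  per axis.
* **Feed-forward network (DNN)** — a 54 → 256 → 128 → 64 → 3 multilayer
  perceptron with ReLU hidden activations and a linear output, trained
  with Adam under squared error, deterministic given its seed.

Hyperparameters (σ, λ, ε, C) are chosen by exhaustive grid search scored
with grouped cross-validation, and all evaluation uses leave-one-patient-out
CV in which both hemispheres of the held-out patient leave the training set
together. Repeated landmark segmentations give a per-landmark, per-axis
Gaussian observer-uncertainty law used twice: to augment small training sets
with noisy replicas, and to propagate input uncertainty into a Monte-Carlo
confidence interval on each predicted target. Lead placement is summarised
by d1, the distance from the active-contact centre to the planned target,
and d2 = ‖(T − L) × u‖/‖u‖, the minimal distance from the lead axis to the
target.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort shaped like a typical surgical series (15 patients, one unilateral,
29 leads) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_observer_variability.py
python analysis/03_model_comparison.py --seed 1
python analysis/04_augmentation_sweep.py --seed 1
python analysis/05_uncertainty_propagation.py --seed 1
python analysis/06_lead_geometry.py
```

With `--seed 1` this prints, among other things:

```
cohort: 29 leads over 15 patients (one unilateral), 0 landmark-constraint violations
intra-observer: mean paired distance 0.677 +/- 0.102 mm over 29 pairs
   model  mean_error_mm  sd_error_mm  x_mean_mm  y_mean_mm  z_mean_mm
    rkhs          1.473        0.747      0.778      0.430      0.952
     svr          1.448        0.746      0.766      0.412      0.945
     dnn          1.691        0.861      0.929      0.481      1.146
baseline          1.634        0.841      1.038      0.403      0.958
svr: mean 95% CI half-width 0.229 mm over 29 hemispheres
29 leads: d1 median 1.20 mm [IQR 0.85-1.91], d2 median 0.83 mm
```

Reading these numbers: the kernel metamodels predict the implanted active
contact to within about 1.5 mm on average — below the ≈2 mm displacement
usually considered clinically meaningful for this target — and beat the
constant-mean baseline, while the 100k-parameter network has too little
data at n = 28 training hemispheres to do so. The confidence half-width
says how much the prediction would move under another rater's plausible
landmark placement, and d2 < d1 always holds because the nearest point of
the lead axis is at least as close as the active contact itself.

The same pipeline is available as a CLI (`vimtarget simulate | variability |
train | predict | loocv | augment-sweep | geometry`); every command is
byte-deterministic given `--seed`.

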