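# Methods

`idhgan` benchmarks minority-class balancing strategies for predicting
intradialytic hypotension (IDH) — a clinically significant blood-pressure
drop during hemodialysis — from per-measurement session records. Because
real hemodialysis records of this kind are held under IRB restrictions,
the package ships a synthetic cohort generator that reproduces the data's
multi-level structure, and every claim the test suite makes is a claim
about method behavior on that synthetic cohort, not about clinical data.

## Synthetic cohort model

Records are generated at four levels:

* **Patient** — baseline systolic pressure ~ N(150, 15²) mmHg, dry weight,
  diabetes (p = 0.60) and hypertension (p = 0.30) flags.
* **Monthly laboratory** — albumin, hemoglobin, fasting glucose: a patient
  mean plus a per-(patient, month) wobble.
* **Session** — ultrafiltration rate/volume, blood flow, venous pressure,
  dialysate conductivity, an ultrafiltration-profile flag; sessions run
  thrice weekly (Mon/Wed/Fri) from the configured start date.
* **Measurement** — systolic pressure follows a within-session AR(1)
  trajectory around the patient baseline (reversion 0.10/step, innovation
  sd 4 mmHg) minus a log-normal hypotensive drop whose log-scale mean is
  `b + 0.9·z_uf + 0.7·diabetes + 0.3·hypertension + 1.2·(t/T) +
  0.02·(150 − SBP_{t−1})`. Diastolic pressure is `0.33·SBP + 18 + noise`;
  pulse rate reverts to 77 bpm and rises with the drop.

The label `idh_next` marks whether the **next** measurement of the same
session meets the IDH criterion; the last measurement of a session has no
successor and carries a missing outcome. The criterion defaults to
*next systolic < 90 mmHg or a fall of ≥ 20 mmHg from the session's first
systolic reading* — a common clinical operationalization; both thresholds
are configurable because the pipeline itself is threshold-agnostic.

The intercept `b` is solved by bisection on a pilot simulation so that the
realized label prevalence matches a configurable target (default 14.85%).
The drop's log-rate is clipped to [−10, 4] and the systolic floor is
30 mmHg so that extreme intercepts explored during bisection cannot
overflow the trajectory; within the calibrated range these clips are
inactive.

What the generator does **not** emulate: measurement-device noise
structure, informative (non-random) missingness, patient dropout,
treatment feedback (staff intervening when pressure falls), and any
between-feature correlation beyond the risk pathway above. Passing tests
therefore demonstrate correct mechanics and qualitative behavior of the
balancing/benchmark machinery, not clinical performance levels.

## Preprocessing

Order of operations: date encoding → within-session lag construction →
complete-case filtering → temporal split → scaling. Lags are built from
true adjacent measurements before filtering, so a missing source value
propagates into the lag and the row is excluded rather than borrowing a
value from a non-adjacent surviving measurement. No imputation is ever
performed.

* **Date encoding** — days elapsed since the earliest session (default)
  or weekday (Monday = 0), the latter a sensitivity-analysis toggle.
* **Lags** — lag-1/lag-2 of systolic, diastolic and pulse rate, computed
  strictly within a session; pulse pressure (systolic − diastolic) is
  derived for the current and lagged time points. Rows lacking a required
  lag are dropped, not zero-filled.
* **Temporal split** — the cut is placed at the between-date boundary
  whose realized record fraction is closest to the target (default 0.75),
  ties to the earlier cut. Sessions have a single date, so partitions are
  automatically session-disjoint; nothing computed on test rows (scaler
  statistics, lag values) can reach the training pipeline.
* **Robust tanh scaler** — `x' = tanh(c·(x − median)/IQR)` per continuous
  feature with quartiles by linear interpolation, fitted on the training
  partition only. The scale constant defaults to `c = 0.5`, which maps
  ±2 IQR to ≈ ±0.76 and avoids early saturation; a constant feature falls
  back to IQR 1 (transforming to 0) with a warning. The transform is
  strictly monotone and invertible on (−1, 1).

## Conditional WGAN-GP

The generator maps 128-dimensional standard-normal noise concatenated
with a 2-dimensional one-hot class label through a 256-wide projection,
two residual blocks (affine → LeakyReLU(0.2) → affine, skip-added,
LeakyReLU after the sum), and a tanh output matched to the scaled feature
space. The critic applies three spectrally-normalized affine layers
(input → 256 → 256 → 1) with LeakyReLU(0.2) to the sample concatenated
with the same one-hot label. Training follows the WGAN-GP schedule: five
critic updates per generator update, critic loss
`mean D(x̃,y) − mean D(x,y) + λ·mean((‖∇_x̂ D(x̂,y)‖₂ − 1)²)` with λ = 5
and `x̂ = ε·x + (1−ε)·x̃`, ε ~ U[0,1] per sample; generator loss
`−mean D(x̃,y)`; RMSprop with learning rates 10⁻³ (generator) and
2·10⁻³ (critic), decayed by 0.9 every 30 epochs. A fixed epoch budget
replaces a convergence criterion for reproducibility, and the full
per-step loss history is retained.

The implementation runs on a purpose-built numpy reverse-mode autodiff
engine whose backward rules are themselves graph operations, so the
gradient penalty's second-order term (the derivative of the critic's
input-gradient norm with respect to the critic weights) is exact.

Numerical choices that proved necessary and are part of the package's
design:

* **Spectral normalization differentiates through σ.** σ is estimated by
  one power-iteration step per forward pass; the singular vectors are
  detached but σ = uᵀWv itself stays in the graph. Detaching σ entirely
  makes the gradient penalty inflate weight norms that the normalization
  immediately cancels, and the critic never learns.
* **Learnable per-layer gain.** Each normalized critic weight is scaled
  by a trainable scalar (initialized at 1). With a hard unit spectral
  norm the three-layer critic stays nearly linear, its score is maximized
  on the boundary of the tanh box, and the generator collapses to a
  corner; the gain restores the curvature the gradient penalty needs
  while the normalization keeps the matrices well-conditioned.
* **Late Polyak averaging of the generator.** Sampling uses an
  exponential moving average of generator weights (decay 0.995) started
  after 60% of the training schedule. Adversarial training leaves the
  generator oscillating around the equilibrium; averaging the late
  iterates smooths that oscillation and cuts the minority-recovery
  Wasserstein error several-fold across seeds. Averaging from the start
  is harmful — early iterates are still drifting — hence the warmup.
* **Saturation-safe start.** The generator's output layer is initialized
  with a reduced gain (0.25/√h) so the tanh pre-activation starts inside
  its linear range, and the RMSprop second-moment accumulator starts at 1
  (decaying to the standard scale-free behavior over a few hundred
  steps). Without both, the first ~10 generator updates push the output
  into saturation where tanh gradients vanish irrecoverably. Hidden
  layers keep Kaiming initialization.

Sampling snaps binary columns to the nearest of {0, 1}; continuous
outputs remain strictly inside (−1, 1). `balance` mode appends exactly
(N_majority − N_minority) synthetic minority rows, yielding a 50.00%
positive rate; `augment` mode appends a configurable two-class synthetic
block, defaulting to a 50/50 block that doubles the dataset (the
per-class counts are parameters because a single canonical mix does not
exist for augmentation). Original rows are preserved verbatim and
appended rows carry a `synthetic` flag.

## SMOTE and ADASYN

Both synthesize minority rows as `x_i + u·(x_nn − x_i)`, u ~ U(0,1), with
the neighbor drawn among the k = 5 nearest minority neighbors under
Euclidean distance in the scaled space (binary columns participate as
0/1 coordinates). SMOTE spreads anchors evenly across minority points;
ADASYN weights each minority point by the fraction of majority points
among its k nearest neighbors in the full training set, normalizes, and
apportions the deficit by largest remainder (floor, then one extra row
per largest fractional share, ties to the lower index). Per-point
rounding without redistribution is biased here: hardness fractions lie
on a 1/k lattice, so whole blocks of points round the same way and the
total drifts from the deficit in proportion to the minority count; the
apportionment keeps the allocation adaptive while matching the deficit
exactly. If no minority point has majority neighbors, weights fall back
to uniform with a warning.

## Fidelity metrics and test battery

Per feature: 1-D Wasserstein distance on empirical samples (quantile
integral), KL(real ‖ synthetic) and Jensen-Shannon divergence on
histograms with 50 shared bins over the pooled min–max, smoothed by
ε = 10⁻¹⁰ and renormalized (natural log). The KL direction penalizes
synthetic data that fails to cover real mass. The per-feature distance
vectors are the observations for the cross-method battery: a
tie-corrected Kruskal-Wallis test across methods, then pairwise
Mann-Whitney U tests (exact enumeration when n_a·n_b ≤ 400 and tie-free,
otherwise the tie- and continuity-corrected normal approximation) at a
Bonferroni-corrected level α/C(k,2) — 0.05/6 ≈ 0.0083 for four methods.

## Prediction benchmark and statistics

XGBoost binary classifiers over a fixed grid of six tree counts
(80–130, step 10) × five depths (8–16, step 2) = 30 combinations per
dataset variant, all other hyperparameters held at standard values
(learning rate 0.3, histogram trees, no subsampling, L2 weight 1, no
class re-weighting, seed 42) so that performance differences are
attributable to the training data, not tuning. Metrics at threshold 0.5:
accuracy, precision, recall, F1 from the confusion matrix; ROC-AUC by
the trapezoid rule; PR-AUC as step-interpolated average precision (the
conservative estimator for imbalanced problems).

The comparison layer runs, per metric, a one-way ANOVA across the five
variants with ω² = (SS_B − df_B·MS_W)/(SS_T + MS_W) — a 5 × 30 design
gives df (4, 145) — followed by pairwise Mann-Whitney U tests at
α = 0.05/10 = 0.005 with Cohen's d (pooled-SD, first-minus-second).
Negative ω² (possible when F < 1) is reported as-is and read as a
negligible effect. Box plots (median/IQR/outliers per variant, one panel
per metric) carry significance annotations from the pairwise table.

## Interpretation

Attributions use the exact polynomial-time TreeSHAP algorithm on the
margin (log-odds) scale, computed on the held-out test partition.
Local accuracy — base value plus attributions reconstructing the margin
output — is enforced on every matrix to 10⁻⁵ (the tree library
accumulates in float32, which bounds achievable reconstruction
precision). Features are ranked by mean absolute attribution with a
Spearman correlation of feature value against attribution as the
directionality summary; the beeswarm plot mirrors the standard
value-colored summary-plot convention.

## Problem sizes and seeds

Desk-scale defaults keep the full pipeline and test suite tractable on a
single CPU: the default demonstration cohort is ~20k records (56
patients × 20 sessions × 18 measurements), the GAN trains 30 epochs at
batch 512 inside the pipeline, and the parameter-recovery measurement
uses a 5,000-row two-Gaussian toy trained 200 epochs at batch 128. The
reference-composition assembly arithmetic (95,856 training records,
14,121 positive) runs at full scale since it is count arithmetic plus
neighbor searches. Every stochastic stage derives its seed from a global
seed through fixed offsets recorded in the run manifest.

## Known limitations

* The numpy WGAN-GP is single-threaded and desk-scale; it is faithful to
  the training algorithm but not a GPU implementation, and very long
  schedules are slow.
* Binary conditioning only (two-class one-hot); categorical features
  with more than two levels are out of scope.
* The generator's fidelity after short schedules (tens of epochs) is
  rough; distribution-level recovery to W₁ < 0.1 needs the ~200-epoch
  schedule used in the recovery measurement.
* Synthetic-cohort results quantify mechanics, not clinical effect
  sizes; in particular the strong planted risk signal makes the
  prediction task easier than real hemodialysis data. A consequence the
  test suite measures directly: because the minority class follows a
  clean generative rule that a boosted-tree learner already captures
  from the real training rows, GAN balancing confers no consistent
  PR-AUC advantage across cohort replicates on this generator —
  high-fidelity synthetic minority rows can even blur the decision
  boundary — so cross-seed ordering checks of that advantage should be
  read as a property of the cohort model, not of the balancing code.
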