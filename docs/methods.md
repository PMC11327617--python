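# Methods

This note records the modeling assumptions, the parameter choices that
matter, the numerics, and the known limits of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Discrete-time survival model

Follow-up is partitioned into five right-closed bins `(cut_{m−1}, cut_m]`
with `cut_0 = 0` and cut points at the {10, 30, 50, 70, 90}th
linear-interpolation percentiles of the observed training times (events and
censored pooled). A single softmax over `K·5 + 1` cells (K = 1 event type,
death) yields per-subject probabilities `y`; the cumulative incidence
function is the running sum of in-horizon cells and the survival function
its complement. Survival is reported at the cut points and linearly
interpolated to integer months with one month = 30.44 days, anchored at
S(0) = 1.

The sixth, beyond-horizon cell is a deliberate departure from a pure
five-cell softmax: without it, S at the last cut point would be forced to
zero and subjects censored past the horizon would have no likelihood
contribution. With it, a subject censored beyond `t_max` contributes
`−log y_beyond`, consistent with `S(t_max) = y_beyond`.

Training minimizes `L = L_1 + λ_rank·L_2`:

* `L_1` — mean negative log-likelihood: `−log y_{bin}` for events,
  `−log S(bin)` for censored subjects, probabilities clamped at 1e−12
  inside logs (numeric safety only; clamping is never active for a healthy
  softmax output).
* `L_2` — mean of `exp(−(F̂_i(bin_i) − F̂_j(bin_i))/σ)` over acceptable
  pairs (i has an event, `bin_i < bin_j`), zero when no pair is acceptable.

These are the standard DeepHit-style forms; `σ = 0.1` and `λ_rank = 0.5` by
default. The ranking term uses bins, not continuous times, matching the
resolution at which the head models hazards.

## Architecture

**Image encoder.** A 3D ViT: non-overlapping 8³ patches over the 4-channel
volume (a 32³ volume gives 64 tokens of raw dimension 2048), linear patch
embedding to width 32, learned positional embeddings, 2 pre-norm
transformer blocks with 4 heads and MLP ratio 2, and a final layer norm.
This desk-scale sizing keeps CPU training in seconds-to-minutes; larger
settings are configuration-only. The decoder for context restoration is a
linear unpatchify head — the simplest faithful restoration target — and the
contrastive projection is a two-layer MLP on the mean-pooled tokens.

**Self-supervised objective.** Each volume is corrupted twice per step by
swapping 4 disjoint patch-aligned block pairs and zeroing 2 random boxes of
extent ≤ 6 voxels (patch-swap blocks equal the tokenizer patch so one
corruption never straddles tokens). Reconstruction is mean absolute error
against the clean volume; the contrastive term is NT-Xent at temperature
0.1 over the 2N pooled projections. The default combination is the
product-regularized form `L_rec + λ·L_con·L_rec` with `λ = 1`; the additive
form, and each term alone, are selectable for ablations. Under embedding
collapse NT-Xent equals `log(2N−1)` exactly, which serves as a collapse
detector in training logs.

**Fusion.** Covariates are encoded by a trainable fully connected module
into 4 tokens of width 32. Cross-attention runs twice with independent
projections (image→clinical and clinical→image); the final attention layer
takes the concatenated enriched sequences as keys/values and the *raw*
clinical projection as query — of the two readings of the design this
package adopts the raw projection, on the grounds that the clinical
sequence empirically carries the stronger prognostic signal and the final
layer should be steered by it. Learned positional embeddings are added to
image tokens only, before fusion; layer norm precedes every attention site
(pre-norm), chosen for stability at small batch sizes. Attention pooling
with a learned query collapses the fused sequence; two fully connected
layers emit the 6 logits.

The encoder is frozen before survival training; freezing is enforced by
dropping gradient tracking on its parameters, and tests assert both a
stable parameter checksum and the absence of any gradient buffer.

For clinical-only operation the same machinery runs with α = β (self-
attention); for imaging-only operation the mean enriched image token stands
in as the final query.

## Synthetic cohorts

The generator emulates the structure the model assumes, with known ground
truth:

* **Covariates** mirror a multicenter glioblastoma table: age ~ N(63, 12)
  truncated to [18, 90], 60% male, 57% gross total resection, MGMT
  methylated 50% with 20% missing-completely-at-random, 90% IDH wild-type,
  KPS ≥ 80 in 60% with 30% missing. Missingness is MCAR — real cohorts'
  "not available" fractions are matched in magnitude but not mechanism.
* **Imaging**: an ellipsoidal "brain" of Gaussian-noise intensity with a
  spherical lesion whose volume fraction (target range 0.01–0.15) enters
  the hazard linearly; per-channel intensity offsets give the same geometry
  different conspicuity per contrast. Default imaging effect for fusion
  experiments is 20 log-hazard per unit fraction, sized (once, by
  simulation) so imaging contributes at least +0.05 oracle concordance over
  the clinical signal alone.
* **Outcomes**: per-bin hazard `h_m = logistic(b_m + lp)` with baseline
  logits (−2.0, −1.4, −1.0, −0.8, −0.6) over bins ending at 120, 240, 365,
  540, 730 days, putting the median near 12 months. Event bins are sampled
  sequentially; continuous times are uniform within the bin (avoiding grid
  artifacts in KM and concordance estimates). Censoring is uniform on
  [0, horizon] with the horizon bisected to the target censored fraction —
  independent of risk by construction.

Because the true hazards are recorded, the Bayes-optimal time-dependent
concordance can be computed exactly and acts as the ceiling against which
trained models are judged.

What passing tests on these cohorts do **not** show: robustness to MR
physics (bias fields, motion, registration error), informative censoring,
site effects, multifocal disease, or covariate missingness that correlates
with outcome. The generator is a statistical emulator, not an imaging
simulator.

## Evaluation statistics

* **Time-dependent concordance** follows the Antolini formulation: the
  predicted CIF is evaluated at the earlier subject's time bin; pairs are
  comparable when `t_i < t_j` and subject i has an event; ties in the
  prediction count 1/2.
* **Brier / integrated Brier** use inverse-probability-of-censoring
  weights from the Kaplan–Meier estimate of the censoring distribution
  (`Ĝ(t_i−)` for events by t, `Ĝ(t)` for survivors, censored-before-t
  subjects contribute 0); the integral is trapezoidal over the monthly
  grid, normalized by its span. Month-grid integration (rather than
  cut-point integration) was chosen to match the resolution of the
  interpolated curves.
* **Kaplan–Meier, log-rank, Cox, Schoenfeld**: product-limit estimation
  with deaths preceding censorings at ties; the standard two-group log-rank
  with hypergeometric variance; Newton–Raphson maximization of the Breslow
  partial likelihood converging at max |score| < 1e−8 with step-halving
  tolerant of float-level likelihood noise; the Grambsch–Therneau test on
  scaled Schoenfeld residuals (`s* = d·Cov(β̂)·r`) against Kaplan–Meier
  transformed time `g(t) = 1 − Ŝ_KM(t)`.
* **Risk dichotomization**: predicted median survival is the first month
  with S < 0.5 (infinite if never); "favorable" means strictly above the
  12.0-month threshold, so a median exactly at the threshold is
  unfavorable.

## Protocol

Splits are 70/15/15 with exact sizes (largest-remainder rounding) and
stratification by event indicator × survival-time tertile, falling back to
event-only strata when a cell is empty. All preprocessing statistics
(intensity landmarks, covariate ranges, category maps) are fitted on the
training split only and frozen; fitted objects refuse to re-fit. The test
split is evaluated exactly once per experiment — a consumed flag makes a
second evaluation an error. Two seeds (data, model) determine everything;
identical configurations reproduce predictions bitwise on a single thread.

Training uses Adam (lr 1e−3 to 3e−3 in the provided configurations, batch
16–64) with early stopping on the validation likelihood term at patience
10, restoring the best state.

## Problem sizes

The shipped configurations are sized for a single CPU: pretraining on
60–200 volumes of 32³ voxels for 10–30 epochs, survival training on cohorts
of 200–600 subjects, and calibration studies with 200–1000 replicates.
These sizes are the package's reference conditions; every reported quantity
in `scripts/acceptance.py` is computed fresh at run time under them.

## Known limitations

* The autodiff engine is minimal by design: no GPU, no mixed precision, no
  shifted-window attention; throughput limits pretraining to desk-scale
  volumes.
* Competing risks are not modeled (K fixed at 1); the cell indexing is kept
  general but cause-specific formulations are out of scope.
* The imaging-only configuration is functional but secondary; its final
  query (mean enriched token) is a pragmatic choice, not a tuned one.
* Bootstrap confidence intervals for the metric reports are not built in;
  the acceptance script reports point estimates.
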