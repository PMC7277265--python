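# Methods

This note documents the models, numerical choices and known limitations of
`semdepth`, in the order data flow through the package.

## Simulated experiment

The generator (`semdepth.simulate`) emulates a two-condition event-related
visual-word experiment: 8 runs, 36 word trials per run (one trial for each
of 18 living and 18 non-living Spanish nouns, randomly ordered), TR 0.85 s,
520 volumes per run of which the first 9 are steady-state dummies, up to two
number-word catch trials per run, and alternating deep/shallow runs
(overridable `condition_order`).  Each trial is fixation (0.25 s), blank
(0.5 s), word (1 s), task delay (4 s), then a jittered inter-trial interval
drawn from {6.0, 6.5, 7.0, 7.5, 8.0} s with probabilities
(0.5, 0.25, 0.125, 0.0625, 0.0625) — a halving ("pseudo-exponential") law
whose tail mass is split equally over the last two levels so it sums to 1.

**Trial spacing.** Summing all component durations gives an onset-to-onset
interval of 11.75–13.75 s, which cannot accommodate 36 trials plus catches
within a 520 × 0.85 s run.  An interval of 10.75–12.75 s does fit, and the
default `spacing="compact"` rule reproduces it by counting the 1 s word
display inside the 4 s delay; `spacing="component_sum"` implements the
strictly additive reading for designs with room to spare.  The generator
raises a configuration error naming the run whenever a drawn schedule would
exceed the run length.

**Signal model.** Each ROI carries a category pattern per class and an
i.i.d. word-deviation pattern per word, all centred across voxels
(zero spatial mean).  The amplitude of trial *t* (word *w*, category *c*) is

    gating[t] * (gain_condition * category_pattern[c] + word_gain * word_pattern[w])

where `gain_condition` is `category_gain_deep` or `category_gain_shallow`.
The neural time course is a boxcar spanning word onset through the task
delay (5 s, configurable), convolved with a canonical double-gamma HRF
(positive gamma delay 6, undershoot delay 16, ratio 1/6, sampled at TR/10
and normalized so an isolated trial peaks at 1 — gains are therefore peak
BOLD amplitudes in noise-SD units).  On top of the signal: a baseline of
100, per-voxel random linear drift plus a slow cosine (period 120 s,
amplitude `drift_amplitude`), and white Gaussian noise (`noise_sd`).

Two deliberate consequences of this construction:

- *Word deviations are i.i.d.*, so held-out words carry no category
  information in expectation; a finite pool of 18+18 words still leaks a
  chance class-mean, which is why out-of-sample (word-pair) accuracy
  fluctuates around 0.5 with SD ≈ 0.05 per dataset.  (Forcing the
  deviations to sum to zero within category was rejected: the constraint
  makes each held-out word anti-correlated with the sum of its trained
  category-mates and produces systematic anti-learning.)
- *Patterns have zero spatial mean*, so trial-to-trial gating moves
  information content without moving the ROI-mean signal.  Gating coupling
  between ROIs (a Gaussian copula on the per-trial gains, with the latent
  correlation pre-corrected so the realized Pearson correlation of the
  uniform gating series equals the configured strength) therefore changes
  informational connectivity while leaving functional connectivity flat by
  construction — the dissociation the IC control analysis is meant to
  demonstrate.  Coupling entries may name a condition, in which case the
  mixing applies only to that condition's runs.

The generator does **not** model spatial autocorrelation, physiological
noise, motion, or anatomical variability.  Passing tests therefore show the
pipelines recover what they are designed to recover under their own
assumptions, not that they are robust to those nuisances.

## Preprocessing

Dummy volumes are dropped; voxels constant within any single run are
removed from every run (a `per_run=False` switch tests the stacked series
instead); each voxel is then linearly detrended and z-scored within run —
detrend before scale, so the output has exactly zero mean and unit SD.
Voxels whose detrended residuals are (numerically) constant are zeroed and
reported rather than rescaled.  Trial examples average the six volumes
acquired from 3.4 s after word onset; the classifier feature vector
averages the subset acquired no later than 6.8 s (five volumes at TR
0.85 s).  At this TR the closed interval [3.4, 8.6] s contains seven grid
points, so the six-volume count is taken as definitive and the window is
"first six volumes at/after onset + 3.4 s"; both the five- and six-volume
vectors are exposed (`vector="classifier"` / `"example"`).  Trials whose
window runs past the end of a run are dropped and reported, not raised.

## Decoding

PCA is fitted on the training split with component count
min(training examples, voxels) — when voxels exceed examples this is an
information-lossless rotation into the span of the examples — and the
projected data feed a linear SVM (liblinear squared-hinge, L2, C = 1,
tol = 1e-4; the variant is recorded in result metadata because only the
penalty, cost and tolerance are canonical).  Stratified splits hold out 20%
with *exactly* equal per-class counts on both sides (rounding ties toward
the smaller test set); word-pair splits enumerate all living × non-living
pairs (324 at full pool size; `n_pairs` subsamples); leave-one-run-out
warns that few-fold estimates are unstable.  Group statistics: per
ROI×condition one-sample *t* against 0.5 with BH-FDR within condition
across ROIs, and per-ROI paired deep−shallow *t* with BH-FDR across ROIs
(Benjamini–Yekutieli available by flag).

## Informational connectivity

For each condition, a leave-one-trial-out loop trains the PCA+SVM pipeline
on the individual volumes inside the remaining trials' 3.4–6.8 s windows
(each volume labelled with its trial's category) and evaluates every volume
of the left-out trial, recording the probability assigned to the true
category.  Probabilities come from Platt-style logistic calibration of the
training decision values (default) or a plain sigmoid of the decision value
(`probability_mode="sigmoid_decision"`); which mode produced a series is
recorded.  Volumes before the first onset belong to no trial and are
excluded; catch trials are skipped.

IC is the pairwise Pearson correlation of these series; FC is the same
correlation between ROI-mean time courses.  Constant series give undefined
(masked) entries, never zero.  The permutation effect size shuffles one
series n_perm times (default 10,000) and reports
(r_true − null mean) / null **variance** — the variance form is
deliberate and a `use_sd` flag provides the conventional z-like variant.

One property worth stating plainly: ROIs scanned in the same runs share an
event-locked discriminability profile (values rise and fall within each
trial for every ROI simultaneously), so raw IC — and the shuffle-null
effect size, which destroys exactly that timing — is positive even between
ROIs with no planted coupling.  Claims about coupling should therefore rest
on the condition *contrast* (paired deep−shallow per ROI pair, BH-FDR
across pairs), which cancels the shared profile; the effect size is
accuracy-independent in the sense that raising discriminability levels does
not push genuinely independent, exchangeable series out of the null band.

## Encoding

Per stratified fold (default 300, 80/20, stratified by category label —
labels are used *only* for partitioning), feature columns are standardized
with the training rows' mean and SD (fitting the scaler per fold avoids
test-set leakage; the scoping is a package choice) and mapped to voxels by
ridge regression with penalty α = 100.  Per-voxel performance is the R² on
held-out trials averaged over folds: at most 1, negative when the model is
worse than predicting the mean.  The aggregate reported by default is the
mean over positive-VE voxels (those "identified for further analysis"),
with the mean over all voxels always available — both are exposed because
either convention is defensible.  The empirical chance pipeline is
identical except each fold's *training* feature rows are permuted against
intact targets.  RDMs mean-centre each feature dimension across words and
use correlation distance (1 − Pearson between word rows; cosine available);
degenerate zero-variance rows yield flagged NaN entries.  Model-family
comparison: within-family one-way ANOVA per ROI×condition (BH-FDR over
ROIs within condition), all vision−embedding per-subject differences
tested against zero with BH-FDR, the mean family difference contrasted
deep vs shallow with paired *t* + BH-FDR, and percentile bootstrap 95% CIs
of mean VE (1,000 resamples).

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run everything at desk scale as
a matter of design: 50 stratified splits (instead of 300) for chance
calibration over 20 simulated subjects; 6 runs × 18 trials, 16-voxel ROIs
and 14 subjects for the IC/FC contrast; 1,000 permutations for effect
sizes; 50 encoding folds.  These sizes were chosen so each property is
measured with comfortable statistical margin while a full run stays in the
minutes range on one CPU.  Every stochastic step takes an explicit seed
(NumPy `default_rng`), and identical seeds give bit-identical outputs,
including through the CLI.

## Known limitations

- The simulator's noise is white; high-pass-filtered real data have
  temporal autocorrelation that widens all null distributions.
- Word-pair generalization on i.i.d. word patterns has irreducible
  dataset-level variance (finite word pool); bands tighter than ±0.02 on
  its mean would need more than 20 simulations.
- LinearSVC's squared-hinge/penalized-intercept details are one concrete
  choice within "linear SVM with default parameters"; accuracy is
  insensitive to the variant but decision values (and hence calibrated
  probabilities) are not guaranteed to match other implementations.
- `compare_models` treats models as a between-group factor in the one-way
  ANOVA (no subject random effect), matching the stated analysis rather
  than the repeated-measures design a mixed model would assume.
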