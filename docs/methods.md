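# Methods

## The analysis in brief

The pipeline decodes binary stimulus or decision categories from
distributed activity patterns in small anatomical ROIs. Per subject it
estimates a *beta series* — one GLM coefficient image per trial — and
feeds the trial × voxel matrix of each ROI to a two-step classifier:
searchlight feature selection followed by a linear support vector machine,
wrapped in an outer leave-one-trial-out loop. Group inference compares the
per-subject accuracies to the 50% chance level and across regions.

Because no real data ship with the package, a synthetic-cohort generator
defines the study conditions and provides ground truth; all claims the
test suite makes are claims about this generative world (see
"What the generator does and does not emulate").

## Synthetic data

**Masks.** Eight ROIs (CA1, CA3, DG, SUB × two hemispheres) are grown as
random 6-connected blobs inside disjoint octants of the grid, with exact
target voxel counts (defaults 267, 248, 183, 111 — typical means for
1.5 mm manual subfield segmentations). Only counts, connectedness and
disjointness matter downstream; no anatomical shape is modelled.

**Task and behaviour.** Nine stimulus categories — the proportion of
scene A in the morph: 1.0, 0.7, 0.6, 0.55, 0.5, 0.45, 0.4, 0.3, 0.0 —
each presented `n_repeats_per_stimulus` (default 40) times in a shuffled
order; one trial occupies 2.5 s stimulus + 3 s confidence rating + 2 s
rest = 7.5 s. Choices follow a logistic psychometric function
`P(A) = expit(slope · (morph_fraction − 0.5))` with default slope 10
(≈ 88% correct at the 0.7 morph). Confidence (1–3) thresholds a noisy
evidence variable `0.45 + 0.8·|fraction − 0.5| + N(0, 0.18)` at 0.30 and
0.60, so expected confidence rises with stimulus unambiguity while even
fully ambiguous trials are mostly rated "fairly sure"; with the default
3% no-decision rate this yields ≈ 4% exclusions for the unambiguous-scene
analysis and ≈ 25% for the 50%-morph analysis — the realistic regime.
Correctness is defined only where a right answer exists (fractions 0
and 1).

**BOLD.** Each trial adds its category's pattern vector (i.i.d. standard
normal across ROI voxels, scaled by `pattern_amplitude`) with the
HRF-convolved stimulus boxcar as time course, on a constant baseline of
100 with i.i.d. Gaussian noise (`noise_sd`, default 2 — 2% of baseline)
and an optional linear drift. Noise is white: no autocorrelation, motion,
physiological or scanner artifacts are simulated. 50%-morph trials
express the pattern of the trial's latent decision state (the simulated
choice) instead of a stimulus pattern; the state pattern is
`s·p + sqrt(1 − s²)·q` with `p` the matching 100%-scene pattern, `q`
independent, so its correlation with the scene pattern is exactly
`s = morph_pattern_share`. The default share of 0 reproduces the
qualitative dissociation in which cross-condition decoding sits at chance
while both within-condition analyses succeed.

All randomness derives from one integer seed through named
`numpy.random.default_rng` streams (masks, schedule, behaviour, patterns,
noise), so identical configurations are bit-reproducible.

## GLM

Volumes are smoothed with an isotropic Gaussian
(`sigma = FWHM / (2·sqrt(2 ln 2))` in voxel units, default FWHM 3 mm,
reflective boundaries — which preserves the total image sum). The design
has one column per trial: a boxcar of the stimulus duration at the trial
onset, convolved with the canonical double-gamma HRF (peak 6 s,
undershoot 16 s, unit dispersions, undershoot ratio 1/6, 32 s kernel),
built on a 16×-oversampled grid and decimated at scan times, so onsets
need not align to the TR. Nuisance columns and an intercept follow.
Per-voxel ordinary least squares (via pseudo-inverse) returns the task
betas; a rank-deficient design is rejected with the collinear columns
named (rank-revealing QR). No high-pass filter or autocorrelation model
is applied — the synthetic noise is white, and the generator applies no
slow drift by default. One run per subject is modelled.

## Decoding

**Searchlight scores.** For each ROI voxel, the neighbourhood is the
radius-3 sphere (123 offsets) clipped to the ROI, so its size varies near
borders. The score is the leave-one-out cross-validated accuracy of a
linear SVM (C = 1) on the neighbourhood's features, computed strictly
within the training data at hand — inside an outer fold that means the
n − 1 training trials, giving the inner cross-validation k = n − 1 folds.

**Selection.** Centres are ranked by score, ties broken by lexicographic
centre coordinate for determinism. The default `union_top` rule unions
the neighbourhoods of the top-ranked centres until the union reaches a
target fraction (default 0.6) of the ROI — about 160 voxels for a
CA1-sized ROI; a `single_best` rule (one neighbourhood) is also
available. A single radius-3 sphere holds at most 123 voxels, so typical
reported selected-voxel counts above that are only reachable by a union;
this motivates the default.

**Outer loop.** Leave-one-trial-out: per fold, scores and selection are
recomputed from the training trials alone, an SVM is trained on the
selected voxels, and the held-out trial is predicted; accuracy is the
fraction of correct held-out predictions. Cross-condition decoding does
selection and training once on the full training condition and evaluates
once on the disjoint test condition.

**Feature scale.** The pipeline feeds the classifiers t-unit features:
each trial coefficient divided by its OLS standard error (per-voxel
residual sd × the regressor's leverage factor), computed from the design
and the whole-run residuals — never from trial labels or any train/test
split, so it cannot leak. The reason is not cosmetic: realistic BOLD
scales give raw trial betas an sd of order 0.01–0.1, and a fixed-C hinge
SVM on such tiny features is dominated by its (regularized) intercept —
it then always predicts the training majority class, which in
leave-one-out is systematically the *wrong* class for the held-out trial,
driving null accuracy to 0 instead of 50%. t units restore the scale the
fixed hyperparameter presumes while keeping the decoder itself free of
data-dependent preprocessing. An optional per-fold per-voxel z-scoring
(fit on each outer fold's training trials) exists but is off by default:
its fold-dependent mean-centering carries a trace of the training fold's
class imbalance and measurably depresses null accuracy for very small,
smoothed ROIs.

**SVM.** The classifier is a hinge-loss linear SVM with the intercept
carried as an augmented, regularized constant feature (the liblinear
formulation), solved in the dual to a projected-gradient tolerance of
1e-4 by deterministic coordinate descent. The nested procedure needs
millions of fits on tiny problems (tens of trials, ≤ 123 features), where
the per-call overhead of general-purpose wrappers dominates, so the
solver is implemented in numba with two accelerations: leave-out refits
warm-start from the full-data dual solution, and short coordinate-descent
bursts alternate with an exact (ridge-stabilised) solve of the
free-support-vector subsystem plus a box line search, which removes the
zigzag convergence tail on these low-rank duals. The test suite verifies
the solver against scikit-learn's liblinear (same formulation, decision
values match to 1e-3) and libsvm (qualitative agreement), and verifies
that warm-started leave-out tables equal exhaustive cold refits exactly.
Ties at a decision value of exactly 0 predict the lexicographically
larger class, deterministically.

## Group statistics

Per-region accuracies (collapsed across hemispheres by per-subject
averaging, after a per-region two-level repeated-measures check that is
numerically the square of the paired t-test) are compared to chance with
two-sided one-sample t-tests; regions are compared with a one-way
repeated-measures ANOVA, `F = MS_regions / MS_(subject×region)` with
dfs `(r−1, (r−1)(n−1))`, computed from the explicit sums-of-squares
decomposition; significant effects are followed by all six pairwise
paired t-tests. The threshold is p < 0.05 throughout, with no sphericity
or multiple-comparison correction by default (matching common reporting
practice; both omissions are caveats for real use). Zero-variance inputs
are reported as flagged degenerate results rather than errors: identical
values at the reference give t = 0, p = 1; a constant nonzero offset
gives t = ±inf, p = 0 (and F = inf for a zero interaction term).

## What passing tests do and do not show

The generator's noise is white and Gaussian, its patterns are i.i.d.
across voxels, trials are temporally well separated, and anatomy is
reduced to connected blobs. Results on this world validate the
*machinery* — leakage-freedom, chance calibration, signal recovery,
metric identities — not the neuroscience: autocorrelated noise, pattern
smoothness, motion, susceptibility artifacts and anatomical variability
can all change absolute accuracies on real data. The small-sample
behaviour of leave-one-out is also real and worth knowing: with very few
trials per class, the one-trial class imbalance in each training fold
gives any classifier a genuinely below-chance expectation under the null;
at the study's 40 trials per class this bias is negligible, and the
chance-calibration check is run at that trial count.

## Problem sizes used in validation

The chance-calibration experiment uses 100 subject-ROI datasets on a
14 × 14 × 10 grid with 16-voxel ROIs and 40 trials per class — the trial
count of the emulated study, with grid and ROI reduced to what a single
CPU handles comfortably. Signal-recovery and dissociation checks use
similar reduced grids with amplitudes spanning chance to ceiling. Full-scale
cohorts (16 subjects, 267-voxel CA1, three analyses) run with the same
code path but are not part of the default test run.

## Known limitations

- One scanning run per subject; no motion/physiological nuisance model.
- The selected-voxel count is controlled by a target fraction, not
  learned; the `single_best` alternative is provided but the exact
  mechanism behind any particular reported count is underdetermined.
- The repeated-measures ANOVA offers no sphericity correction by default.
- `simulate_bold` holds the whole run in memory (~200 MB at full scale).
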