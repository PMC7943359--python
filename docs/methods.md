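# Methods

`stereorsa` implements the full analysis chain of a backward-masking fMRI
study of stereotype-biased face perception, together with a synthetic-data
generator that plants every effect the chain is supposed to detect.  This
note records the models, the generator's assumptions, the parameter
defaults, and the numerical conventions; anything quantitative stated here
is computed by the test suite or the pipeline, not asserted from memory.

## The analysis chain

**Design.**  Four face conditions cross sex and emotion: angry male, happy
male, angry female, happy female (35 faces per cell, 140 total).  Scanning
uses four runs — two backward-masked runs always first, then two unmasked
runs — each trial a 4 × (33 + 167 + 300) ms sequence totaling 2000 ms (one
TR), with 77 null events per run.  Outside the scanner, subjects categorize
every face twice (once by gender, once by emotion; 280 mouse-tracking
trials), rate 30 descriptors for each of the four categories (120 rating
trials), and perform a masked gender-discrimination task.

**Stereotype strength.**  For the four 30-length rating vectors we compute
all pairwise Pearson correlations and score

    s = ([r(angry,male) + r(happy,female)] − [r(angry,female) + r(happy,male)]) / 2,

which spans [−2, 2]: +2 is a maximal male = angry / female = happy
association, 0 none, −2 the reverse.  The literal difference of correlation
sums spans [−4, 4]; we divide by 2 so the score matches its published
[−2, 2] anchors (the unhalved sum is available via `halved=False`).

**Mouse-tracking.**  Trajectories are translated to a standard space with
the start at (0, 0) and response targets at (±1, 1.5) (the convention of
the common mouse-tracking toolbox), mirrored so the chosen response lies
right, and resampled to 101 points (100 time bins, endpoints inclusive) by
linear interpolation.  MD is the signed perpendicular distance, from the
direct start→response line, of the path point with the largest absolute
deviation — positive toward the opposite response, negative for paths
bowing toward the chosen side.  Trials are excluded when they exceed the
2000 ms deadline (a trial at exactly 2000 ms is kept) or end at the wrong
response.  `max(MD)` is defined as the perpendicular distance of the
opposite response location from the direct line (≈ 1.664 in standard
space): the farthest meaningful deviation.  The normalized bias
`MD/max(MD)` is clamped to [0, 1]; its complement is the bias toward the
selected response.  Per condition, the two block means yield a 4-length
similarity vector over (angry, happy, male, female), and Pearson distances
(1 − r) between condition vectors form the 4 × 4 subjective DM.  The
group-average DM averages subjects' similarity vectors element-wise first
and computes distances on the averages (mean-then-distance).

**Congruency model DM.**  Distance 1 between the congruent pair (angry
male ↔ happy female), 2 between the incongruent pair (angry female ↔ happy
male).  The four pairs the hypothesis is silent about sit at the midpoint
1.5, encoding no directional prediction; a pair mask allows excluding them
instead.  Note this hypothesis matrix is not a realizable correlation
structure (1 − DM is indefinite), so it can be a regression target but
never a generation target.

**Deviation model.**  Trial-level MD is regressed on gender (male = −0.5,
female = +0.5), emotion (angry = −0.5, happy = +0.5), the mean-centered
stereotype score, and all interactions, with subjects as clusters:
generalized estimating equations with an exchangeable working correlation
and robust sandwich standard errors (the robust covariance makes the
working-correlation choice immaterial).  Simple slopes at ±1 SD of
stereotype strength are linear contrasts B_ge ± SD·B_ges with sandwich
variances — algebraically identical to recentred refits.

**Signal detection.**  d′ = z(hits) − z(false alarms) with male faces as
signal, using the log-linear correction (0.5 added to each count, 1 to
each total) so extreme rates stay finite.  Subjects with |d′| ≥ 1.74 (the
chance band, treated as a given constant) are flagged: masking failed for
them.

**Pattern estimation.**  Condition regressors are 2000 ms boxcars
convolved with a gamma-variate HRF h(t) ∝ (t/pq)^p e^{p−t/q}, p = 8.6,
q = 0.547 s (the family's de-facto defaults; peak at pq ≈ 4.7 s,
peak-normalized, h(0) = 0), sampled on a 20× oversampled grid.  Two
crossing schemes are supported: the four crossed cells, or the four
non-crossed categories (each event loading on its emotion and its gender
regressor).  Per-voxel OLS gives t statistics; per-condition t maps are
averaged over runs and z-normalized across in-mask voxels (population SD).
Nuisance regressors are accepted as a user-supplied matrix.

**RSA.**  Neural DMs are Pearson distances between condition patterns.
DMs are vectorized in a fixed order (row-major lower triangle of the
labeled matrix, shared by every module) and compared by Spearman rank
correlation (average-rank ties), or by multiple-regression RSA on
rank-transformed pair vectors (with intercept) when a covariate DM — the
group-average subjective DM — must be adjusted for.  Group inference is a
one-sample t test on Fisher-z-transformed rhos or raw betas; masking arms
are compared by a paired t test.  Negative betas are reported as-is.
With only six pairs, a subject's DM can tie the group DM in rank order
exactly, leaving the partial beta unidentified; such cases raise a
diagnosable error and the pipeline drops those subjects from the
individual-differences stages (counts reported).

**Searchlight.**  A radius-3 sphere (inclusive Euclidean distance on
voxel indices; 123 voxels) visits every in-mask voxel; the sphere is
intersected with the mask at edges (shrunk, not skipped; centers with
fewer than 2 usable voxels are missing, not zero).  The local
regression-RSA beta is written to the center.  Subject maps are smoothed
with a fixed Gaussian kernel (σ = FWHM/2√(2 ln 2), mask-aware
renormalization, default 6 mm at 2 mm voxels — a fixed-kernel
approximation of iterative smooth-to-FWHM).  Group inference is a
one-sided sign-flip max-statistic permutation test of the voxelwise t map
(default 5000 flips; the pipeline's desk-scale default is 300), which
controls family-wise error exactly under sign symmetry.
Threshold-free cluster enhancement is not implemented; the max-statistic
correction is the corrected-inference surface.

**PPI.**  The seed region's mean BOLD series is deconvolved against the
gamma HRF by ridge-regularized inversion of the convolution matrix
(penalty λ·tr(AᵀA)/n with λ = 10⁻³ by default; λ→0 recovers exact
deconvolution on noiseless input).  Because h(0) = 0 the kernel is a pure
delay: the final few time points of the neural series are unobservable
and are determined by the ridge prior alone — reconvolution is still
exact, which is what the interaction regressor needs.  The interaction is
the deconvolved seed times the psychological condition (masked = −1,
unmasked = +1, constant within a run) reconvolved with the HRF; a
BOLD-level product is available behind `level="bold"`.  The model has
three predictors of interest (seed, condition, interaction) plus an
intercept; deconvolution and reconvolution respect run boundaries.  A
liberal-threshold seed-definition utility keeps 6-connected clusters of
at least 20 voxels above a t threshold.  The final linkage correlates
per-subject PPI interaction betas with the per-subject
[unmasked − masked] RSA-beta difference, one-tailed for the directional
hypothesis r > 0.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes —
not faces, not realistic fMRI noise (no drift, motion, or physiology),
and not whole-brain geometry.  Passing tests therefore demonstrate that
the chain recovers planted effects under its own model assumptions, not
that it is robust to real-data artifacts.

**Ratings.**  Per subject a target score b is drawn from
N(bias_mean, bias_sd) clipped to [−2, 2] and realized exactly by
construction: with empirically orthonormal latent vectors v ⊥ u, angry = v,
happy = −v, male = ρv + √(1−ρ²)u, female = −male, ρ = b/2, centered at the
scale midpoint with amplitude 1.2 Likert units.  Element-wise noise
(default SD 0.3) attenuates empirical correlations by amp²/(amp²+σ²); ρ
is pre-inflated by the inverse factor (capped at |ρ| ≤ 1).  Ratings are
clamped to [1, 7] rather than resampled; clamping is rare at the default
amplitude and the implied angry↔happy correlation of −1 is an
idealization of the construction.

**Trajectories.**  Each path is a quadratic Bézier from (0, 0) to the
chosen target with its control point displaced perpendicular to the chord
toward the opposite response by amplitude A; the deviation profile is
2t(1−t)·A/… with maximum exactly A/2 at the midpoint, so planting
MD = m means A = 2m and MD is analytically known.  Sampling is at 60 ms
intervals (piecewise-linear resampling underestimates the peak by under
0.2%).  The planted trial MD is

    m = baseline + [incongruent]·(congruency_effect + moderation·(b_i − bias_mean)) + trait + noise

with the moderation term centered so the marginal gender × emotion
coefficient equals −2·congruency_effect regardless of the population
mean.  The trait term is a per-subject random offset per block × condition
cell (SD 0.08): stable perceptual idiosyncrasies, without which every
subject's subjective DM would share a single rank order (opposite cells
are near-exact complements of the bias vectors) and the
individual-differences analyses would be degenerate by construction.
Designated fractions of trials exceed the deadline (RT pushed past
2000 ms) or end at the wrong response.

**Defaults** (chosen to sit in the regime of the reference behavioral
results): stereotype bias mean 0.49, SD 0.62 (score units); MD baseline
0.40 and trial noise SD 0.50 standard-space units (condition means near
0.38–0.50); congruency effect 0.075 (read as gender × emotion B = −0.15
under ±0.5 coding); moderation 0.0285 (three-way B ≈ −0.057); exclusion
rates 2.83% timeouts, 3.70% errors; discrimination d′ mean 0.22; PPI
coupling c = 0.3.

**Patterns and volumes.**  Condition patterns mix four independent
unit-variance voxel vectors through the matrix square root of the target
correlation C = 1 − DM (validated PSD) plus voxel noise; the realized
distance DM converges to the target as voxels grow and noise shrinks.
Searchlight volumes place such patterns inside non-overlapping spherical
signal regions on a small grid, pure noise elsewhere.  The masked arm is
planted by giving the subject's own DM weight 0 (the target collapses to
the common group structure), the unmasked arm weight w_i ∈ [0, 1].

**BOLD.**  The seed's neural series is the stimulus boxcar; the target's
is a·seed + c·seed×condition (+ optional evoked term), both convolved with
the gamma HRF per run, with measurement noise added after convolution.
Voxelwise BOLD drives each voxel by its pattern amplitude so the GLM
recovers planted patterns exactly at zero noise.  Event schedules are
randomly ordered per run with the half-sample balanced across cells
(estimation-efficiency optimization is out of scope); onsets fall on the
TR grid and masked runs precede unmasked runs.

**The pipeline's coupling.**  One latent weight w_i per subject scales
both the expression of that subject's subjective DM in the unmasked arm
and their PPI coupling (c_i = c·w_i), making the
connectivity-disruption → representational-disruption link true by
construction with effect size controlled by the spread of w.

## Problem sizes

The default pipeline runs 24 subjects, 600-voxel ROIs, a 12³ searchlight
grid with one radius-4 signal sphere, and 300 sign-flip permutations —
sizes at which every stage's recovery behavior is visible on one CPU in
well under a minute.  The recovery and calibration studies in the test
suite use 100 subjects × 100 replicates for the deviation model, 100
subjects for the masking-arm RSA contrast, 200 reruns on 12³ grids for
the family-wise error calibration (null per-subject statistic maps fed to
the permutation stage), and 300 reruns for the link's null p-value
uniformity.

## Known limitations

- Generated trajectories are single smooth bulges; real trajectories
  show sub-movements, pauses and x-flips, so MD here is cleaner than in
  real data.
- The ratings construction pins the angry↔happy correlation at −1 and
  realizes scores exactly; real rating structure is noisier and
  higher-rank.
- The masked/unmasked manipulation is planted directly in the pattern
  targets; there is no model of partial awareness or graded masking
  efficacy.
- fMRI noise is white; no autocorrelation, drift or motion, hence no
  prewhitening in the GLM.
- With six condition pairs, rank-based partial RSA is intrinsically
  coarse: exact rank ties between subject and group DMs occur with
  non-trivial probability and those subjects carry no identifiable
  individual-differences signal.
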