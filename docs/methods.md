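# Methods

This note documents the models, numerical choices and known limitations
of the rewardmap pipeline in the order the stages run.

## Task model and behavioral scoring

The monetary gambling task is represented exactly: 240 trials at 2.5 s
per trial (10 min), a 1.5 s pie cue (win chance 25/50/75%) followed by a
1.0 s feedback stimulus at cue + 1.5 s. Six trial types with counts
40/40/60/20/20/60 are permuted uniformly at random under a seed. Bets
are 10 (safe) or 50 (risky) tokens; the token delta is +bet on a win,
−bet on a loss, 0 on a missed trial.

The simulated bettor is a logistic agent: the probability of a risky
bet is `sigmoid(logit(p_base) + a·L + b·(pie − 0.5))` where `L` counts
the consecutive losses immediately preceding the trial. It exists to
make the behavioral covariates controllable, not to model human
learning; no prospect-theoretic utility or reinforcement dynamics are
attempted.

Scoring counts, for K = 1..3, risky and safe bets whose K preceding
trials were all losses, and for K = 2..3 risky/safe bets whose K-trial
preceding window has a strictly negative token sum. Decisions that the
underlying task description leaves open, fixed here as defaults:

- **Missed trials break a consecutive-loss run** (they carry no wager
  and no outcome). The alternative reading — a missed trial is
  transparent and the run continues across it — is available via
  `missed_breaks_run=False`.
- **Overlapping windows all count**: a three-loss run followed by a
  risky bet increments the K=1, K=2 and K=3 counters. This matches the
  roughly 2x-per-K decay of typical score magnitudes.
- **"Net loss" is strict** (< 0); a window netting exactly zero counts
  as neither loss nor gain.
- Missed bets are excluded from every numerator; scores are invariant
  to trailing missed trials.

## BOLD simulation

The phantom is a desk-scale ellipsoidal "brain" on a 24 x 24 x 12 grid
(voxels 2.5 x 2.5 x 3.5 mm, world origin at the grid centre), roughly
2,800 mask voxels — a miniature of a full-resolution acquisition grid
chosen so a 30-subject cohort simulates and fits in seconds. Four
disjoint truth clusters of 48–60 voxels are planted well inside the
mask; three carry a win > loss contrast and one the reverse, mirroring
a study in which one region responds more to losses. All spatial
thresholds (minimum cluster size 20 here vs 100 on a full-scale grid)
scale with the config.

Each voxel's series is

    baseline
    + a_win·(h ∗ win-feedback onsets) + a_loss·(h ∗ loss-feedback onsets)   [truth voxels]
    + cue_amplitude·(h ∗ cue onsets)                                        [whole mask]
    + drift + motion_coupling·motion₁ + AR(1) noise

with h the unit-peak gamma HRF. Event regressors are evaluated by
direct summation of h(t_k − onset) at the TR grid — identical code to
the design-matrix builder, so noiseless simulation followed by fitting
recovers amplitudes to machine precision (an identifiability test, not
a realism claim). Task responses are locked to **feedback** onsets,
where the win/loss information arrives; the cue response is a separate
global signal so nuisance/task separation is testable.

Noise is stationary AR(1) (default marginal SD 1.0, lag-1 correlation
0.3) plus low-frequency drift (linear ramp and two cosine bases with
per-voxel random weights, amplitude 1.0) plus a motion-coupled artifact
(0.5 x the first of six smoothed-random-walk motion series). There is
no physiological (cardiac/respiratory) noise, no MR physics, no
susceptibility distortion, and no inter-subject anatomy: spatial
normalisation is the identity, all subjects share the phantom grid.
Consequently, passing tests demonstrate the statistical machinery under
the stated noise model — not robustness to registration error or
structured physiological confounds.

Cohorts draw each subject's per-cluster contrast amplitude
delta = a_win − a_loss from Normal(±1.0, 0.3) (sign per the cluster's
planted direction; a_loss fixed at 1.0). The default contrast-to-noise
ratio of 1.0 makes single-voxel detection comfortable at n = 240 while
leaving the between-subject structure realistic enough that the group
stage is non-trivial. Covariates are generated as
`cov = Σ_c r_c·z_c + sqrt(1 − Σ r_c²)·ε` over standardized cluster
amplitudes z_c, which achieves the requested population correlations
exactly when clusters are independent (they are, by construction);
requests with Σ r_c² ≥ 1 are rejected. Generated covariates are placed
on familiar instrument scales (e.g. an impulsivity subscale with mean
19.8, SD 4.61) purely for readability.

## Subject-level GLM

Estimation follows the pseudo-inverse formulation: G = (X'X)⁺,
β̂ = G X' y, σ̂² = (y'y − y'X G X'y)/df, df = n − 1 − rank(G),
t = C'β̂ / sqrt(σ̂² C'GC). Numerical choices:

- **Centring.** No explicit intercept column is used; the data and all
  regressors are temporally mean-centred before fitting, which is what
  the "n − 1" in the df formula reflects. Switchable (`center=False`).
- **Rank tolerance.** Singular values below (largest SV)·1e−10 are
  treated as zero, making df reproducible on rank-deficient designs.
- **Estimability.** A contrast outside the row space of a
  rank-deficient design (e.g. a subject with zero win trials) triggers
  a warning; the reported values are then based on the minimum-norm
  solution. Voxels with zero residual variance are flagged undefined
  (NaN), never silently zeroed.
- **HRF defaults** shape n = 3, tau = 1.25 s, delay = 2.5 s (peak 5 s
  after the event), all exposed in config since the gamma family is
  conventionally parameterised several ways.
- The **response** regressor is modelled at a fixed 0.75 s after cue
  onset (mid bet window); trial logs carry no reaction times.
- The default **11-column layout** uses four task columns
  (loss-feedback, win-feedback, cue, response) with contrast
  (0,...,0,−1,+1,0,0); a strict two-task-column 9-column layout is
  provided for sensitivity checks (`layout="two_task"`).
- t_v is an activation index; no parametric p-values are attached at
  the subject level. Residual autocorrelation is not modelled
  (no prewhitening), so subject-level t values are calibrated only
  under white noise — which the null-calibration tests verify — and
  are conservative-to-liberal under AR(1) noise; group inference uses
  only the across-subject distribution of contrast estimates, which is
  unaffected.

A caveat worth knowing: with exactly zero noise, the data-driven PC1
lies in the span of the task regressors (the only variance present),
making individual coefficients non-identifiable. Exact-recovery tests
therefore supply an external nuisance course as PC1; with any noise at
all the collinearity disappears and the pipeline computes PC1 from the
data as specified.

## Group refinement

Selection uses the across-subject one-sample t of the per-subject
contrast values C'β̂ (amplitude units, not t units — cluster summary
statistics then behave like response amplitudes; switchable), two-sided
α = 0.001 uncorrected by default. The selection matrix is
subjects x voxels: refinement operates on between-subject co-variation,
which is the quantity the subsequent correlation analyses use.

Sparse PCA is the elastic-net alternating scheme: an orthonormal
projection step A = UV' (SVD of X'X B) alternating with an L1
soft-thresholding loading step B_j = soft(X'(X a_j), λ)/(1 + ridge).
A voxel is kept iff it loads on any of the top k = 10 components.
Numerical choices:

- **Convergence** is declared on the sparse loadings: relative change
  below 1e−4 with a stable row support, or a row support unchanged for
  20 iterations with change below 5e−2. The rotation A can drift
  indefinitely when component variances tie (symmetric planted
  clusters); the kept set is what matters and stabilises long before A
  does. Non-convergence raises an error carrying iteration diagnostics.
- **Automatic penalty.** When no λ is given, column scores |X'X a_j|
  from the PCA initialisation are sorted and λ is placed in the largest
  multiplicative gap, ignoring splits that isolate fewer than 5% of
  columns (the extreme tail of near-orthogonal noise columns produces
  spurious gaps). If no gap reaches a factor of 1.9 the spectrum is
  treated as having no noise floor and every column is kept. The 1.9
  threshold sits between the within-signal spectral gaps observed on
  dense selections (≤ ~1.6, where pruning would discard real signal)
  and the genuine signal/noise gaps of sparse planted supports
  (≥ ~2.2). The chosen λ and resulting support are recorded in the run
  manifest. Note the α = 0.001 selection is often already almost pure
  signal, in which case keep-everything is the correct refinement and
  stray voxels fall to the size filter.
- λ = 0 reduces to ordinary PCA support (all columns kept); support is
  non-increasing along an increasing penalty path.

Clusters are connected components of the kept set (26-connectivity by
default; 6 and 18 available), dropped below the minimum size, ordered
by size. The centroid is the affine-mapped mean voxel coordinate; the
anatomical label is read from a label volume at the labeled voxel
nearest the centroid. A toy six-region label map (left/right x three
anterior-posterior bands) ships with the package as a stand-in for an
atlas; real atlases can be supplied as a label volume + name table.
Direction is win>loss iff the group-mean cluster value is positive.
Per-subject cluster values are plain means over cluster voxels;
summaries use the n−1 SD and SE = SD/√n.

## Correlation reporting

Pearson r with two-sided p from the exact transform
t = r·sqrt((n−2)/(1−r²)) on n−2 df, pairwise-complete deletion, and
per-cell n recorded (real covariate tables often miss a subject; the
printed SEs of some published neuropsychological tables are consistent
with n = 29 rather than 30, so no global n is assumed). Inter-cluster
correlations are Bonferroni-corrected over the k(k−1)/2 unordered pairs
(m = 45 at k = 10) at family-wise α = 0.05. The cross-domain
(cluster x covariate) table is deliberately uncorrected — the
convention for small exploratory samples — and instead classifies every
cell by |r|: negligible < 0.1 ≤ small < 0.3 ≤ moderate < 0.5 ≤ large
(configurable). Descriptive tables round half away from zero at 2
decimals, matching how summary tables are conventionally printed.

## Reproducibility

All stage seeds derive from a single master seed via
`numpy.random.SeedSequence` spawning; no stage consumes unseeded
randomness. Manifests echo every resolved parameter plus a hash of the
config; repeated runs reproduce all TSV outputs byte-identically.

## Problem sizes

The shipped defaults are desk-scale by design: 24 x 24 x 12 grids,
240 volumes, 30-subject cohorts, 20-seed recovery studies, a 500-subject
streaming run for correlation recovery, and 200–500-replicate oracle
suites. These sizes give Monte-Carlo error comfortably below every
tolerance asserted in the tests while a full test-plus-acceptance cycle
stays in the minutes range on a single core.

## Known limitations

- No slice-timing, motion re-estimation, registration, or distortion
  correction; motion enters only as known nuisance series.
- Noise is stationary AR(1) + smooth drift; no physiological noise.
- The sPCA orientation (subjects x voxels) is one of two defensible
  readings; a time x voxels variant is not implemented.
- No permutation-based cluster-level inference and no canonical
  correlation analysis; the correlation tables are exploratory.
- The betting agent is memory-one (consecutive-loss count); richer
  sequential strategies are out of scope.
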