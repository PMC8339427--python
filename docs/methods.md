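# Methods

This note documents the models, numerical procedures and design choices
behind `icatk`: what the toolkit computes, what the synthetic-data generator
does and does not emulate, and where genuinely open choices were resolved.

## The test and its scores

The ICA is a rapid visual categorisation task: 100 grayscale natural images
(50 with an animal, 50 without, of varying difficulty) are shown for 100 ms
each, followed by a 20 ms blank interval and a 250 ms dynamic backward mask
that curtails recurrent visual processing.  The participant categorises each
image as animal / non-animal.  A 10-image practice block (5 per category)
gates entry: above chance (≥ 6 of 10) proceeds, a failed first block triggers
a retry with fresh images, a second failure restarts the flow.  The number of
attempts accumulates across restarts because it is itself informative about
impairment.

Two readings of the practice rule ("at chance or below" on the first attempt
vs "below chance" on the second) conflict; both gates here use the same rule —
more than 50% of 10, i.e. ≥ 6 correct, passes.  Timeouts are recorded as
`response = none`, count as incorrect for accuracy, and are excluded from the
mean correct RT; the response window defaults to 3000 ms.  Reaction time is
referenced to image onset (the usual psychophysics convention).

Scores for a session:

* `Accuracy = 100 · n_correct / n_main_trials` (timeouts incorrect),
* `Speed = min(100, 100 · exp(−RT/1025 + 0.341))` where `RT` is the mean
  reaction time of correctly answered, responded main trials,
* `ICA Index = Speed · Accuracy / 100`,
* `ICA Score = (1 − AI probability) · 100` for the classifier's output.

The typeset form of the speed equation is ambiguous about whether `+0.341`
sits inside or outside the exponent.  The inside reading is adopted: it puts
the speed cap at `RT = 1025 × 0.341 = 349.525 ms` and implies group mean RTs
of roughly 610–810 ms for the published group speed values, which is
plausible for masked categorisation in older adults, whereas the outside
reading implies ~300 ms, faster than the stimulus-to-response pipeline
allows.  The constants live in `SpeedConstants` and are configurable.

## Mask generation

One seeded white-noise field (default 256 × 256, i.i.d. uniform intensities)
is smoothed with Gaussian filters at four spatial scales — σ ∈ {1, 2, 4, 8}
pixels for a 256-px frame, rescaled proportionally for other sizes — and each
smoothed image is thresholded at its median, which guarantees a high-contrast
≈ 50/50 binary pattern and makes the output depend only on the rank order of
intensities.  Four variants per scale are produced by rotating 90°, 180°,
270° and mirroring horizontally; the un-transformed pattern is *not* included,
since 4 scales × 4 variants must equal the stated pool of 16.  A per-trial
mask draws two distinct frames per scale and shuffles the eight into a random
order; each frame is displayed for 250/8 = 31.25 ms (a uniform split — the
per-frame duration is otherwise unspecified).  Display geometry (the 7°
visual angle) is not modelled.

## Synthetic cohorts

The generator reproduces the *structure* the analysis relies on, not human
cognition.  Its components:

* **Demographics.** Per (cohort, diagnosis) group, age and education are
  truncated normals with the published group means/sds (age windows 30–95 for
  cohort 1, 55–90 for cohort 2 per its recruitment criterion); sex is
  Bernoulli at the published female fraction; MoCA and ACE are rounded,
  clipped normals loaded 0.6 on a shared latent cognition factor, so
  convergent-validity correlations come out positive (the exact r is not a
  calibration target).
* **Responses.** Rasch-style with a guessing floor: P(correct) =
  `g + (1−g)·logistic(ability − difficulty)` with `g = 0.35`.  The floor sits
  below the 0.5 forced-choice chance level so that severely impaired profiles
  can fail the above-chance practice gate.  Item difficulties are standard
  normal (bank standardized to exact zero mean / unit sd so the realized bank
  matches the scale the calibration assumes).  Reaction times of responded
  trials are lognormal with within-session log-sd 0.25 and a difficulty shift
  of 0.04 log-units (harder → slower); 2% of trials time out.
* **Heterogeneity.** Latent ability and log-RT location vary between
  participants with sds {0.6, 0.7, 0.9} and {0.15, 0.20, 0.30} for
  healthy / MCI / mild AD — chosen once so simulated ICA-Index group sds land
  near the published ~8 / ~11 / ~15.  Ability correlates −0.4 with age within
  healthy and MCI groups and 0 within mild AD, matching the published
  within-group pattern.  The RT location is *not* loaded on the shared
  cognition factor by default: a nonzero loading induces a within-group
  speed–accuracy covariance that lifts the realized group index mean above
  the product of the calibrated marginal targets (≈ +0.6 for mild AD at
  loading −0.5).  The loading remains exposed for users who want that
  coupling and accept the shift.
* **Calibration.** Group accuracy targets are the published
  accuracy-by-diagnosis values averaged over the two age bands
  (83.25 / 76.7 / 65.2%); group speed targets are derived from the published
  group ICA-Index means as `index_mean / accuracy_target × 100`, so index
  means are hit by construction.  The two latent location parameters per
  group are solved deterministically: expected accuracy and expected speed
  are computed by Gauss–Hermite quadrature over the between-participant
  latents (21 nodes each) and the item difficulties (realized bank when
  available, 41 nodes otherwise), and Brent's method inverts each.  The speed
  equation inverts in closed form, `RT = 1025 · (0.341 − ln(speed/100))`; a
  target at the cap is non-unique and returns the boundary RT.  Residual
  calibration error measured at n = 2000 per group is ≤ 0.4 on speed,
  accuracy and index.
* **Repeated-testing fixture.** 12 healthy participants (ages 26–73, mean
  48.2, sd 17.1) × 78 sessions = 936 scored tests, calibrated to the combined
  healthy targets, with an optional linear per-session ability drift (zero by
  default — the no-practice-effect null).  Only main blocks are simulated
  here; the fixture exists to feed the ANOVA, which the practice gate cannot
  affect under the null.

What the generator does **not** emulate: item-level content effects beyond a
scalar difficulty, response strategies, fatigue or learning within a session,
realistic practice-gate failure rates (simulated healthy participants pass on
the first attempt more often than the published 88%), cohort differences
beyond the published group parameters, or any claim of cognitive realism.
Passing tests therefore demonstrate the pipeline's correctness and internal
consistency, not clinical performance on real patients.

## Classifier

`ImpairmentClassifier` is logistic regression fitted with stochastic gradient
descent (scikit-learn `SGDClassifier`, logistic loss) on standardized
features (accuracy %, speed, ICA Index, age in years).  Standardization is
fitted on training data only — in cross-validation, per fold.  Defaults:
L2 regularization α = 1e-4, ≤ 1000 epochs, adaptive learning rate with
η₀ = 0.01, tolerance 1e-4, iterate averaging (ASGD) on, seeded shuffling.
Averaging plus the adaptive schedule is needed for a converged fit at
n ≈ 230: with the plain "optimal" schedule the cross-validated AUC on
identical data fluctuated by up to 0.14 across seeds, versus ≤ 0.01 for the
averaged fit, which matches a fully converged logistic regression reference.

The probability threshold is 0.5, inclusive on the impaired side (ties are
measure-zero; the convention is documented rather than consequential).
Class imbalance (95 healthy vs 135 impaired in the default cohort) is left
unweighted.

Leave-one-out cross-validation refits the whole estimator per fold and
predicts the single held-out participant.  Training rows are sorted into a
canonical (lexicographic) order before each seeded fit so the per-participant
probabilities are invariant to the order examples are supplied in; identical
rows are interchangeable, so ties in the sort are harmless.  Learning curves
draw `n_repetitions` (default 20) random training subsets per size, redrawing
up to 100 times when a subset loses a class (unavoidable near size 3), and
report mean test AUC with a normal-approximation 95% CI over repetitions —
the CI collapses to zero width at full training size, where every subset is
the whole set.

## Evaluation statistics

AUC is the Mann–Whitney pair-ordering probability (ties 1/2), computed on the
continuous probability score; its CI uses DeLong's method.  Sensitivity,
specificity and percent-agreement proportions use Wald normal-approximation
CIs clipped to [0, 100] — the convention consistent with the published
tables (Wilson intervals do not reproduce them).  Comparator predictions use
single cutoffs: MoCA ≥ 26 and ACE ≥ 90 are healthy.  For percent agreement
the comparator test is the reference for PPA/NPA denominators; OPA is
symmetric, so the directional choice does not affect it.  Cohen's d uses the
pooled sd with n−1 weights and a two-sample t-test p-value.  Displayed tables
round to one decimal, half-up; internal values are unrounded.

The practice-effect test is a one-way ANOVA of the ICA Index across session
number.  When the session table identifies participants, each participant's
scores are centred on their own mean first: with the same participants in
every session group, the raw one-way ANOVA is severely conservative (the
between-participant spread inflates the within-group variance while session
means, sharing the same people, barely move — measured rejection rate 0/200
under the null), whereas the centred version holds the nominal 5% size
(measured 4%, CI 1.3–6.7%).  Without participant identifiers the raw ANOVA
is used, preserving the textbook two-group F = t² identity.

## Numerical and degenerate-input choices

* Median thresholding of a constant image is rejected (`ValueError`), as is a
  pattern that comes out single-valued.
* `score_session` raises on sessions with no correct responded trials (speed
  undefined) and on empty main blocks.
* Group calibration rejects accuracy targets outside the achievable band
  `(100·(1−timeout)·g, 100·(1−timeout))` and speed targets outside (0, 100].
* Zero-variance groups make Cohen's d, Pearson r and the ANOVA undefined;
  all raise rather than returning NaN.
* LOOCV folds that lose a class are skipped with a warning and a NaN
  probability; loaders validate session-log rows and report the offending
  line number.

## Problem sizes in the shipped checks

The test suite exercises: calibration recovery pooled over five replicate
studies of 200 sessions per group (the pooled mean must sit within ±1.5 of
each group's speed and index targets; pooling averages out the Monte-Carlo
noise of a single draw, whose group-mean sd reaches ~0.9 for mild AD);
LOOCV AUC across ten seeded 230-participant cohorts (expected inside
[0.75, 0.92]); a cross-cohort learning curve at sizes 5 and 73 with 20
repetitions; and 200 replications of the 936-session fixture for the ANOVA
size check.

## Known limitations

* The simulator's realism is limited to the calibrated first and second
  moments of the published group summaries; higher moments, item content and
  cross-feature dependence are stylised.
* The classifier bracket [0.75, 0.92] characterises the synthetic cohort
  design, not real-data performance; published clinical results are computed
  from patient data this package does not ship.
* The practice gate's attempt counts are generated but not used as a model
  feature (the classifier uses the four published features).
* No GUI or stimulus rendering: the item bank is metadata (id, category,
  latent difficulty), and mask frames are the only exportable imagery.
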