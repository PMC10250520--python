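# Methods

This document describes the algorithms, statistical models, default
parameters, and numerical choices implemented in `gnet`, together with their
assumptions and known limitations.

## 1. Stimulus representation

A stimulus is a 3×3 (configurable n×n) grid in which exactly five (configurable
`n_elements`) cells contain a colored shape. It is encoded as three length-9
row-major integer vectors:

- `layout` — 1 where a cell is occupied, 0 elsewhere; exactly `n_elements`
  ones.
- `shapes` — 0 for empty cells; 1 = circle, 2 = square, 3 = triangle on
  occupied cells.
- `colors` — 0 for empty cells; 1 = red, 2 = green, 3 = blue, 4 = yellow,
  5 = orange, 6 = purple on occupied cells.

`Stimulus.validate()` enforces that the three vectors agree on occupancy:
shape and color codes are nonzero exactly where `layout` is 1.

## 2. Pool generation

`generate_pool(seed, config)` builds a pool of 5 familiars and 100 novels
(20 per novel category, i.e. `variants_per_base = 4` variants of each of 5
bases per category) in three steps.

**Step 1 — originals.** Ten stimuli are drawn fully at random: layout is a
uniform random choice of 5 occupied cells out of 9; each occupied cell gets an
independent uniform shape and color. Layouts are constrained to be pairwise
distinct across the ten. The first five become the *familiars*; the remaining
five are *unused originals* (they seed the fully-novel category and are never
shown as themselves). Familiars are additionally redrawn until they contain at
least two distinct colors — see §2.1.

**Step 2 — layout-preserving full re-randomizations.** For each familiar,
four `NOVEL_COLORS_AND_SHAPES` variants are drawn by keeping the base layout
and redrawing every occupied cell's shape and color uniformly at random (with
replacement). For each unused original, four `FULLY_NOVEL` variants are drawn
the same way. A candidate identical to *any* Step-1 stimulus is rejected and
redrawn (whole-stimulus collision check, at most 1000 retries). Each
fully-novel quartet is then assigned to a familiar by a random permutation of
the five familiars, which defines its reference point for the
distance-to-familiar index.

**Step 3 — partial re-randomizations.** For each familiar, four variants per
remaining category are drawn, always keeping the layout:

- `NOVEL_SHAPES` — redraw every occupied cell's shape uniformly; colors kept.
- `NOVEL_COLORS` — redraw every occupied cell's color uniformly; shapes kept.
- `NOVEL_COLOR_COMBINATIONS` — keep shapes; redraw each occupied cell's color
  uniformly from the *set of distinct colors present in the base*, so the
  palette is preserved but its arrangement over cells changes.

Step-3 candidates are rejected only if identical to their own base (not
checked against the rest of the pool), again with at most 1000 retries.

All per-cell draws are independent and uniform *with replacement*; a variant
may therefore coincide with its base on any individual cell, and only
whole-stimulus identity triggers resampling. This makes per-cell mismatch
probabilities exactly 2/3 (shapes, 3 alternatives) and 5/6 (colors, 6
alternatives), giving closed-form expectations used as test oracles:
E[DTF] = 5·(2/3) = 10/3 for novel shapes and 5·(5/6) = 25/6 for novel colors
(slightly inflated in practice by the identity-rejection step; the test
tolerance accounts for this).

### 2.1 Degenerate-familiar constraint

If a familiar's five elements all share one color (probability 1/6⁴ = 1/1296
per familiar), every `NOVEL_COLOR_COMBINATIONS` draw from the one-color
palette is identical to the base and the collision-rejection loop can never
terminate. Step 1 therefore redraws familiars with fewer than two distinct
colors. The effect on category means is below 0.01 difference points, but it
makes generation total: every seed yields a valid pool. Unused originals are
not constrained (fully-novel variants redraw colors from the full palette).

### 2.2 Rendering

`render_stimulus` draws a stimulus to a PNG with Pillow: white background,
square cells of `pixel_size ≥ 30` px, a margin of one tenth of the cell size
inside each occupied cell, flat fills with no antialiasing so rendered colors
are exactly the palette RGB values (verified by a pixel-fidelity test).
Rendering is presentational only; all analysis operates on the vectors.

## 3. Difference metrics and indices

`matrix_difference(a, b)` counts positions at which two equal-length vectors
hold different codes — a plain positional categorical mismatch count (0 and
nonzero codes compared alike). `stimulus_difference` sums this over the
layout, shape, and color vectors; for two 5-of-9 stimuli the maximum is 26
(layout can mismatch in at most 8 positions, shapes and colors in at most 9,
and full disjointness caps the total at 26).

`compute_indices(pool)` returns, per novel stimulus:

- **DTF** — difference to its base familiar (for fully-novel stimuli, to the
  familiar assigned by the random pairing).
- **DTAF** — mean difference to all five familiars.
- **DTAN** — mean difference to the 99 other novels
  (`dtan_same_category_only=True` restricts to the 19 same-category novels).

`index_correlations` reports pairwise Pearson correlations among the three
indices over the 100 novels. Because pools are random, these statistics vary
substantially from pool to pool; the expected difference between two
independent random 5-of-9 stimuli is 17.5, which anchors the typical DTAF of
familiar-derived categories near 0.2·DTF + 0.8·17.5/… (four cross-familiar
terms out of five).

## 4. Trial schedule

`build_schedule(pool, seed)` produces three phases:

1. **Familiarization** — 25 trials: each familiar 5 times, shuffled, 3.0 s.
2. **Incidental study** — 75 trials: each familiar 5 more times plus 50
   novels (10 per category, the "shown" half of a per-category 10/10
   old/distractor split), shuffled, 3.0 s; the task is an old/new judgment
   on which the study-performance exclusion is based.
3. **Recognition** — 100 trials: the 50 shown novels (role `OLD`) and the 50
   held-out novels (role `DISTRACTOR`), shuffled, 1.5 s; seen / not-seen /
   maybe-seen judgment.

Durations are metadata only (no timing simulation). `TrialSchedule.validate`
re-checks all counts, role confinement, and the per-category split.

## 5. Response simulator

`simulate_cohort` generates synthetic response logs from logistic response
models; it exists to exercise the analysis pipeline and for parameter-recovery
testing, not to model human memory mechanistically.

For participant *j* with z-scored difference index *x* (z-scoring uses the
population SD over the 100 novels, so simulator coefficients are per-SD
effects):

- Phase-2 novel trials: P(respond NEW) = logistic(a_j + b_j·x).
- Phase-2 familiar trials: correct (OLD) with probability
  `familiar_accuracy`.
- Phase-3 trials: P(SEEN) = logistic(c_j + d_j·x + e·old + f·old·x), where
  `old` is 1 for studied items; independently, a trial becomes `MAYBE` with
  probability `maybe_rate` or `NONE` (no response) with probability
  `miss_rate`.

Per-participant intercepts and slopes (a_j, b_j) and (c_j, d_j) are drawn
from bivariate normals around the cohort means; by default the random effects
are independent (`re_correlation = 0`). The old-type effect *e* and
interaction *f* are fixed at the cohort level, matching the fitted model's
random-effect structure (random intercept + random old-type offset per
participant, uncorrelated).

Defaults (`ParticipantParams` / `CohortParams`): study intercept 1.0 (SD
0.5), study DTF slope 0.5 (SD 0.25), recognition intercept −0.2 (SD 0.5),
recognition difference slope −0.8 (SD 0.25), old-type effect 0.4, interaction
0.35, familiar accuracy 0.9, maybe rate 0.1, miss rate 0.02, 95 participants.
Rationale: the negative difference slope with positive interaction makes
hit rates rise and false-alarm rates fall with novelty, producing a graded
corrected-recognition profile across categories of realistic magnitude at
n = 95; SDs are half/quarter of the means so that cohort heterogeneity is
visible but fits converge reliably. These are demonstration values, not
estimates of any empirical population.

Seeding: `SeedSequence(seed).spawn(n)` gives each participant an independent
stream; by default each participant also gets a fresh schedule (shuffle
order), with `shared_schedule` available for yoked designs.

## 6. Exclusion rules

`apply_exclusions` flags participants who:

- **MISSED** — gave no response (`NONE`) on more than 1/3 of phase-2 + 3
  trials;
- **STUDY_CHANCE** — whose phase-2 accuracy 95% CI lower bound (on answered
  trials) is below the 1/3 chance level; CI methods: Clopper–Pearson exact
  (default, via `scipy.stats.binomtest.proportion_ci`), Wilson, or normal
  approximation;
- **MAYBE_OVERUSE** — answered `MAYBE` on more than 25% of phase-3 trials
  (strict) or at least 50 trials (lax).

The report lists per-participant rates, the CI bound, and all reasons.

## 7. Analysis

**Corrected recognition** per participant × category: hits (SEEN on old
items) minus false alarms (SEEN on distractors), out of 10 each, so the score
ranges −10..10.

**Category tests** (`category_tests`):

- One-way repeated-measures ANOVA over the five categories with
  Greenhouse–Geisser correction and generalized eta squared (via `pingouin`);
  GG is applied unconditionally because sphericity is rarely tenable for
  ordered category structures and the correction is conservative when
  sphericity holds.
- A linear trend contrast with weights (−2, −1, 0, +1, +2) over categories
  ordered novel-color-combinations → shapes → colors → colors-and-shapes →
  fully-novel, computed as per-participant contrast scores tested with a
  one-sample t (reported as F = t² with df 1, n−1); positive means
  performance increases with novelty.
- Per-category one-sample Wilcoxon signed-rank tests against zero
  (one-sided, greater), Shapiro–Wilk normality checks, and a paired Wilcoxon
  comparing SEEN counts on old vs. distractor items.

**Mixed-effects models.** The study model predicts phase-2 NEW responses from
an intercept and one difference index, with correlated-free random intercept
and slope per participant. The recognition model predicts SEEN from
intercept, old-type indicator, index, and their interaction, with random
intercept and random old-type offset per participant (uncorrelated) — the
random-effect structure mirrors the simulator in §5. `compare_models` ranks
the DTF/DTAF/DTAN variants by AIC (ΔAIC ≥ 10 labeled "no support") and
refuses to compare fits made on different observation sets.

## 8. GLMM estimation (numerical choices)

No installed Python library fits maximum-likelihood binomial mixed models
with a log-likelihood/AIC, so `gnet.glmm` implements a Laplace-approximation
logistic GLMM:

- Random-effect modes per group are found by damped (step-halving) Newton
  iterations, vectorized across groups via padding to a common group size.
- The marginal log-likelihood is the Laplace approximation with a batched
  `slogdet` of the per-group curvature; mode estimates are warm-started
  between outer iterations.
- The outer optimization over fixed effects and log standard deviations uses
  `scipy.optimize.minimize(L-BFGS-B)` with `eps = 1e-6`, `ftol = 1e-11`, and
  log-SD bounds [−4, 3]; fixed effects are started at the plain logistic
  regression solution.
- Standard errors come from a central-difference numerical Hessian of the
  profile objective; AIC = −2·logL + 2·(p + q) counts fixed effects plus
  variance components; marginal/conditional R² follow Nakagawa (fixed-effect
  variance over fixed + random + π²/3).
- Complete separation is detected and raised as `SeparationError`.

Validation: fits agree with R `lme4::glmer` (`(1 + old || participant_id)`,
Laplace) to 4–5 decimals in coefficients and ~0.001 in AIC (cross-checked in
the test suite by calling `Rscript` directly), and with an 80-point
Gauss–Hermite quadrature oracle in the random-intercept case. A single
n = 95-participant fit takes ~0.5 s.

Laplace is a first-order approximation; for binary data with small groups it
can bias variance components slightly downward relative to adaptive
quadrature. At the group sizes here (100–175 observations per participant)
the discrepancy is far below the reported precision.

## 9. Known limitations

- Pool statistics (DTAF, DTAN, index correlations) vary widely between
  random pools; any single pool's values can sit several Monte-Carlo SDs
  from the generator's long-run means. Conclusions about the generator
  should always be drawn from many pools (the acceptance script uses 250).
- The simulator is a descriptive logistic device: no encoding dynamics,
  forgetting, response times, or sequential effects; `maybe`/`none`
  responses are independent coin flips rather than confidence-driven.
- Step-3 variants are collision-checked only against their own base, so
  (rarely) two variants within or across categories can coincide — this
  mirrors the generation design rather than being an oversight.
- The linear contrast treats the five categories as equally spaced, which is
  a modeling convention, not a measured property of the stimulus space.
- The GLMM assumes Gaussian random effects and the specific structures in
  §7; alternative structures (e.g. random index slopes in the recognition
  model) are not exposed.

## 10. Problem sizes exercised

The test suite fits the GLMM on simulated cohorts of 30 and 95 participants
(5 250–16 625 observations), runs 200-pool Monte-Carlo checks of the
generator, 50-cohort parameter-recovery/model-comparison checks, and
800-replicate null calibration of the category tests. The full suite runs in
about 2½ minutes; `scripts/acceptance.py` (250 pools) in under 10 seconds.
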