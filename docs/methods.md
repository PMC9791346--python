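# Methods

`morphstair` simulates and analyses a two-alternative forced-choice (2-AFC)
vocal-emotion-recognition study in which listeners — cochlear-implant (CI)
users and normal-hearing (NH) controls — discriminate anger from surprise in
morphed voices, with or without congruent or incongruent facial emotion.
Task difficulty is controlled by the *morph level* (ML): the position of a
voice on a synthesized continuum from an emotion anti-caricature (60%)
through the original recording (100%) to an emotion caricature (140%), in
20% steps. Higher morph levels carry more diagnostic emotional information
and are easier to judge. Audio/video synthesis itself is out of scope; the
morph level is treated as a scalar difficulty axis.

## Observer model

Each simulated participant responds correctly with probability

    p(ml) = γ + (1 − γ − λ) · F((ml − α) / β),

where F is the standard logistic, γ = 0.5 is the 2-AFC guessing floor,
λ ∈ [0, 0.1] a lapse rate, and β the slope scale in ML units. The function
is parameterised by its 75%-correct point θ₇₅: α is solved in closed form so
that p(θ₇₅) = 0.75 exactly. θ₇₅ may lie off the grid or outside [60, 140],
which is how floor and ceiling participants arise. Defaults: β = 10 ML
units, λ = 0.02. These two are generic psychophysical choices, not
condition summaries, and are exposed in the configuration.

Per observer, the four presentation conditions share one slope and lapse and
differ only in threshold: both auditory-only streams use the auditory
threshold θ_aud, the congruent audiovisual condition uses θ_aud − Δ_benefit,
the incongruent one θ_aud + Δ_cost (lower threshold = better performance).

### Cohort generator defaults

Group-level thresholds are drawn from normal laws whose means reproduce the
study's condition means on the ML scale (CI: auditory 118.9, congruent
97.08, incongruent 129.76; NH: 80.30, 72.04, 96.28), so Δ_benefit means are
21.82 (CI) and 8.26 (NH) and Δ_cost means 10.86 (CI) and 15.98 (NH).
Auditory SDs are the printed SEMs scaled by √25 (22.5 CI, 13.6 NH). The
SDs of Δ_benefit and Δ_cost are **not identifiable** from group summaries
(the independence-based subtraction of variances is even negative for the
NH congruent condition), so plausible values were fixed once: benefit SD 10
(CI) and 5 (NH), cost SD 8 (both). Δ draws are truncated at zero, so
benefit and cost are non-negative per observer while their group means stay
close to the targets.

Reaction times are lognormal, parameterised by a median (default 1200 ms)
and the tail mass beyond the 6000-ms exclusion cutoff (default 0.9%,
mirroring the magnitude of the study's exclusion proportions). The
quality-of-life score (WHOQOL-BREF environmental-health domain, 4–20 scale)
is generated jointly with θ_aud through a Gaussian copula whose latent
correlation 2·sin(πρ_s/6) yields the target Spearman correlation exactly in
population (default ρ_s = −0.38: better auditory performance, i.e. lower
thresholds, goes with higher QoL).

### What the generator does not emulate

Speaker- and pseudoword-specific difficulty, listener-sex effects, learning
or fatigue across blocks, RT–accuracy dependence, and any coupling between
Δ_benefit and θ_aud (an optional topic in the multisensory
inverse-effectiveness debate; no published value exists, so the default is
independence). Passing tests therefore show that the *pipeline* recovers
what this generative model puts in, not that the model captures every
feature of real CI listeners.

## Adaptive staircase

Each condition runs an independent transformed up-down staircase over the
ML grid: trials come in rounds of four at a fixed ML; with ≤ 2 correct the
next round moves one 20%-step up (more diagnostic information), with exactly
3 correct it stays, with 4 correct it moves one step down, clamped at 60 and
140. Each condition contributes 96 trials = 24 rounds, interleaved in 8
blocks of 48 trials with 12 slots per condition per block, so rounds never
straddle blocks. The starting level is 100 (the unmanipulated voice; the
neutral centre of the continuum) and the first 4 rounds per condition are
burn-in, excluded from every summary. Within a round the sampler presents
2 anger + 2 surprise items in random order, four distinct speakers, and each
pseudoword twice, keeping the 2-AFC unbiased within rounds.

**Equilibrium accuracy.** The rule balances where P(4 correct) = P(≤ 2
correct), i.e. 4p³ − 2p⁴ = 1, giving p* ≈ 0.734 — slightly below the nominal
0.75. On the coarse 20% grid the stationary distribution additionally
spreads over levels whose accuracies are asymmetric around the threshold, so
the realised post-burn-in accuracy for mid-grid observers is ≈ 72–73%, and
recovered mean MLs sit ≈ 1–2 ML units below the generating θ₇₅ at slope 10.
Both deviations are documented behaviour of the 2/3/4 rule, well inside one
grid step; the acceptance checks compute them from scratch.

## Quantification rules

- Trials with RT > 6000 ms from voice offset are excluded (strict
  inequality); the excluded proportion is reported.
- The two auditory-only streams are pooled into one condition: mean of the
  two accuracies (Experiment 1) or mean of the two round-ML summaries
  (Experiment 2). Because both streams have equal round counts, summary- and
  round-level pooling coincide.
- Benefit = congruent − pooled auditory, cost = incongruent − pooled
  auditory, on the experiment's native scale (accuracy in Experiment 1,
  where positive benefit is facilitation; ML in Experiment 2, where
  *negative* benefit is facilitation).
- The caricature slope is the accuracy difference between the highest and
  lowest morph level a participant performed on, divided by the number of
  20% steps between them. A level qualifies only with at least
  `min_trials_per_ml` trials (default 4 = one full round, guarding against
  single-trial accuracy estimates); with fewer than two qualifying levels
  the score is missing — a value, not an error — which reproduces the
  availability pattern of participants pinned at the 140% ceiling. Slopes
  use post-burn-in trials, consistent with all other Experiment-2 summaries.
  Per-ML accuracy pools the auditory streams by unweighted mean of the two
  stream accuracies at each level (a level visited by one stream keeps that
  stream's value).

## Group matching

To compare audiovisual effects at equal auditory baselines, pairs of the
lowest-performing CI user (largest auditory ML) and the highest-performing
NH control (smallest auditory ML) are removed iteratively. "Until the mean
difference is minimal" is operationalised as the global minimum of the
absolute mean difference over all admissible removal counts, ties broken
toward retaining more participants; a greedy variant stopping at the first
local minimum is available as a strategy option. Ties within a group on the
ML value remove the larger participant id, deterministically. Groups must
have equal size and at least `min_group_size` = 2 members remain.

## Statistics

t family and Spearman correlation (midranks for ties) delegate to
scipy.stats; Welch tests use Welch–Satterthwaite fractional df, and
one-tailed tests implement the preregistered directional contrasts (larger
audiovisual benefit in CI users; lower congruent MLs for matched CI users).
No multiple-testing correction is applied. Zero-variance inputs yield an
explicitly flagged undefined statistic rather than an exception.

The split-plot ANOVA (one or two within-subject factors, optional
between-subject group) is computed from orthonormal within-subject
contrasts: for each within effect the subjects' contrast scores give
hypothesis and error SSCP matrices whose traces reproduce the classical
univariate sums of squares, F ratios, and partial η². Sphericity
corrections come from the pooled within-group covariance of the contrast
scores: Greenhouse–Geisser ε = tr(Σ)²/(d·tr(Σ²)) and Huynh–Feldt
ε = (N·d·ε_GG − 2)/(d·(N − g − d·ε_GG)) capped at 1 (N subjects, g groups,
d effect df); a 2-level factor has ε ≡ 1. The implementation is
cross-checked in the tests against pingouin (mixed design F/p/η²p; epsilons
in pure within designs) and statsmodels AnovaRM (two within factors). Note
pingouin computes mixed-design epsilons from the unpooled covariance; the
pooled form used here is the SPSS/R convention. Limitations: the design
must be complete (one observation per subject per cell) and between-subject
groups equally sized — the simulated studies are balanced by construction.

## Type-I-error calibration

`calibrate_type1` simulates null cohorts in which both groups share one
generating law, builds each participant's Experiment-1 accuracy benefit
from binomially aggregated condition counts (64 congruent trials, 128
pooled auditory trials — statistically equivalent to trial-level Bernoulli
draws), and applies the two-tailed Welch group test. The vectorised Welch
statistic is pinned to `stats.t_test` in the unit tests. With 10,000
replicates the Monte-Carlo SE of the rejection rate at α = 0.05 is ≈ 0.22
percentage points.

## Problem sizes and numerical choices

The test suite runs scaled-down Monte-Carlo checks (60 observers for
staircase targeting, 1,500 calibration replicates) alongside full-size
acceptance checks (500 observers for targeting and recovery, 10,000
calibration replicates, 1,000 random matching instances against the
brute-force oracle). All randomness flows through numpy `SeedSequence`
spawning, so every table is bit-reproducible from the run configuration;
configs round-trip through YAML.
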