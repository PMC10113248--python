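# Methods

## Cohort representation and outcome

A cohort is a long-format table: one row per patient per evaluation
(T0 admission, T1 ≈ four months post-event, T2 discharge), each row carrying
the days since injury, the clinical variables observed at that visit, and
the discharge Glasgow Outcome Scale. The GOS (1 death … 5 good recovery) is
binarized at ≥ 4 into a positive/negative outcome; this cut-point is the
prediction target throughout. Evaluation times must be days since *injury*;
a loader for data recorded as days since admission must supply the
injury-to-admission offset explicitly — no silent assumption is made.
Patients who die before discharge keep GOS = 1 (negative); their missing
later visits simply contribute no rows. Missing values are permitted only
as explicit markers (NaN/empty), and an evaluation whose clinical variables
are all missing is treated as unobserved.

The train/validation split is stratified on the binary outcome with exactly
⌊fraction × stratum size⌋ patients per stratum assigned to validation. The
floor (rather than rounding) is deliberate: with strata of 116 and 27
patients at a 0.30 fraction it yields 34 + 8 = 42 validation patients,
whereas rounding would give 43.

## Univariable screening

Continuous variables: two-sided Welch (unequal-variance) two-sample
*t*-test. The equal-variance form gives the same significance pattern on
data of this shape; Welch is safer with group sizes as unbalanced as 116
vs 27. Categorical variables: chi-squared test of independence, replaced by
the Fisher exact test whenever any expected cell count is below 5 (the
standard convention). For 2×k tables with k > 2 the exact test is the
exhaustive conditional test: all tables with the observed margins are
enumerated and those with point probability not exceeding the observed
one are summed (this reproduces scipy's two-sided 2×2 convention); an
enumeration guard rejects tables too large for exact treatment, which does
not occur at clinical sample sizes. A variable is retained for the FAMD
iff its minimum p-value across evaluations is ≤ α (default 0.05, with ≤ so
that a boundary p exactly at α keeps the variable). No multiple-testing
correction is applied — the screen is a filter, not an inferential claim.

## Factorial analysis of mixed data

The Pagès formulation: continuous columns are centered and scaled to unit
*population* variance; each categorical level becomes a 0/1 indicator
divided by √(level proportion) and then centered. The encoded matrix is
decomposed by SVD with uniform row weights 1/n; eigenvalues are squared
singular values over n, scores are rows projected on the right singular
vectors. On a continuous-only table this is exactly correlation-matrix PCA.
Levels never observed in training are dropped from the encoding; rows with
any missing value among the active variables are excluded from fitting
(complete case), and projection requires complete rows — matching how
missing T1 visits are handled everywhere else in the pipeline. All centers,
scales and level proportions are retained so held-out rows are projected
with training statistics only.

Two deterministic sign conventions apply to component 1: first, each
loading column is flipped so its largest-|loading| entry is positive
(platform-independent SVD signs); second, the pipeline orients the modeled
dimension so that the positive-outcome training group has the higher mean
score. The latter matters because the threshold classifier assumes the
positive band lies above the negative one; without it the orientation
would be arbitrary. Rows from all available evaluations are pooled into
one FAMD (one row per visit), so a patient contributes up to three rows
and the dimension is comparable across time.

Variance fractions are eigenvalue shares; the contribution of an encoded
column to a component is its squared loading (×100), aggregated over a
categorical variable's levels.

## Michaelis–Menten trajectory model

Per outcome group, Dimension-1 scores y at times t are fitted with
f(t) = a + m·t/(K + t) by least squares on the parameterization
(a, m, log K), which enforces K > 0. Starts: a deterministic 3×3×3 grid
spanning the observed score range (a), ± the score span (m) and the
observed time range (K); the best optimum is kept, and an explicit
initial guess bypasses the grid. Convergence is accepted on scipy's
termination criteria or on a near-zero gradient (a run that exhausts its
evaluation budget *at* the shared optimum is not a failure). A flat
response (m ≈ 0) leaves K unidentifiable and is flagged degenerate rather
than rejected.

The parameter covariance is σ̂²(JᵀJ)⁻¹ with σ̂² = RSS/(n−3) and J the
Jacobian in the natural (a, m, K) parameterization at the optimum; standard
errors are its diagonal square roots. Group parameters are compared with a
two-sample Wald z-test, z = (θ̂₁−θ̂₂)/√(SE₁²+SE₂²), against the standard
normal. On the reference group fits this gives p = 0.52 for a and p = 0.63
for K (no group difference in baseline or half-time) and p ≈ 2×10⁻⁵ for m
— the groups differ in how much they can improve, not where they start.

### Monte-Carlo confidence bands

Pointwise 95% limits for the fitted curve come from 10,000 draws of
(a, m, K) from N(estimate, covariance), evaluating f on a daily grid from
0 to 600 days (the observed discharge range) and taking the 2.5th/97.5th
empirical percentiles. Draws with K ≤ 0 are redrawn (f is meaningless
there) and counted; a covariance that is not positive semidefinite is
repaired by clipping negative eigenvalues to zero, with a warning. The
percentile band is an approximation whose coverage approaches the nominal
95% as the information in the data grows; at low signal-to-noise it can
undercover by a few points (a known property of Wald-type propagation for
nonlinear curves), which the test suite quantifies at a regime where
coverage is nominal within ±2%.

## Threshold classifier

The crossover day t\* is the first grid time at which the negative group's
upper limit falls to or below the positive group's lower limit, refined by
bisection on the linearly interpolated gap to 0.1-day precision; if the
bands never separate the rule carries an explicit no-separation flag.
Before t\*: score > Threshold 1 (negative upper limit) → positive;
score < Threshold 2 (positive lower limit) → negative; otherwise shadow
(no call). From t\* on: score ≥ Threshold 3 (positive lower limit) →
positive, else negative. Ties sit in shadow before t\* and count as
positive on Threshold 3 — ties are measure-zero in practice; the convention
is fixed for determinism. Multi-visit patients are combined by the
earliest non-shadow visit (default), so an early confident call is never
overridden; a latest-visit rule is available as a config option.

Sensitivity and specificity target the *negative* outcome class: with the
cohort's ≈81/19 class mix the reconstructed validation counts are only
arithmetically consistent when negatives are the detection target. A flag
on the confusion computation flips the convention.

A structural property worth knowing: Threshold 3 is a confidence band for
the *mean* curve, not a prediction band for individual scores. As data
accumulate the band tightens while individual dispersion does not, so a
fixed share of positive-outcome patients will fall below the positive
band's lower limit regardless of noise level — specificity is structurally
capped well below 100% while sensitivity for negatives stays near perfect.
This matches the reference behavior and bounds attainable accuracy near
0.81 + 0.19·spec for the default class mix.

## Synthetic cohorts

The generator emulates the study conditions: group membership
Bernoulli(0.81 negative); latent scores on the group's Michaelis–Menten
curve — defaults (a, m, K) = (−4.73, 11.56, 44.87) positive and
(−3.01, 4.61, 91.99) negative — plus N(0, noise_sd²); T0 uniform on
[10, 93] days, T1 ~ N(167, 30²), T2 = T1 + N(40, 10²), redrawn until
ordered; each T1 deleted with probability 0.07. The observation-time model
(uniform/Gaussian with redraw) is invented to match the published summary
statistics while staying simple. The default noise_sd = 2.0 is chosen so
the spread of simulated scores, and hence the standard errors of fits to
them at the study's sample size, are on the scale the reference fits imply;
no printed residual variance exists to anchor it exactly, so it is a
config knob, not a claim.

Observed variables derive from the latent score through declared links:
continuous = affine(latent) + noise, clipped to instrument ranges
(CRS-r 0–23, RLAS 1–8, ERBI-A −325–0, ERBI-B 0–100); categorical = ordered
levels cut at strictly increasing latent thresholds (soft boundaries via
optional link noise); sex is drawn independently of the latent. GOS is 4–5
in the positive group, 1–3 in the negative, so the binarized outcome equals
the generating group. What the generator does *not* emulate: the real
cohort's joint covariate dependence beyond the single latent factor,
etiology structure, informative missingness, or center effects —
so green tests demonstrate correctness of the machinery under the assumed
model, not clinical performance on real data.

## Problem sizes and reproducibility

Default analysis runs use 143-patient cohorts (101 training / 42
validation after the stratified 70/30 split), 10,000 Monte-Carlo draws and
a 1-day grid over 0–600 days. The simulation-based checks use 200
replicates of 300 points for parameter recovery and 1,000 replicates of
600 points for band coverage — sizes at which the stochastic properties
under test are measured with small Monte-Carlo error while keeping the
whole suite fast. Every random stage (simulation, split, bands) draws its
seed deterministically from one master seed, so any run is bit-for-bit
reproducible.

## Known limitations

- The crossover day is highly sensitive to band width: reconstructions
  from synthetic data at the default noise level concentrate tens of days
  below the reference cohort's 86, with a Monte-Carlo spread of ~18 days.
- Complete-case FAMD: no iterative imputation of partially observed
  visits.
- No per-patient random effects; the Michaelis–Menten fit pools all visits
  of a group, treating within-patient correlation as noise.
- Dimension 2 is computed but never modeled; no rotation is applied.
- The classifier is deterministic set-membership — no posterior
  probabilities and no ROC sweep.
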