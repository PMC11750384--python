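# Methods

## The task and the questions

The face detection task (FDT) is a speeded go/no-go paradigm: press a
key for upright faces, withhold for inverted faces and chairs. Half the
face identities are anti-caricatures (typical: morphed toward a face
average) and half caricatures (distinctive: morphed away from it). Two
individual-difference quantities are derived per participant:

- **expansion** — the distinctive-minus-typical RT difference, read as
  how far apart similar faces sit in that person's face-space;
- **adaptability** — the typicality difference in exponential learning
  rates over repeated exposures to the same identities, read as how
  fast the representation recalibrates.

Both are related to a composite face-identity-processing ability score
(mean within-test rank over a four-test battery) via the typicality ×
score interaction in linear mixed models.

## Generative model of the synthetic data

Per participant *i*, identity *j* with typicality class c(j), and
occurrence *n* (1..40):

    RT_ij(1) = RT0_i                          (first presentation = anchor)
    RT_ij(n) = RT_inf + (RT0_i − RT_inf) · exp(−α_ic · n)   for n ≥ 2

with additive terms applied at every occurrence: a constant typicality
offset δ for distinctive identities (optionally modulated linearly by
the participant's centred composite rank — the "ability coupling" whose
null is coupling = 0), a symmetric gender offset (±offset/2), and
i.i.d. Gaussian trial noise. RT0_i = baseline + participant intercept
(Gaussian). Go responses occur with the hit probability, false alarms
on no-go stimuli with the false-alarm probability; simulated RTs above
the 1000 ms response deadline become misses.

Two deliberate choices:

- **Anchoring.** The exponential curve's n=0 value is not observable;
  operationally RT0 is the first presentation's RT. The generator
  therefore pins occurrence 1 to RT0 and places occurrences n ≥ 2 on
  the curve with the raw occurrence exponent. Under this anchoring the
  rate inversion (below) is *exact* on noise-free data — the
  discrepancy to a fully smooth curve at occurrence 1 is < 0.5 ms at
  the default rates.
- **False-alarm RTs** follow the same general practice speed-up as hits
  (the participant's mean rate applied at the occurrence-equivalent
  task position). Without this, hits speed up while false alarms stay
  flat, and the generator would build in a spurious trial ×
  accuracy interaction; the emulated world has no speed–accuracy
  trade-off, and the simulated check's p-values are null-distributed
  with this choice.

### Default parameters (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| participants | 52 | analysed sample size |
| trials | 576 = 480 go + 48 inverted + 48 chairs, 11 blocks | task design (576 trials split into 11 near-equal blocks; blocks have no analytic role) |
| baseline RT | 355 ms | puts the task mean near ~350 ms given the asymptote and default rates |
| asymptote RT_inf | 200 ms | fixed constant of the learning model |
| participant intercept SD | 30 ms | between-participant mean-RT spread ~32 ms |
| trial noise SD | 60 ms | within-participant RT SD ~64 ms |
| typicality offset δ | 3 ms | observed detection advantage |
| learning rates α (typical = distinctive) | 0.0025 /occurrence | drops RTs ~15 ms over 40 occurrences; equal class means make the no-rate-difference null the default generator |
| α between-participant SD | 0.001 | modest rate heterogeneity |
| hit / false-alarm probability | 0.99 / 0.86 | near-ceiling hits, liberal responding |
| gender RT offset | 15 ms (male − female), centred | a detectable gender difference in RTs |
| ability coupling | 0 | the null of no typicality × ability relation |
| battery moments | CFMT+ 66.31 (11.15), YBT 9.59 (3.24), GFMT2-S 32.57 (3.86), J-BFFT 0.85 (0.14) | descriptives typical of young-adult samples on these tests |
| battery correlations | 0.19–0.43 | inter-test correlation range typical of such batteries |

Battery scores are multivariate normal, clipped to each test's legal
range and kept continuous (the rank composite is insensitive to
granularity; clipping slightly attenuates correlations for the
near-ceiling J-BFFT). Gender is Bernoulli(1/2) with two levels.

### What the generator does **not** emulate

Skewed RT distributions (ex-Gaussian tails), block-level feedback
effects, post-error slowing, identity-specific rate spread beyond the
typicality classes, fatigue/drift, and any image-level stimulus
properties. Passing tests therefore demonstrate correctness of the
analysis chain on a well-specified Gaussian world, not robustness to
real RT pathologies.

## Preprocessing

Floor rule first (drop hit RTs < 200 ms, strict), then one pass of the
±2 SD rule with mean and *sample* SD computed per participant on the
floor-surviving hit RTs (strict inequality). The rules apply to hits
(go responses to upright faces) — the only RTs analysed. Participants
with fewer than two floor-surviving RTs skip the SD rule with a
warning. The filter is audited per rule and participant.

**A property worth knowing:** a symmetric ±2 SD window around the
pooled participant mean truncates the shifted (distinctive)
distribution asymmetrically and shrinks mean condition differences.
With an 80 ms noise SD, a 10 ms generative offset is attenuated to
~7 ms after filtering (~30%); at the default scale (3 ms offset,
~60 ms noise) the attenuation is proportionally similar (recovered
~2.8 ms). Recovery checks of the contrast estimator therefore run on
the unfiltered response set, where it is unbiased.

Signal detection: hits vs pooled false alarms (inverted + chairs),
1/(2N) correction for rates of exactly 0 or 1, d′ = z(h) − z(f),
criterion = −(z(h)+z(f))/2. Because participants sit near ceiling on
480 go trials, the participant-mean d′ and the d′ of the sample-mean
rates can differ substantially; both conventions are computed and
reported side by side.

## Learning rates

α = −log((RT_inf − RT_n)/(RT_inf − RT_0))/n per retained presentation
with n ≥ 2, RT_0 = the first *retained* presentation's RT, and n the
raw occurrence index (preserving the task's time axis under missing
trials). Undefined values (RT_n ≤ RT_inf, or an anchor at/below the
asymptote) are excluded and audited. Numerically the inversion is exact
to ~1e-13 relative error whenever the trajectory stays ≥ 0.01 ms above
the asymptote; closer in, the subtraction RT_n − RT_inf has no digits
left to invert, so such presentations are treated as at-asymptote.
Because the estimator is a log ratio, heavy trial noise biases
individual α values (Jensen); noise-free data are recovered exactly and
small-noise data on average.

## Composite ability score

Within each test, participants are ranked ascending by score (rank n =
best of n), midranks for ties, ranking performed among participants
non-missing on that test; the composite is the mean of available ranks,
so the complete-data grand mean is (n+1)/2. Per-test z-scores are
provided for exploratory single-test models. Larger rank = better
performance, so a positive typicality × score coefficient means better
performers show larger typicality effects.

## Mixed models and inference

Fixed effects: typicality (distinctive indicator), the composite score,
occurrence, typicality × score, typicality × occurrence, and a gender
covariate when available. Random effects: participant intercepts, plus
a random typicality slope where it converges; on non-convergence or a
singular covariance the model is refit intercept-only and the downgrade
recorded in the fit's notes — never silently. Estimation is REML via
statsmodels MixedLM; fixed effects are reported from the profile GLS
solution at the estimated variance parameters, which coincides with the
optimizer's estimates on healthy fits and remains well-defined at
variance boundaries.

**Satterthwaite df** are computed from the REML machinery directly:
df_j = 2·f_j²/(∇f_jᵀ A ∇f_j), with f_j(θ) the sampling variance of
coefficient j as a function of θ = (residual SD, Cholesky of the
random-effects covariance), ∇f_j by central differences, and A twice
the inverse numerical Hessian of the REML deviance. Per-group Gram
matrices make each deviance evaluation O(groups·(p+q)²). Agreement
with R's lmerTest is ~4–6 significant digits (tested). Where the
approximation degenerates the residual df is substituted and noted.

**BIC and Bayes factors.** BICs come from a maximum-likelihood refit of
the same structure (REML likelihoods are not comparable across
fixed-effect sets), counting fixed effects + free covariance elements +
the residual variance. The interaction Bayes factor is
BF₁₀ = exp((BIC_null − BIC_alt)/2) against the same model without the
typicality × score term (the null refit with the structure the full
model settled on). `log_bf10` is carried alongside since the ratio
itself over/underflows beyond |ΔBIC| ≈ 1400. Learning-rate models are
fit on the original and the log outcome scale (non-positive rates
dropped and counted) and compared by raw BIC, without a
change-of-variables correction and despite the differing n — the
operational convention in this literature; the lower BIC wins.

The paired typicality contrast uses participant condition means,
distinctive − typical, a paired t-test, and Cohen's d = mean/SD of the
paired differences with a 95% CI by inverting the noncentral-t CDF.
Zero-variance differences return a flagged degenerate result. Gender
comparisons use the two-sided Wilcoxon rank-sum (exact null up to
n = 50 without ties, else the tie-corrected normal approximation with
continuity correction; W is the first group's Mann–Whitney U, the
R convention). Battery correlations are pairwise-complete Pearson.

"Multiple-comparisons corrected t-tests (Satterthwaite's method)" is
implemented as a df approximation with no multiplicity correction — a
Holm adjustment flag exists and is off by default.

## Calibration

Under the null generator (coupling 0, equal rate means), the typicality
× score interaction test rejects at 0.054 over 500 scaled-down
replicates (20 participants, 12 identities × 10 occurrences) at
α = .05, inside the 95% binomial band [0.032, 0.071], with uniform
p-value deciles. The Monte-Carlo routine fits the random-intercept
model, which is the correctly specified structure there (the null
generator has no typicality-slope heterogeneity).

## Problem sizes

The test suite works at scaled-down sizes (6–20 participants, 10
occurrences; 500 Monte-Carlo replicates for calibration); the
acceptance script runs the full 52-participant, 576-trial design.

## Known limitations

- Satterthwaite df rely on numerical differentiation; for ill-scaled
  variance parameters the df can be unstable (guarded by a residual-df
  fallback, noted on the fit).
- The exclusion-rule attenuation of condition differences (above) means
  filtered-data contrasts underestimate generative offsets under heavy
  noise; the package mirrors the standard procedure rather than
  correcting it.
- BF values are BIC approximations (unit-information prior), not
  fitted Bayesian model comparisons; they agree with such tools only in
  order of magnitude.
- The log-scale learning-rate model conditions on α > 0, so its BIC
  comparison against the linear model inherits the selection the
  original analysis applied.
- Real-data ingestion expects the package's documented column schema;
  external deposits need a column-mapping step, validated strictly at
  read time.
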