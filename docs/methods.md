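# Methods

## Problem and scope

`ema_rt` analyses response times (RTs) logged while older adults answer
short daily ecological momentary assessment (EMA) items on a 7-point
Likert scale, asking whether the *dynamics* of those latencies — in
particular how quickly a person habituates to repeated self-report —
track change in depressive symptoms over a one-month window.  The
pipeline runs end-to-end on a synthetic cohort generator because raw
participant data of this kind are not publicly deposited; every stage is
written against the generator's known truth.

## RT cleaning

RT distributions are heavily right-skewed, so outliers are removed with
an asymmetric IQR rule computed per item, pooled across subjects: trials
outside `[Q1 − 0.5·IQR, Q3 + 1.5·IQR]` are excluded.  Quartiles use
linear interpolation between order statistics (the dominant convention;
none is mandated by the design).  Bounds are computed once on the raw
data and then applied; both bounds are inclusive ("outside" is read
strictly).  Filtering is idempotent.

## Standardization (Z-RT)

Within each (subject × item × response-option) cell,
`Z = (RT − mean) / SD` with the population SD (`ddof=0`).  The population
convention makes a two-point cell standardize to exactly ±1 and the
per-cell mean-0/SD-1 invariant exact, which the tests assert to 1e-9.
Cells with fewer than 2 trials or zero SD cannot be standardized; they
are dropped and counted in an audit log rather than raising, since
sparse option use is expected (a subject may pick an extreme option
once).

## Per-subject decay features

Adaptation is summarized by `f(t) = θa·exp(−θb·t) + θc` fitted
independently per subject (no partial pooling) to the raw-RT and Z-RT
series by bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, iteration cap 10 000).  Bounded problems cannot
use a pure Levenberg–Marquardt iteration, so the trust-region variant is
used wherever bounds are active.

* Initialization: θc ← mean of the last quarter of the series, θa ←
  mean of the first quarter minus θc, θb ← 0.1.  This is scale-aware and
  deterministic.
* Bounds: raw RT — θa ∈ [0, 2·max(y)], θb ∈ [0, 10], θc ∈ [0, max(y)];
  Z-RT — θa ∈ [−6, 6], θb ∈ [0, 10], θc ∈ [−3, 3].  Negative amplitude
  is meaningful only on the standardized scale.
* R² = 1 − SS_res/SS_tot, with R² ≡ 0 when SS_tot = 0 (constant series);
  a constant series also yields θa → 0, θc → the level.
* Time is the calendar day index; missed days leave gaps rather than
  re-indexing completed trials.
* Non-convergence returns the last iterate flagged `converged=False`;
  series shorter than 4 points are reported as missing features.

A consequence worth noting: the synthetic generator (like the
hierarchical model) places the decay on the **log-RT** scale, and the
exponential of a decay curve is not itself a decay-plus-asymptote curve.
Raw-scale NLS therefore recovers an *effective* decay rate that is
systematically faster than the generative one.  Parameter-recovery tests
consequently assess θb on the log-RT scale, where the noise is additive
around the true curve; raw-RT fits remain the feature definition used in
the correlation screen.

## Outcomes

Symptom change is the simple difference Δ = post − pre per scale
(GDS-15, CESD-R, PHQ-9, BAI); improvement is negative.  Responders are
subjects with ΔGDS-15 ≤ −3.81, a minimal-detectable-change threshold for
that scale (meta-analytically derived; used here as a constant), with
the boundary counting as response.

Pre/post comparisons use a Shapiro–Wilk gate at α = .05 on the
differences: normal → paired t with Cohen's d = mean(diff)/SD(diff)
(sample SD); non-normal → Wilcoxon signed-rank with the matched-pairs
rank-biserial correlation (W⁻ − W⁺)/(W⁻ + W⁺).  Zero differences are
dropped before ranking (Wilcoxon's original treatment), which keeps the
rank-biserial well defined; an all-zero difference vector returns a
degenerate flagged result.  Tests are one-tailed with the direction
fixed a priori as symptom reduction, and effect sizes are signed so
improvement is positive.

## Association screen

Spearman rank correlations (average ranks for ties) between every
per-subject feature column and each of the four change scores, with
pairwise-complete deletion and a 3-pair minimum per cell.  No
multiple-testing correction is applied; the emitted table marks .05 /
.01 / .001 per-cell thresholds with stars and is explicitly exploratory.
Constant features yield an undefined ρ and are flagged rather than
silently dropped.

## Hierarchical model

For each observation `n` (subject `i`, option `r`, normalized time
`t ∈ [0,1]`):

    RT_n ~ LogNormal(η_n, σ_log),   η_n = θa(i)·e^(−θb(i)·t_n) + θc(i,r)

    log θa(i) = β0a + β1a·g(i) + σa·z_a(i)
    log θb(i) = β0b + β1b·g(i) + σb·z_b(i)
    θc(i,r)   = β0c + β1c·g(i) + u_c(i) + α_c(r) + ε_c(i,r)

with g(i) ∈ {0,1} (nonresponder reference), z ~ N(0,1) non-centered,
u_c ~ N(0, σ_subj²), ε_c ~ N(0, σ_cell²), and Σ_r α_c(r) = 0 enforced
*hard* through R−1 free parameters (exact identifiability rather than
soft-centering); the N(0,1) prior is evaluated on the full constrained
vector.  Priors: β0* ~ N(μ_emp, 3²), β1* ~ N(0, 3²), α_c(r) ~ N(0,1),
σa, σb, σ_subj, σ_cell ~ HalfNormal(1.5), σ_log ~ HalfNormal(1).

Empirical centers μ_emp are data-derived, scale-matched defaults: β0c
centers at the mean log RT; β0a at log(max(early − late mean log-RT,
0.05)) where early/late are the first/last quarters of normalized time;
β0b at log 3 (moderate decay over unit time).

* Normalized time uses the **global** maximum observed day index, so
  t ∈ [0,1] exactly and subjects missing late days still map inside it.
* Random-effects variants `none`, `b_only`, `a_and_b`, `b_and_c`,
  `full` nest by which subject-level terms exist; `b_and_c` (random
  decay rate and asymptote, fixed amplitude) is the default structure.
* Models are fit per item; an averaged outcome pools items per
  (subject, day) and re-bins the averaged score into 7 equal-width bins
  over [1,7] (right-open except the last) to keep the option structure.
* The model consumes outlier-filtered RTs, for consistency with the
  feature pipeline.

### Inference

Posteriors are sampled with the package's own No-U-Turn sampler
(`ema_rt.nuts`): dynamic HMC with slice-based trajectory selection, a
generalized U-turn criterion under a diagonal metric, dual-averaging
step-size adaptation, and windowed diagonal mass-matrix estimation
during warmup.  The model supplies analytic gradients of the log
posterior (verified against finite differences in the test suite, and
the sampler against analytically known Gaussian targets).  Scale
parameters are sampled as logarithms with the Jacobian correction.
Default settings: 4 chains, 1000 warmup + 1000 retained draws,
target acceptance 0.95, maximum tree depth 10; chain seeds are forked
deterministically from one seed, so runs are exactly reproducible on a
fixed platform.

Reliability gates (this package's, distinct from any achieved
diagnostics): divergence fraction > 5% or split R-hat > 1.05 on any
scalar parameter flags the posterior unreliable with a warning; the
pipeline continues.  R-hat/ESS and PSIS-LOO come from ArviZ.

### Model comparison and summaries

Variants are compared by PSIS-LOO on identical observations with
moderation terms omitted, reporting ELPD-LOO, its SE, p_loo and the
fraction of observations with Pareto k ≤ 0.7.  Pointwise likelihoods are
densities of RT (Jacobian included), comparable across likelihood
families.

Group effects are reported as responder/nonresponder ratios computed
draw-by-draw: exp(β1) for the log-linked θa and θb, and the additive
log-RT effect β1c exponentiated to a multiplicative RT ratio for the
asymptote.  Summaries are the posterior median, central 95% credible
interval and P(ratio > 1).

Posterior predictive checks bin observations by normalized time and
compare each bin's observed mean RT with the predictive median and 94%
interval of replicated bin means on the original RT scale.

Sensitivity refits swap in (a) the full random-effects variant, (b) a
Student-t observation model on log RT, and (c) Student-t priors on the
β coefficients, with ν fixed at 4 (heavy-tailed but proper; no value is
externally mandated).

## Synthetic cohort generator

The generator emulates the target study design: 49 subjects × 28 daily
occasions × 4 items, ~94% adherence (6% missing occasions), log-normal
RTs decaying exponentially in log-RT space with subject-varying rate and
asymptote, option-specific latency offsets, responder moderation of the
decay rate (×5) and asymptote (×1.25), and multiplicative right-tail RT
contamination (scale 8, rate 2%) for the IQR rule to catch.  Default
noise scales: σa = 0.3, σb = 0.4, σ_subj = 0.3, σ_cell = 0.1,
σ_log = 0.3; nonresponder centers θa ≈ 0.8 (log-RT units), θb = 3 per
unit normalized time (adaptation largely completes within the window,
which is what makes asymptote contrasts estimable at the precision the
analysis reports), θc = log 2.5 (≈ 2.5 s asymptotic RT).  About 30%
of subjects are responders.  Where the study regime states a value
(cohort size, adherence, ratios 5 and 1.25, σ_log = 0.3) the default is
that value; the remaining scales are fixed, field-plausible choices made
once.

Likert answers come from a bounded AR(1) latent mood (φ = 0.7) shared
across a day's items, with subject offsets and item jitter, discretized
by fixed cutpoints at ±0.5, ±1.5, ±2.5.  This coupling is a stand-in:
the joint law of answer content and latency in real data is unknown, and
nothing downstream depends on its specifics beyond producing a realistic
spread of option usage.  Pre/post scale batteries draw baseline scores
from published cohort moments (GDS-15 9.4 ± 4.4, CESD-R 33.9 ± 18.2,
PHQ-9 13.0 ± 7.4, BAI 22.8 ± 16.5); the GDS-15 change is generated around
group means (−6 responders, −0.8 nonresponders, integer-rounded, noise
SD configurable) truncated to respect the MDC boundary, so emitted
batteries reproduce the truth labels exactly; other scales' changes are
coupled to the GDS-15 change with scale-specific slopes and noise.

What the generator does **not** emulate: within-day multiple prompts,
notification timing, item-order effects, time-varying symptom dynamics
within the EMA window, or any app/user-interface behaviour.  Passing
tests therefore demonstrate correctness of the estimators under the
stated generative family, not validity of the scientific conclusion on
real data.

## Problem sizes used in the checks

Study-scale checks (parameter recovery, posterior predictive coverage)
use 49 subjects × 28 days with 5 replicate cohorts and 2 chains of
400 warmup + 400 draws per fit; the structure-selection check uses 10
replicates of 16 subjects × 12 days with 250 + 250 draws.  The
acceptance script fits the moderated model at the full default MCMC
settings.  These sizes are the package's release-test configuration;
the sampler accepts arbitrary sizes.

## Known limitations

* The NUTS implementation runs chains sequentially and is pure NumPy;
  a study-scale moderated fit takes on the order of a minute per 1000
  transitions rather than seconds.
* Raw-scale decay features are biased estimators of log-scale generative
  rates (see above); they are used as behavioural features, not as
  estimates of the hierarchical model's parameters.
* With slow adapters (θb ≈ 1 over the window), the asymptote is weakly
  identified within a 28-day window; group-effect posteriors for θc are
  accordingly wide, and the decay-rate ratio interval is wide on its
  lower side.
* Exact draw-level reproducibility holds for a fixed platform and
  dependency set; floating-point differences across BLAS builds can
  change draws (summaries are stable).
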