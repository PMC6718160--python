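# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Study system and scope

The package implements the landing-sample life-history workflow for a
large, slow-growing, protogynous reef fish: a commercial-landings
length/sex/gonad sample of a few hundred to a few thousand fish, a
length-stratified otolith subsample of ~400 fish read twice by
independent readers, and the data-poor status indicators that can be
computed from lengths alone. All parameter defaults describe that
reference system: asymptotic length L∞ = 85.28 cm, growth rate
K = 0.14 yr⁻¹, t₀ = 0.16 yr, maturity midpoint L₅₀ = 38.5 cm, total
mortality Z = 0.9 yr⁻¹, longevity 22 yr, annulus completion in
November–December, spawning peaks in February–March and August–September,
and a 1:8 male:female landed sex ratio.

## Reproduction

**GSI.** GSI = 100·GW/(TW − GW); the denominator is somatic weight, so
the index is invariant under a common rescaling of gonad and somatic
weight. Monthly summaries pool all sampling years into 12 calendar
months and are restricted to sexually mature females (any gonad stage
past immature counts as mature). Months without data are flagged empty
rather than reported as zero.

**Sex ratios.** Pearson χ² against 1:1 per length bin (default 5 cm)
with df = 1; a bin is "significant" above 3.841 (two-tailed 5%). Bins
missing one sex entirely are flagged (`ratio_with_zero`) because the χ²
there is driven by the zero cell.

**Length at maturity.** Binary logistic model logit(p) = a + βL with
L₅₀ = −a/β. Priors are flat and wide, with β restricted to the
maturity-increasing sign — the only structural information "uninformative
priors" can carry here. Sampling uses emcee's affine-invariant ensemble
(20 walkers) initialised around the MLE; the defaults (100 000 total
draws, thinning 100, 10% burn-in) keep the 1:100 thinning ratio of the
traditional very-long-chain setup at a desk-scale cost, and the full
scheme is available through `AnalysisConfig`. The reported L₅₀ is the
posterior mean with an equal-tailed credible interval (default 90%);
acceptance fraction and an autocorrelation-based effective sample size
are attached as diagnostics. Complete separation is flagged, not
hidden: the posterior then concentrates in the gap between the largest
immature and smallest mature fish, where the data carry no further
information. L₁₀₀ is reported descriptively as the smallest length class
at and above which every sampled female is mature; it is a sample
statistic, not a model parameter.

**Age at maturity.** The equivalent parameterisation
p = 1/(1 + e^{−r(A − A₅₀)}) is fitted by maximum likelihood
(Nelder–Mead on the exact log-likelihood), with the A₅₀ standard error
from the numerically observed information. Perfectly separated data have
no finite MLE; the midpoint of the separation gap is returned with an
infinite slope, which is the likelihood's limit.

## Ageing quality control

APE for fish j is (1/R)·Σᵢ|xᵢⱼ − x̄ⱼ|/x̄ⱼ·100 averaged over fish; CV is
100·SDⱼ/x̄ⱼ averaged over fish (SD with one delta degree of freedom).
Fish whose mean read is zero are excluded — the relative error is
undefined for them, and including them as zeros would deflate the
statistic. For two readings CV ≥ APE algebraically. PD and IRD are
binned by the first reading's age class; the choice of binning reading
is conventional and configurable in spirit (the profiles are nearly
symmetric under swapping readers).

MIR = (R − rₙ)/(rₙ − rₙ₋₁) needs at least two rings and a positive last
increment; fish at or above 50 cm TL are excluded by default because
outer rings of old fish are closely spaced and the denominator becomes
unreliable. Month-pair comparisons use Welch's unequal-variance t test —
the safer default when only "a t test for independent samples" is
specified. The annulus window is inferred as the month(s) attaining the
minimum monthly mean MIR (ties within 1%).

Ages used downstream default to reading 2, configurable to reading 1 or
the rounded mean. For growth fitting, ring counts are converted to
decimal ages by adding the fraction of a year elapsed since the annulus
window (month − 11.5 mod 12)/12; without this correction every age is
understated by ~0.5 yr on average and t₀ absorbs the bias.

## Growth

The VBGF is fitted by nonlinear least squares with additive Gaussian
error, using a bounded trust-region reflective optimizer (a
gradient-based Gauss–Newton-type method reporting convergence).
Starting values come from a Ford–Walford step on mean length at integer
age, with a second start at (1.1·max length, 0.2, 0) to escape local
minima; the best RSS wins. Standard errors are asymptotic,
σ²(JᵀJ)⁻¹ with σ² = RSS/(n − 3). Fits whose L̂∞ exceeds twice the
largest observed length are flagged with a boundary diagnostic rather
than adjusted — data lacking old fish genuinely cannot pin the
asymptote, and the flag is the honest output.

Kimura's test uses the residual-sum-of-squares form
χ² = −N·ln(RSS_Ω/RSS_ω), N the total observations in both groups, Ω the
unconstrained two-curve fit (sum of the two single-group RSS), ω the fit
under 1 or 3 equality constraints; a numerical guard enforces
RSS_ω ≥ RSS_Ω so the statistic is never negative. Calibration on
synthetic data: type-I error 0.03 at nominal 0.05 over 200 null
replicates of 100 fish per group (slightly conservative, as expected for
an RSS-based LRT at this n), power 100% at α = 0.01 against the
inshore/offshore parameter contrast (42.48/0.44/0.56 vs
85.75/0.11/−2.62).

ABI back-calculation maps ring radii to lengths through the allometry
L = A·Rᶜ anchored at a biological intercept (L_bi, R_bi); c is the
log–log regression slope of length on radius (or fixed by config). The
default intercept length is 13.5 cm — the smallest fish the reference
sampling reached — with the intercept radius taken on the fitted
allometry when not supplied. A non-monotone back-calculated series
signals a wrong exponent and raises instead of returning.

## Demography and status

- M = exp(a + b·ln t_max) with defaults (ln 4.899, −0.916), the
  maximum-age estimator; t_max is the maximum observed age. At
  t_max = 22 this gives M = 0.289 yr⁻¹.
- Chapman–Robson (default): ages recoded from the modal (fully
  recruited) class, Ŝ = T̄/(1 + T̄ − 1/n), Z = −ln Ŝ, SE by the delta
  method from Var(Ŝ) = Ŝ(Ŝ − (T − 1)/(n + T − 2)). The log-linear catch
  curve on the descending limb is the alternative. Both assume the
  descending limb is fully selected; gear selectivity and ageing error
  both flatten the limb and bias Z low, which the pipeline reports as-is.
- S = e^{−Z}; F = Z − M floored at zero with a warning;
  GT = A₅₀ + Z(longevity − A₅₀), where Z enters as a weighting in [0, 1].
- L_opt = 3L∞/(3 + M/K); indicators are plain percentages of the catch
  length composition (> L₅₀; within ±10% of L_opt; > 1.1·L_opt), pooled
  and per gear/stratum subset; empty subsets are flagged, not zeroed.
  F is compared against the proxy F_MSY = 0.922·M.

## The synthetic generator

What it emulates: integer ages from a truncated geometric law with rate
Z (max age 22); per-fish VBGF trajectories scaled by one multiplicative
Gaussian deviation (CV 8%) so trajectories are smooth and mean
length-at-age sits on the curve; capture month uniform, with decimal age
measured from the November–December annulus window; weight from a power
law (0.0136·TL^3.05, 8% lognormal noise); female-first sex change by a
length-based logistic (midpoint 65.7 cm frozen from the calibration
routine that solves for an expected 1:8 landed sex ratio, slope
0.15 cm⁻¹, 2% primary males for diandry); maturity Bernoulli on a
logistic in length (midpoint 38.5 cm, slope 0.40 cm⁻¹ — chosen so the
smallest all-mature class lands near the low 50s cm as observed in this
system); gonad weight from a two-peak seasonal GSI (circular Gaussian
bumps at months 2, 3, 8, 9); ring radii back-computed through a single
allometric length–radius law (exponent 1.2), which makes ABI
back-calculation exact by construction and keeps the otolith margin in
phase with months-since-annulus; two readings with integer count errors,
rounded Gaussian truncated at ±3 rings, SD proportional to age
(SD = 1.0 at age 8) so disagreement concentrates in old fish; otolith
weight linear in age (0.05 + 0.12·age g). Gear selectivity is an
effort-weighted pair of logistics (inshore 50%-retention at 38 cm,
slope 0.40; offshore at 52 cm, slope 0.30; effort weights 0.2/0.8), and
stratum labels are assigned in proportion to the stratum-specific
retention at the fish's length.

Two sampling designs are built in: `age_distribution="exponential"` is
the landed catch; `"uniform"` emulates the length-stratified otolith
subsample (similar numbers per 5-cm class), which is what makes the old
age classes — and hence L∞ — estimable at n ≈ 400.

What it does not emulate: spatial structure or movement, cohort
strength variation, environmental covariates, within-year growth
seasonality, dome-shaped selectivity, ageing bias (error is centred),
and length-dependent maturity within an age class beyond what the
length noise induces. Passing tests therefore demonstrate estimator
correctness and calibration under the stated sampling designs, not
robustness to every field complication.

## Pipeline design

A run simulates (or loads) two samples — landing and ageing — then
executes reproduction → ageing → growth → demography. Reproduction,
mortality and the length-based indicators use the landing sample;
reader QC, periodicity, growth and age-at-maturity use the ageing
subsample; longevity is the maximum age across both. All randomness
derives from one root seed split per stage (CRC-based, stable across
processes), so reruns are byte-identical apart from the timestamp. A
stage failure is recorded with its reason and only dependent stages are
skipped. Problem sizes in the test suite (100-seed recovery loops at
n ≈ 358–400, 200 Kimura null replicates, n = 2000 for mortality,
n = 4550 for the sex-ratio band) were chosen as the smallest designs
at which the corresponding asymptotics are trustworthy.

## Known limitations

- The length–weight relation defaults to the linear form used in the
  reference workflow; the allometric (log–log) form is the better model
  across a wide size range and is available via `model="power"`.
- Catch-curve Z inherits every violation of the equal-recruitment,
  full-selection assumptions; with the default selective landing sample
  it is biased low by design and should be read as an illustration, not
  as a recovery of the generator's Z (the acceptance checks recover Z
  under full retention).
- The Bayesian maturity fit restricts β > 0; stocks where maturity
  genuinely declines with length (senescence, skipped spawning) are out
  of scope.
- The MCMC effective-sample-size diagnostic uses emcee's
  autocorrelation-time estimate, which is itself noisy on short chains;
  treat it as an order of magnitude.
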