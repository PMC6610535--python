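# Methods

## Per-patient response: the PSA slope

Each patient contributes a series of PSA measurements (ng/ml) at times
measured in months from the start of radiotherapy. The response is the
simple OLS slope of PSA against time, in ng/ml/month. The last
pre-treatment measurement (the single point with time <= 0) is included in
the fit; if several pre-treatment values are present only the latest is
kept, so the pre-treatment level anchors the regression without letting an
unregulated pre-treatment sampling schedule dominate it. PSA is regressed
on its natural scale, not log-transformed — the slope magnitudes this
produces (roughly −0.1 to −0.35 ng/ml/month) are the scale on which the
dose-response model and its priors are parameterized. Patients with fewer
than two usable measurements, or no time spread, are excluded from
modeling and listed in the run log rather than imputed.

The slope is dichotomized at zero: "positive" means strictly rising PSA;
zero and negative slopes are "nonpositive". (A separate cohort count
splits at strictly-negative, since "how many patients' PSA actually fell"
is the natural descriptive question.)

## Dose grouping and risk stratification

Total dose is binned into four ordered groups: <50 Gy, [50, 70) Gy,
exactly 70 Gy (within a configurable tolerance, default 0.005 Gy, since
prescriptions are recorded as nominal values) and >70 Gy. D'Amico risk
levels are assigned with High taking precedence (iPSA > 20 ng/ml OR
Gleason >= 8 OR stage >= T2c), then Low (iPSA <= 10 AND Gleason <= 6 AND
stage <= T2a), else Intermediate; this precedence makes the published
conditions — which overlap at iPSA = 10 and 20 — exhaustive and
exclusive.

## The Bayesian dose-response model

With slope_ij the response of patient j at dose level i:

    slope_ij | mu_i            ~ Normal(mu_i, sigma2_slope)
    mu_i     | mu_{i-1}        ~ Normal(mu_{i-1}, d_i * sigma2_mu)
    mu_0                       ~ Normal(0, 1e4)
    1/sigma2_slope, 1/sigma2_mu ~ Gamma(0.001, 0.001)

The random walk expresses the dose-response idea that mean responses at
nearby doses should be similar, with the link loosening as the dose gap
grows: d_i is the square root of the gap between the representative dose
of level i and that of level i−1. The representative dose of a group
defaults to its observed mean total dose (nominal fallback 45/60/70/75 Gy
when the data lack spread), and mu_0 is a latent reference-level mean
placed at 0 Gy, giving d_1 = sqrt(dose_1). Priors follow the common
diffuse convention: Gamma(0.001, 0.001) on both precisions and precision
1e-4 (variance 1e4) on mu_0; all are configurable.

Every full conditional is conjugate — each mu_i given its neighbours and
data is normal, each precision is gamma — so the fit is a systematic-scan
Gibbs sampler with no tuning. Defaults: 3 chains, 12,000 kept iterations
after 2,000 burn-in, thin 1, overdispersed starts at group mean ± 2 group
sd (offsets cycled across chains), all driven by one seed through spawned
per-chain generators. Non-finite states abort with the iteration index.
Summaries pool chains: mean, sd, empirical 2.5/50/97.5 percentiles, and
the Gelman-Rubin statistic R̂ = sqrt(((n−1)/n·W + B/n)/W). Note the
(n−1)/n factor lets R̂ sit marginally below 1 when the between-chain
variance is essentially zero; chains that are exactly constant and equal
report R̂ = 1, constant at different values report infinity.

Two limiting cases make the sampler testable against closed forms: with
both variances fixed the whole posterior is Gaussian (dense linear-algebra
oracle; 1-D/2-D quadrature for the single-group case), and with
sigma2_mu fixed very large the levels decouple into independent normal
models whose posterior means are the group sample means. With only four
random-walk increments informing it, the posterior of sigma2_mu is
heavy-tailed and often concentrates near zero, which shrinks the four
level means toward each other; this adaptive smoothing is intended model
behavior, visible as a small coverage cost (~92% empirical coverage of
95% intervals in the recovery simulations) concentrated on the extreme
dose levels.

## Classical statistics

Kaplan-Meier estimation, the k-sample log-rank test (hypergeometric
variance, ties pooled), Mann-Whitney (exact null distribution when
n_x·n_y <= 400 and tie-free, otherwise the tie-corrected normal
approximation), Kruskal-Wallis with midranks and tie correction, one-way
ANOVA, Pearson correlation, and a Newton/IRLS logistic fit (convergence
tolerance 1e-8, perfect or quasi separation raised as an explicit error)
are provided behind one module; the implementations delegate to lifelines,
scipy and statsmodels and are pinned by hand-computed and brute-force
oracles in the test suite. "Mean disease-free survival" is the restricted
mean: the area under the KM curve truncated at the largest observed time
(the common statistics-package convention; the truncation point is
selectable), with a Greenwood-derived standard error and a ±1.96·se CI.

## Prentice surrogacy evaluation

All criteria use alpha = 0.05 by default, with no multiple-testing
correction (the report says so explicitly):

* **I, dose → recurrence:** log-rank across the four dose groups AND
  Mann-Whitney of total dose by recurrence status, both p < alpha.
* **II, dose → slope:** ANOVA (or Kruskal-Wallis, by config) of slope
  across dose groups, p < alpha; the posterior credible-interval overlap
  across dose pairs is reported alongside as the Bayesian reading.
* **III, slope → recurrence:** reported in both forms — dichotomized
  (log-rank by slope sign) and continuous (Mann-Whitney of slope by
  recurrence). The two can genuinely disagree; the overall verdict uses
  the continuous form by default, switchable, and the report always shows
  both.
* **IV, full capture:** two prongs, both required: in the joint logistic
  model (recurrence ~ dose in Gy + slope in ng/ml/month, both continuous;
  categorical dose coding available) the dose coefficient must be
  non-significant while the slope coefficient is significant; and the
  dose log-rank test inside each slope-sign stratum must be
  non-significant. A stratum that cannot be tested (no events, or a
  single dose group) counts conservatively as "not met": full capture is
  then unproven, not established.

The overall verdict is the conjunction of I-IV; it is monotone — breaking
any criterion can never validate the surrogate.

## The synthetic cohort generator

The generator emulates the two input tables the pipeline consumes. Per
patient: a dose group from configurable probabilities (default the
observed 24/30/119/22-of-195 mix; assignments are redrawn, bounded, until
all four groups are populated, because the random-walk model needs all
levels), an actual dose drawn inside the group's bin (exactly 70 Gy for
group 3), iPSA log-normal (default log-mean 2.2, log-sd 0.77), Gleason
and T-stage from categorical mixes chosen so that all three D'Amico
strata occur (roughly 13/52/35 Low/Intermediate/High), and follow-up
drawn Beta(1, 3)-skewed over 4-67 months (mean ~20 months — most
patients are followed a year or two, a minority much longer).

The true slope of a patient is Normal(mu_g, slope_sd²) around the group
mean; defaults mu = (−0.1543, −0.2733, −0.2203, −0.332) ng/ml/month with
slope_sd = 0.17, which yields ~90% negative slopes. Observed PSA is
max(0, baseline + slope·t + Normal(0, noise²)) at one jittered
pre-treatment time and quarterly jittered visits capped at 19
measurements (so the number of visits tracks follow-up length almost
perfectly). The max(0, ·) assay floor is logged; it makes long
trajectories of low-baseline fast-falling patients sub-linear, a
deliberate realism that biases their OLS slopes toward zero — recovery
tests therefore use high-baseline/short-follow-up settings where the
floor never binds.

Recurrence is exponential with log-hazard = intercept + b_dose·dose +
b_pos·1[slope > 0] (defaults 0.5, −0.08/Gy, +1.5), censored
administratively at the end of follow-up (an optional random early
censoring rate exists but defaults to 0; the real cohort's censoring
mechanism is unknown). The slope-sign indicator can be taken from the
latent true slope (default) or from the OLS sign of the generated
measurements (`mediator="measured"`). The measured option exists because
a surrogate-endpoint benchmark needs the *analyst's* surrogate to be the
exact mediator: with the latent sign, measurement error misclassifies
near-zero slopes and leaves a residual dose effect inside slope-sign
strata, so "full mediation" would not hold by construction.

Two named configurations package the benchmark cohorts:
`mediated_benchmark_config` (n = 400, balanced dose groups, strong
dose-to-slope gradient, hazard exp(−5.6 + 3.0·1[measured slope > 0]), no
direct dose term) on which the evaluation should return "valid
surrogate" — empirically in ~83% of replicates, the ceiling being the
alpha criterion IV spends on itself (one 5% logistic check and two 5%
stratified log-ranks ≈ 86% even under perfect mediation); and
`broken_mediation_config` (flat slope means, direct dose effect) on which
criterion II fails.

What the generator does **not** emulate: hormonal therapy, PSA bounce and
nadir dynamics, change-point or mixed-model PSA kinetics, informative
visit schedules, non-administrative censoring, and the real cohort's
heavy-tailed slope distribution (Table-2-style posterior sds imply a
between-patient sd near 0.4 ng/ml/month, which a normal model cannot
reconcile with 90% negative slopes; the defaults favor the negative-slope
fraction). Passing tests therefore certify the statistical machinery
under the stated generative model, not those clinical phenomena.

## Problem sizes and numerical choices

The default pipeline runs 3 × (2,000 + 12,000) Gibbs iterations in a few
seconds. Simulation-based tests use 200 replicates for
recovery/coverage (two chains, 800 kept draws each — ample for posterior
means at this dimension), 300 replicates for the mediated-benchmark rate,
50 for the broken-mediation rate and 500 for type-I error checks; Monte
Carlo standard errors in the sampler-exactness tests come from
autocorrelation-adjusted effective sample sizes. Probabilities in the
dose-group simplex must sum to 1 within 1e-12 (the default closes the
simplex exactly); representative doses must be strictly increasing;
equality with the 70 Gy bin uses the tolerance above; all randomness in a
run descends from a single integer seed via spawned generator streams.
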