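# psadose

Bayesian dose-response analysis of the post-radiotherapy PSA slope, and a
four-criterion (Prentice) evaluation of whether that slope can stand in
for prostate-cancer recurrence as a surrogate endpoint.

## The problem

After radiotherapy (RT) for localized prostate cancer, serum PSA is
measured repeatedly. The **PSA slope** — the OLS slope of PSA (ng/ml)
against time (months), with the last pre-treatment value anchoring the
fit — summarizes each patient's marker response. Two questions drive the
package:

1. **Dose-response.** Do higher total radiation doses (four groups:
   <50 Gy, [50, 70) Gy, =70 Gy, >70 Gy) produce steeper PSA decline? The
   model is a hierarchical normal model with a random-walk prior linking
   the mean response at adjacent dose levels:

   ```
   slope_ij ~ Normal(mu_i, sigma2_slope)            i = 1..4 dose levels
   mu_i     ~ Normal(mu_{i-1}, d_i * sigma2_mu)     d_i = sqrt(dose gap)
   mu_0     ~ Normal(0, 10^4),   1/sigma2_* ~ Gamma(0.001, 0.001)
   ```

   All full conditionals are conjugate, so the posterior is sampled by a
   Gibbs sampler (default 3 chains x 12,000 kept draws), summarized as
   mean / sd / 2.5% / median / 97.5% per dose level with the Gelman-Rubin
   convergence statistic.

2. **Surrogacy.** Is the PSA slope a valid surrogate for disease-free
   survival? The four Prentice criteria are each tested at alpha = 0.05:
   (I) dose predicts recurrence (log-rank across dose groups +
   Mann-Whitney of dose by recurrence); (II) dose predicts the slope
   (ANOVA or Kruskal-Wallis, plus credible-interval overlap); (III) the
   slope predicts recurrence (log-rank by slope sign, and Mann-Whitney of
   the continuous slope); (IV) the slope captures the *full* dose effect
   (in a joint logistic model the dose term must lose significance while
   the slope retains it, and dose log-rank tests inside each slope-sign
   stratum must be non-significant). The surrogate is valid only if all
   four hold.

A synthetic-cohort generator produces patient and PSA-trajectory tables
with the same layout and statistical structure the analysis assumes
(dose-dependent mean slopes, declining trajectories, recurrence hazard
linked to dose and slope sign), so the whole pipeline is testable without
any external data.

## Worked example

```bash
psadose run --seed 1 --out-dir run1
```

runs cohort generation (195 patients) → stratification → slopes → Gibbs
fit → surrogacy, and prints the report. Abridged output from that exact
command:

```
PSA slopes: 175 negative, 20 zero/positive; r(follow-up, #measurements) = 1.00 ...

Posterior PSA-slope means by dose level (ng/ml/month)
  dose_level    mean     sd    2.5%  median   97.5%  gelman_rubin
      <50 Gy -0.1992 0.0385 -0.2744 -0.1994 -0.1234        1.0000
  [50 70) Gy -0.2113 0.0266 -0.2637 -0.2111 -0.1591        1.0001
      =70 Gy -0.1980 0.0149 -0.2272 -0.1981 -0.1687        1.0000
      70< Gy -0.2211 0.0336 -0.2892 -0.2204 -0.1571        1.0000

Prentice criteria at alpha = 0.05 (no multiple-testing correction applied)
  I: dose predicts recurrence: MET
    log-rank: statistic=52.04, df=3, p=2.942e-11
  II: dose predicts PSA slope: NOT MET
    anova: statistic=0.3338, df=3, p=0.8009
    note: 95% credible intervals overlap in 6/6 dose pairs
  ...
  IV: slope captures the full dose effect: NOT MET
    logistic dose: statistic=-0.08601, p=9.871e-06 ...

Overall (criterion III form: continuous): PSA slope is NOT a reliable surrogate
```

Reading: PSA falls after RT at every dose level (all four posterior means
negative; 175/195 patients with a negative slope) and R-hat ~ 1 says the
chains converged. But the dose groups' slope means are statistically
indistinguishable (criterion II fails; all credible intervals overlap)
and dose retains a direct, slope-independent effect on recurrence
(criterion IV fails) — so the slope alone cannot replace the recurrence
endpoint.

Other subcommands: `psadose simulate`, `psadose slopes`,
`psadose fit-bayes`, `psadose surrogacy` (see `--help`); everything is
also importable (`psadose.gibbs_fit`, `psadose.evaluate_prentice`, ...).

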