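# Methods

## The model

`lekipm` joins two data streams that share no parameter — an annual lek-count
index of males and a short series of demographic vital-rate estimates —
through the one quantity both measure: annual population growth rate λ.

**Count stream.** The index observation in year *t* is the high male count
*M*<sub>t</sub> over the lek areas surveyed. Survey effort varies, so counts
carry a weight ω<sub>t</sub> = *l*<sub>t</sub>/*L* (lek areas surveyed over
total lek areas). The count model is Malthusian growth in a latent abundance
index *N*<sub>t</sub> with Poisson observation:

    M_t | N_t      ~ Poisson(ω_t · N_t)
    log N_t        = log N_{t−1} + log λ^c_t
    log λ^c_t      ~ Normal(μ_c,t , σ²_c)
    log N_1        ~ Normal(log(M_1/ω_1), 100)

λ^c is lognormal by assumption; μ<sub>c,t</sub> is constant, linear, or
quadratic in the year index (centred and scaled to [−1, 1]). The Poisson
layer introduces no extra variance parameter, so the parameter set stays
{μ_c (plus trend coefficients), σ²_c, a, b, σ²_r}. A lognormal observation
layer could be swapped in behind the same `ModelSpec` interface.

**Demographic stream.** Vital rates (yearling/adult survival by sex, and
female fecundities F_y, F_a composed from nest initiation, nest success,
clutch size, chick sex ratio, daily chick survival to 30 days and monthly
juvenile survival) populate a 2×2 prebreeding female Leslie matrix
[[F_y, F_a], [S_yf, S_af]]. Its dominant eigenvalue is the demographic
growth rate λ^d for that year; the stable age distribution is the dominant
right eigenvector. The 2×2 eigenpair is computed in closed form (the
quadratic root), with a generic eigensolver used only as a cross-check in
tests.

**Link.** A male-only index and a female-based matrix model need not grow at
the same rate, so the two log growth rates are linked by a regression that
estimates the systematic offset and the difference in variability:

    log λ^d_t ~ Normal(a + b · log λ^c_t , σ²_r)

with priors a ~ N(0, ·) (no systematic difference a priori) and b ~ N(1, ·)
(identical growth a priori). λ^d values enter as fixed data (log dominant
eigenvalues of the year-specific matrices); their own sampling uncertainty is
absorbed by σ²_r.

## Priors

`Priors` defaults:

| parameter | prior | note |
|---|---|---|
| μ_c | N(0.02, 0.50) | near-flat, centred at a stable population |
| σ²_c | IG(9.9, 1/102) | informative; prior mass near 1e−3, the scale of index growth variance |
| σ²_r | IG(2.001, 1/999) | weak; prior mean ≈ 1e−3 with a usable right tail |
| a | N(0, 0.1) | moderately tight: no systematic offset a priori |
| b | N(1, 0.1) | moderately tight: identical growth a priori |

The variance hyperparameters follow the published set for this model family
read in precision-style (BUGS) conventions — a gamma prior on a precision
with (shape, scale) maps to σ² ~ IG(shape, 1/scale) — because that is the
only reading consistent with the posterior scales the model produces. For
the link, neither mechanical reading of the printed value 0.001 works:
as a variance it pins (a, b) at (0, 1) exactly; as a precision (variance
1000) it is empirically degenerate — six demographic years cannot identify
the slope, and a flat slope prior lets the sampler interpolate the link
data through implausible slopes (|b| of tens), collapsing σ²_r onto its
prior. The default variance 0.1 keeps the link priors tight, as intended
for a sparsely informed relationship, while leaving slopes like 0.8
reachable. `Priors.from_table(interpretation=...)` exposes both mechanical
readings of the printed numbers. Trend coefficients get N(0, σ²_μ).

`Priors.vague()` (IG(0.001, 0.001) variances, N(0, 100)/N(1, 100) link) is
used in the calibration experiments. Those experiments check frequentist
coverage at a *fixed* truth, and the equal-tailed interval of a normal
variance under the near-Jeffreys prior is an almost exact chi-square pivot;
informative priors would dominate the six link observations and turn the
calibration check into a check of the prior. The IG scale must be ~1e−3 or
smaller: the growth variances are themselves of order 1e−3, so a scale of
0.01 would already contribute ~10% of the posterior sum of squares.

## Fitting

A hybrid Gibbs/Metropolis sampler, 20,000 iterations with 2,000 burn-in by
default. Per iteration:

1. **Latent path** — single-site random-walk Metropolis on log N_t,
   vectorised over even/odd sites (a site's terms touch only its
   neighbours, so each parity block updates jointly). log λ^c = diff(log N)
   is a unit-Jacobian reparameterisation, so this targets the same joint
   posterior as updating log λ^c directly while keeping a sweep O(T).
   Proposal scales adapt by Robbins–Monro toward 44% acceptance during
   burn-in only; the retained chain has a fixed kernel.
2. **Trend coefficients** — conjugate normal (scalar for the constant model,
   multivariate for linear/quadratic).
3. **σ²_c** — conjugate inverse gamma on the growth residuals.
4. **(a, b)** — conjugate bivariate normal regression update.
5. **σ²_r** — conjugate inverse gamma on the link residuals.

Initial values: latent path at the raw effort-adjusted counts, parameters at
prior means, variances at sample variances of the raw residuals — in
practice convergence is reached within a few hundred iterations. Any
non-finite log density aborts with the iteration index. All randomness flows
through one `numpy` Generator, so runs are exactly reproducible given a seed.

Numerical edge cases: inverse-gamma draws at very small shapes (vague prior,
no data) can underflow the underlying gamma variate; the draw is capped at
1e300 rather than overflowing to infinity. A zero proposal scale leaves the
latent state unchanged (identity proposals are accepted).

## Model comparison and fit checks

**WAIC** (−2(lppd − p_WAIC), variance-form penalty, log-sum-exp stabilised)
compares the constant/linear/quadratic trend models. The pointwise
log-likelihood focuses on the *growth layer*: one term per observed raw
effort-adjusted growth rate, N(g_t; μ_c,t, σ²_c), plus one per demographic
growth rate. The count-level alternative (`focus="counts"`, Poisson terms
conditional on the latent path) is provided, but it cannot separate trend
models: the latent path absorbs any trend, leaving the conditional density
essentially model-invariant. WAIC must be focused at the level at which the
models differ. Because nested-model WAIC differences are of order 1–2 units,
chains used for comparison should be long enough that the Monte-Carlo error
of WAIC is well below that (the comparison experiments use 5,000-iteration
chains).

**Posterior predictive check.** The discrepancy is the sample variance of
the log raw growth rates. For each retained draw a full replicate count
series is simulated from that draw's parameters (new growth path, new
Poisson counts) and the Bayesian p-value is Pr(T_rep ≥ T_obs); values near
0.5 indicate the fitted model reproduces the observed variability, values
near 0 or 1 flag misfit. A mean-squared-deviation variant
(`statistic="mse"`) is provided as an alternative discrepancy.

## Projection

Posterior-predictive growth rates drive an age-structured projection:

1. Simulate 10,000 vital-rate sets from a multivariate normal on the logit
   scale (fecundities are scaled by a ceiling, default 2.0, before the
   logit since they are not probabilities), optionally inflating the
   covariance by a constant c to widen the achievable growth-rate range
   while preserving correlations. `select_inflation` picks the smallest
   c ∈ {1, 1.5, 2, 3, 4} whose simulated λ range covers the target range —
   the quantitative version of a graphical coverage check. Each set's λ is
   its matrix's dominant eigenvalue.
2. For each of `n_trajectories` posterior draws, sample the predictive
   log λ^d sequence, match every year to the nearest simulated λ
   (ties to the lowest row; out-of-range targets clamp to the extreme row
   and emit a coverage warning), and run n_{t+1} = A_t n_t.
3. The initial total is Poisson(β₀) with β₀ = round(mean count × correction
   factor); the correction (default 4.73 = (1 + 1.6 female:male ratio) /
   ~0.55 male lek attendance) converts a male count into a population size.
   The initial age split is the stable age distribution of the first matched
   matrix, on the assumption the population is near stable age structure.

Projection is deterministic given the matched matrices: the only
stochasticity per trajectory is the Poisson initial size and the draw of the
predictive growth path. Summaries are per-year means with 90% intervals.

## Synthetic data

`synthetic.generate_dataset` simulates the exact generative model above:
default scenario is 17 count years at full effort (30 of 30 lek areas),
initial index abundance 750 (counts in the several hundreds), a 6-year
demographic window ending two years before the series, and true parameters
at the published posterior means (μ_c = 0.019, σ²_c = 0.003, a = −0.019,
b = 0.811, σ²_r = 0.033). The truth record (latent growth path, latent
abundances, demographic rates) is returned and written alongside the data.
`generate_vital_rate_study` emulates a short vital-rate study from the
logit-scale MVN; `default_vital_distribution` centres on plausible
sage-grouse rates with matrix growth rate ≈ 0.96 and mildly correlated
(0.3) logit-scale deviations of SD 0.15.

What the generator does *not* emulate: observer effects and detectability,
within-season repeated counts, lek-level spatial structure, demographic
stochasticity in the projection, and autocorrelated year quality. Passing
calibration tests therefore demonstrates that the machinery is correct under
the model's own assumptions, not that those assumptions hold for any field
data set.

## Calibration experiments (what the test suite runs)

* Conjugate full conditionals against brute-force grid posteriors (≤1e−3).
* Closed-form eigenpair against a generic eigensolver (≤1e−12) and the
  Metropolis latent update against 2-D/3-D grid posteriors.
* Parameter recovery: 100 studies of 60 count years + 6 demographic years
  at the default truth; 95% intervals must cover every parameter in ≥90
  studies and μ_c/b posterior means must be unbiased to within half a
  posterior SD. Fits use 2,000 iterations (500 burn-in) — sufficient here
  because convergence occurs within a few hundred iterations at this scale.
* WAIC selection: 50 constant-truth studies, all three trends fitted with
  5,000-iteration chains; the constant model must rank first in ≥80%. Note
  the information-theoretic ceiling: among nested models WAIC behaves like
  AIC, so the expected selection rate is only ~80–84% — the criterion sits
  near the boundary of what any information criterion of this family can
  deliver.
* PPC calibration: 100 well-specified studies; p-values must avoid the
  rejection tails (0.05, 0.95) in ≥90%.

## Known limitations

* The effort weight enters only the Poisson mean; it does not model
  lek-level heterogeneity, so unequal effort with strongly heterogeneous
  leks would bias the index beyond what ω corrects.
* λ-matching selects a single nearest vital-rate set per year; it transfers
  growth-rate uncertainty but not the full vital-rate posterior, and is
  biased low when the simulated λ range fails to cover the predictive range
  (hence the covariance inflation and its coverage warning).
* σ²_c and the Poisson noise are only weakly separable when counts are
  small; with counts in the hundreds (the default scenario) the decomposition
  is informative but posterior coverage of σ²_c is the tightest of the five
  parameters.
* The total number of lek areas L is rarely published; the data-driven
  default (max observed effort) makes ω a relative, not absolute, effort
  measure — which the growth-rate formulation is invariant to.
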