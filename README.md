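# lekipm

Bayesian integrated population modelling for lek-counted grouse.

Monitoring data for rare lekking birds usually come in two poorly matched
pieces: a long, noisy index (annual high counts of males attending leks,
with uneven survey effort) and a short, intensive demographic study
(survival and fecundity estimates spanning a few years). The two share no
parameter, but both measure population change. `lekipm` implements an
integrated model that links them through the annual population growth rate
λ, for analysts who want index-scale trend inference stabilised by
demographic information, and population projections driven by both.

## The model

Counts follow a Malthusian state-space model with effort weighting
ω<sub>t</sub> = l<sub>t</sub>/L:

    M_t | N_t   ~ Poisson(ω_t N_t)
    log N_t     = log N_{t−1} + log λ^c_t
    log λ^c_t   ~ N(μ_c,t, σ²_c)        μ_c,t constant, linear or quadratic in year

Year-specific vital rates build a 2×2 prebreeding female Leslie matrix
[[F_y, F_a], [S_yf, S_af]]; its dominant eigenvalue is the demographic
growth rate λ^d. The streams are linked on the log scale,

    log λ^d_t ~ N(a + b · log λ^c_t, σ²_r),

where a absorbs systematic offset between a male index and a female matrix
model, and b the difference in variability. Fitting is by a hybrid
Gibbs/Metropolis sampler (conjugate updates for all parameters, adaptive
random-walk updates for the latent abundance path). Trend models are
compared by WAIC, fit is checked with a posterior predictive Bayesian
p-value on growth-rate variability, and population trajectories are built
by matching posterior-predictive growth rates to simulated vital-rate sets
(logit-scale multivariate normal with optional covariance inflation) and
projecting a Poisson initial population through the matched matrices.
See `docs/methods.md` for the full account.

## Worked example

Simulate a 17-year study at the default scenario (six demographic years,
full effort, true λ drawn around 1.02 with σ²_c = 0.003), fit it, check it,
and project it:

```python
from lekipm import *

lek, demo, truth = generate_dataset(TrueParams(), n_years=17, seed=42)
weights = effort_weights(lek, EffortConfig.from_series(lek))
spec = build_model(lek, weights, demo, trend="constant", priors=Priors())
draws = run_mcmc(spec, n_iter=20_000, burn=2_000, seed=1)
print(summarize(draws).round(4))
```

```
parameter    mean   lower  upper
       b0  0.0162 -0.0027 0.0352
 sigma2_c  0.0014  0.0007 0.0024
        a -0.0790 -0.1982 0.0430
        b  1.0681  0.4211 1.6979
 sigma2_r  0.0221  0.0074 0.0589
```

`b0` is the mean log growth rate of the count index: exp(0.0162) ≈ 1.016, a
slightly growing population whose 95% interval (0.997, 1.036) includes
stability. The link slope b ≈ 1.07 with a wide interval says six
demographic years barely inform the relationship; the offset a is
indistinguishable from zero.

```python
ppc = variance_ppc(draws, seed=3, thin=4)
print(f"Bayesian p-value: {ppc.p_value:.3f}")

table = simulate_vital_rates(default_vital_distribution(inflation=3.0), 10_000, seed=4)
beta0 = initial_mean(lek, (1996, 2012), 4.73)   # mean count x correction factor
res = project_posterior(draws, table, ProjectionConfig(beta0=beta0, n_trajectories=1000), seed=5)
print(beta0)
print(res.summary.round(0).tail(3))
```

```
Bayesian p-value: 0.432
3888
 year   mean   q05    q95
 2010 2657.0 359.0 7915.0
 2011 2686.0 309.0 8584.0
 2012 2665.0 263.0 8724.0
```

A p-value near 0.5 means the fitted model reproduces the observed
growth-rate variability. The projection starts at a Poisson(3888)
population (the effort-weighted mean count times the 4.73 lek-count
correction) and stays roughly level, with wide 90% intervals — the honest
summary of what a 17-year index plus six demographic years can say.

The same pipeline is scriptable from the shell (`lekipm simulate / fit /
compare / ppc / project`, each taking `--config config.yaml --seed N --out
DIR` and writing CSV/JSON artifacts).

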