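# sarprobit

Spatial autoregressive probit modelling of binary land-management
choices, built around the willingness-to-harvest (WTH) decision of
family forest owners (FFOs): whether an owner would conduct a
commercial timber harvest, as a function of their attitudes,
demographics, land characteristics — and of the stated preferences of
geographically proximal owners.

It is aimed at spatial econometricians and natural-resource social
scientists who have (or want to simulate) georeferenced owner-level
survey data and need the full chain: spatial weights → binary-choice
models → spillover decomposition.

## The model

Each owner `i` holds a latent net utility of harvesting

    y*_i = ρ (W y*)_i + x_i'β + ε_i,   ε ~ N(0, I_n),   WTH_i = 1(y*_i > 0)

where `W` is an n×n row-standardized spatial dependence matrix built by
Delaunay triangulation of parcel coordinates (two owners are neighbours
iff they share a triangle edge; each row of `W` sums to one) and ρ
measures spatial autocorrelation in harvest preferences.  At ρ = 0 the
model collapses to the ordinary probit `P(WTH=1|x) = Φ(x'β)`.

Estimation is Bayesian — priors β ~ N(0, I), ρ ~ U(0, 1) — by an MCMC
scheme cycling three exact conditionals: single-site Gibbs sweeps of
the truncated-normal latent utilities, a conjugate normal draw of β,
and a griddy-Gibbs draw of ρ (log|I − ρW| tabulated once from the
eigenvalues of W).  The ordinary probit is fit by maximum likelihood
for comparison.

Because `(I − ρW)⁻¹` propagates any covariate change to neighbours,
marginal effects decompose into average **direct** (own-observation),
**indirect** (spillover), and **total** impacts via the impact matrix
`S_r = diag(φ(η)) (I − ρW)⁻¹ β_r`, with η the reduced-form mean index.

A synthetic-data generator emulates the survey the package is designed
around — 242 Missouri FFOs (182 residential, 60 absentee), Bernoulli
attitude/demographic indicators at the observed frequencies,
truncated-normal road distances, and outcomes from the latent spatial
process — so every stage is testable without the original data.

## Worked example

```python
from sarprobit import (SimConfig, simulate_dataset, fit_probit, McmcConfig,
                       run_sampler, average_effects, indirect_share)
from sarprobit.reference import SIGNIFICANT_COVARIATES

sim = simulate_dataset(SimConfig(seed=7))          # n=242 study conditions
print("WTH base rate:", round(sim.table.df["wth"].mean(), 3))

probit = fit_probit(sim.table)
print("probit sawlog coefficient:", round(probit.params["sawlog"], 3),
      "| correctly predicted: %.1f%%" % probit.pct_correct)

post = run_sampler(sim.table, sim.w,
                   cfg=McmcConfig(n_draws=20_000, burn_in=5_000, seed=1))
print(post.summary().round(3).loc[["sawlog", "past_harvest", "rho"]])

effects = average_effects(post, w=sim.w, table=sim.table)
print(effects.table.round(3).loc[["sawlog", "past_harvest"]])
print("indirect share (significant covariates): %.1f%%"
      % indirect_share(effects, SIGNIFICANT_COVARIATES))
```

prints

```
WTH base rate: 0.322
probit sawlog coefficient: 1.134 | correctly predicted: 76.4%
               mean     sd  p_value  prob_positive
sawlog        1.129  0.274    0.000            1.0
past_harvest  0.936  0.197    0.000            1.0
rho           0.308  0.121    0.011            1.0
              direct  indirect  total
sawlog         0.302     0.127  0.429
past_harvest   0.251     0.105  0.355
indirect share (significant covariates): 29.5%
```

Read: on this synthetic draw roughly 32% of owners are willing to
harvest; owning forest for sawlog production raises the latent
harvesting utility by ≈1.1 standard deviations; the posterior for the
spatial dependence ρ centres on 0.31 (generated at 0.167 — a single
n=242 dataset identifies ρ loosely, posterior SD 0.12); and of the
total 0.355 probability impact of past harvest experience, 0.105 flows
through neighbours.

The same pipeline is available from a shell:

```bash
sarprobit simulate --n 242 --seed 7 --out study
sarprobit replicate --input study.csv --draws 20000 --burn-in 5000 --out run/
sarprobit recover --replicates 20 --n 500 --rho 0.4
```

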