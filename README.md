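# dynocc — dynamic occupancy models for growing pond networks

`dynocc` fits Bayesian multi-season (dynamic) occupancy models to
detection/nondetection surveys of pond-breeding amphibians in a pond
network that changes over time: new ponds are constructed, some ponds are
destroyed, and subregions are surveyed on a rotating panel.  It is aimed at
monitoring programs that want to know whether metapopulations are
increasing, stable or declining — and how much of the trend is carried by
newly created habitat — while accounting for imperfect detection and
observer heterogeneity.

## The model

For site *i*, visit *j* and year *t*, the observed detections relate to the
latent occupancy state *z<sub>it</sub>* through

    y_ijt ~ Bernoulli(z_it · p_ijt)

with detection modelled separately for night visits (*j* ∈ {1, 2}; observer
random effect β<sub>Obs</sub> ~ N(0, σ²<sub>Obs</sub>)) and the day visit
(*j* = 3):

    logit(p_ijt) = α_p + β_Obs(ijt)   (night),   α_p + β_day   (day)

Occupancy follows a two-state Markov chain masked by site existence
*E<sub>it</sub>* (a pond must exist to be occupied):

    z_i1 ~ Bernoulli(ψ1_Region(i) · E_i1)
    z_it ~ Bernoulli([(1 − z_i,t−1) γ_it + z_i,t−1 φ_i] · E_it)

Colonization γ gets region intercepts, a region-specific new-pond contrast
and seven covariate slopes (log surface area, water-table fluctuation,
forest within 100 m, elevation, large-road area within 1 km, structural
connectivity C<sub>it</sub> = Σ<sub>j≠i</sub> exp(−d<sub>ij</sub>), and pond
age); persistence φ gets region intercepts and a new-pond contrast.  All
continuous covariates are standardized.  Priors are vague: Uniform(0,1) on
probability-scale intercept means, Uniform(0,10) on SDs, Uniform(−10,10) on
logit-scale slopes.

Inference is by MCMC (a latent-state Gibbs sampler written for this model;
an independent forward-marginalized Metropolis sampler serves as a
cross-check), with Brooks–Gelman–Rubin convergence diagnostics and
posterior predictive checks on occupied-site counts.  From the posterior
the package derives metapopulation-size trajectories (split into old and
new ponds), classifies 1999→2019 changes at 90% certainty, and assigns each
metapopulation one of eight patterns describing how new ponds contributed
to its trend.

## Worked example

```python
from dynocc import make_fixture, DynamicOccupancyModel, MCMCConfig

fx = make_fixture("tiny", seed=1)          # synthetic study with known truth
model = DynamicOccupancyModel(fx.data)     # builds covariates + likelihood
res = model.fit(MCMCConfig(n_chains=3, n_burnin=300, n_iter=1000, thin=10,
                           seed=1))
print(res.summary().loc[["alpha_p", "mu_alpha_gamma", "mu_alpha_phi"]])
print(res.change("R1").category, res.pattern("R1").pattern_id)
```

prints (posterior mean, SD, central 95% interval and R-hat per parameter)

```
                    mean        sd      q2.5     q97.5      rhat
alpha_p         0.868599  0.430055  0.107786  1.723228  1.005581
mu_alpha_gamma  0.667775  1.800569 -2.542935  4.244724  1.015574
mu_alpha_phi    0.259905  1.086213 -1.870980  2.424086  1.013096
increase concurrent_increase
```

— the night-detection intercept α_p (generating value 0.5) is recovered
with its 95% interval covering truth, while the colonization and
persistence hyper-means stay wide at this tiny scale; the final line is the
1999→2008 trend classification for region `R1` and its pattern of change
(here both old and new ponds increased).

The same pipeline runs from the shell:

```bash
dynocc simulate --preset tiny --seed 1 -o out/sim
dynocc fit -i out/sim -o out/fit --years 1999:2008 --seed 1
dynocc report -i out/fit -o out/report
```

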