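# Methods

## Model

One species at a time, the package fits a hierarchical dynamic occupancy
model to binary detection histories on a pond network whose composition
changes over the study period.  The latent occupancy state `z_it ∈ {0, 1}`
of site `i` in year `t` follows a two-state Markov chain with colonization
probability `γ_it` (unoccupied → occupied) and persistence probability
`φ_i` (occupied → occupied), both masked by a site-existence indicator
`E_it`: a pond that has not yet been constructed, or has been destroyed,
cannot be occupied.  First-year occupancy uses a region-specific initial
probability `ψ1`.  Detections are conditionally independent Bernoulli
draws given occupancy, so false positives are impossible by construction
(`y ≤ z`); a recorded detection at a site-year with `E = 0` is treated as a
data error, not a zero-likelihood event.

Link-scale structure:

- Detection: night intercept `alpha_p` plus a per-observer random offset
  `beta_obs ~ N(0, sigma_obs²)` for the two night visits, or a fixed day
  offset `beta_day` for the third visit.  Night visits with unrecorded
  observer identity are pooled into a single "unknown" observer level.
- Colonization: region intercepts `alpha_gamma[r] ~ N(mu, sigma²)`, a
  region-specific new-pond contrast `beta_new[r]`, and seven global slopes
  on standardized covariates.
- Persistence: region intercepts `alpha_phi[r]` and a region-specific
  new-pond contrast `delta_new[r]`.  Persistence carries no time index; it
  is constant per site.

Initial occupancy, colonization and persistence intercept hyper-means are
probabilities passed through the logit; wherever the model family is
written with `logit(·)` inside a Bernoulli, the inverse link is intended
and implemented.

## Covariates

The colonization design holds, in order: log surface area (log m², so the
slope acts multiplicatively on area), water-table fluctuation (binary, not
standardized), percent forest within 100 m, elevation (m a.s.l.), area of
large roads within 1 km (m²), structural connectivity, and pond age
(years since construction).  Connectivity is the negative-exponential
kernel `C_it = Σ_{j≠i} exp(−d_ij / s)` over sites existing in year `t`,
with distances in km and kernel scale `s = 1` km (a mean dispersal
distance; configurable, but no kernel estimation is attempted).
Connectivity of a nonexistent site is stored as 0 and never enters the
likelihood.

Age is defined only for new ponds with a known construction year.  Old
ponds and undated new ponds are imputed at the mean raw age of the dated
new ponds, which makes their standardized age exactly 0: the age slope is
identified from new ponds alone and is neutral elsewhere.  If a study
contains no dated new ponds at all, the age column is uninformative and is
kept at standardized 0 rather than rejected.

All continuous covariates are centred and scaled to unit sample variance
(n−1 convention), pooled over all existing site-years — not per region or
per year — because the slopes are global.  Site-level covariates other
than connectivity and age are static and broadcast over years.

## Existence bookkeeping

Where construction or destruction years are uncertain, the minimum
duration of existence is assumed: a site exists from the first year with
survey data (unknown construction) until the last year with survey data
(destroyed, year unknown).  A destruction year `D`, when known, is
exclusive: the site exists through `D − 1`.  The year range is fixed by
configuration (default 1999–2019, 21 occasions) so trajectories align
across species.  Regions with ≤ 10 sites having at least one detection of
the species are excluded from that species' model.

## Inference

The exact per-site marginal likelihood (latent states summed out) is
available through a two-state forward recursion over years, with scaled
normalization for numerical stability and inverse-logit values clamped to
[1e−12, 1 − 1e−12].  This marginal is the package's oracle-tested core:
the test suite checks it against exhaustive enumeration over all latent
sequences to 1e−10 in log space.

Two samplers target the same posterior:

- `latent_gibbs` (default): systematic-scan Gibbs updates of each `z_it`
  from its full conditional, alternating with random-walk Metropolis
  updates of every parameter block given `z` (each block's conditional
  likelihood is then a cheap Bernoulli sum).  Hyper-parameters are updated
  from their likelihood-free conditionals.
- `marginal_mh`: element-wise random-walk Metropolis on the
  forward-marginalized posterior; retained draws receive latent states by
  backward simulation.  It is slower per iteration and mixes more slowly
  through correlated posteriors, so it serves as a correctness cross-check
  at small scale rather than as the workhorse.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in only
and are frozen afterwards, preserving detailed balance for retained draws.
Initialization sets `z` to the observed-occupied state, intercepts near
probability 0.5 with jitter, and SDs near 0.5 (starting SDs at the middle
of their Uniform(0,10) support produces astronomically poor first
likelihoods; the prior itself is unchanged).  Non-finite posteriors at
initialization are retried up to 100 times.

Both samplers were validated three ways: prior recovery with empty data,
simulation-based calibration (rank-statistic uniformity over prior
replicates at reduced scale with a correspondingly narrowed prior — the
prior used to simulate is identical to the prior used to fit, as SBC
requires), and cross-sampler agreement on posterior means.  The
data-augmented sampler mixes far better whenever many site-years are
unsurveyed, because the latent states then carry most of the coupling;
the marginal sampler needs small data and long runs to converge, which is
how the cross-check test uses it.

Default MCMC settings mirror the study protocol (3 chains, 30,000 burn-in,
100,000 iterations thinned by 250 → 1,200 retained draws); tests and the
CLI default to heavily reduced settings (3 × 500 burn-in / 2,000
iterations / thin 10).

Convergence is summarized by the classic Brooks–Gelman–Rubin potential
scale reduction factor computed from between- and within-chain variances
(√(((n−1)/n · W + B/n) / W)); the CLI flags any R-hat > 1.1 with a
distinct soft-failure exit code so multi-species batch runs can continue.

## Posterior predictive checks

The discrepancy statistic is the count of sites with at least one
detection per region-year, compared between the observed data and
replicates simulated from each draw's latent states and detection
parameters.  Only "core" cells — region-years where at least 50% of the
region's existing sites were surveyed (configurable) — enter the check.
The Bayesian p-value is the fraction of draws whose replicate exceeds the
observation, with ties contributing 1/2 (counts are integers, so ties are
common).

## Derived trends

Metapopulation size is the number of occupied sites per region and year,
computed draw-wise from the posterior latent states (not plug-in
probabilities) and summarized by the mean and central 95% interval.  The
old/new decomposition is exact draw-wise: old + new = total in every draw.
Changes between the first and last study year are classified from the
posterior of the difference: increase if Pr(d > 0) ≥ 0.9, decline if
Pr(d < 0) ≥ 0.9, otherwise stable.  The threshold comparison is inclusive
and zero-difference draws count toward neither direction (the conservative
reading for integer counts).

Each metapopulation's (overall, old, new) category triple maps to one of
eight patterns of change — four increase patterns (concurrent increase,
new-driven increase, overcompensation of old-pond declines, old-driven
increase), two stable patterns (stable throughout, compensation of
old-pond declines by new ponds), and two decline patterns (insufficient
compensation, decline throughout).  Triples outside this taxonomy are
labelled `other` and logged rather than forced into a category.
Old-versus-new colonization and persistence probabilities are contrasted
at mean covariates (standardized X = 0) and aggregated across regions by
draw-wise averaging.

## Synthetic studies

The generator emulates the monitoring design end to end: per-region
landscapes with sites placed uniformly in squares sized to a target mean
nearest-neighbour spacing (default 0.6 km; regions offset 50 km so the
dispersal kernel never couples them), log-normal pond areas, Beta forest
cover, Gamma road area, Bernoulli(0.3) water fluctuation; staggered
construction of new ponds since 1991 with a configurable fraction of
unknown construction years (masked only in the analyst-facing table — the
simulation itself uses the true years); an optional small destruction
hazard; a rotating panel in which subregions are surveyed at intervals
drawn from Normal(3.8, 1.38) years, rounded and clipped at 1; and 2 night
visits plus (with probability 0.8, giving the target mean of 2.8 visits)
1 day visit, with observers drawn from a finite pool.

Three presets: `study_scale` (5 regions, 434 old + 422 new sites,
1999–2019, destruction hazard on) for smoke tests; `tiny` (2 regions,
30 sites, 10 years) for fast end-to-end runs; `recovery` (3 regions,
30 sites, 8 years, full annual panel, all visits made) for
parameter-recovery experiments.  Generating parameter values are fixed,
field-plausible choices — night detection ≈ 0.62 per visit, day detection
lower, colonization ≈ 0.2, persistence ≈ 0.75, new ponds colonized more
(mean contrast +0.6 logits) but persisting less (−0.5), moderate covariate
slopes (|β| ≤ 0.5), region and observer SDs 0.3 — with region effects and
observer offsets drawn from these hyper-distributions per replicate.

What the generator does not emulate: spatial clustering of ponds,
correlations between covariates, time-varying detection beyond the
observer effect, and the real network's exact panel membership.  Passing
tests therefore demonstrate that the pipeline recovers truth under the
model's own assumptions at the stated scales, not that the model is
correctly specified for any particular field data set.

## Problem sizes and numerical choices

The test suite and acceptance script run everything at reduced scale,
chosen to keep experiments informative while completing quickly on one
CPU: likelihood-oracle checks enumerate sites of up to 12 years; the
recovery experiment fits 20 replicates (8 in the acceptance script) of
30 sites × 8 years with 3 chains × 500 burn-in / 2,000 iterations / thin
10; the stationarity check uses 2,000 sites × 50 years; SBC uses 24 prior
replicates at 30 sites × 5 years with a narrowed prior (SD bound 1,
slope bound 2).  Quantile summaries use the default linear-interpolation
convention; reported category percentages are rounded to integers with
the exact fractions retained internally.

## Known limitations

- At small network sizes (a few dozen sites) the colonization submodel is
  weakly identified: with only ~100 unoccupied-to-occupied transition
  opportunities informing seven slopes plus intercepts, the likelihood has
  long flat ridges and binary covariates can quasi-separate, so under the
  vague Uniform(−10,10) slope priors the posterior legitimately places
  mass at large slope magnitudes and credible intervals can miss moderate
  generating values.  The same mechanism couples inflated occupancy with
  deflated detection.  This is visible in the recovery experiment's
  per-parameter coverage and disappears as the network grows; an oracle
  logistic regression given the true latent states shows the same
  magnitude inflation, so it is a property of the data scale, not of the
  sampler.  At full monitoring-program scale (hundreds of sites) the
  posterior is far better identified.
- Persistence has no covariates (by design of the model family);
  differences between ponds enter only through the new-pond contrast.
- The marginal sampler is impractical beyond a few dozen sites; it exists
  as an independent check, not an alternative workhorse.
- With sparse rotating panels, latent-state augmentation mixes slowly for
  the colonization slopes; the study-protocol iteration counts (100,000+)
  are genuinely needed at full scale.
- The CLI's `report` step reconstructs only the site metadata it needs
  from a fit directory; it assumes the fit directory is intact and
  unedited.
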