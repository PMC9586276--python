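"""MCMC samplers, convergence diagnostics and posterior predictive checks."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dynocc import (
    DynamicOccupancyModel,
    MCMCConfig,
    ModelParams,
    PriorConfig,
    SiteRegistry,
    assemble_species_data,
    build_design_matrix,
    gelman_rubin,
    make_fixture,
    posterior_predictive_check,
    retained_draw_count,
    run_mcmc,
)
from dynocc.mcmc import PosteriorDraws, rhat_table
from dynocc.simulate import (
    PRESETS,
    _existence_from_registry,
    generate_landscape,
    simulate_dynamics,
    simulate_surveys,
)


class TestRetainedDraws:
    @pytest.mark.parametrize(
        "chains,iters,thin,expected",
        [(3, 100_000, 250, 1200), (1, 1000, 10, 100), (2, 999, 100, 18)],
    )
    def test_arithmetic(self, chains, iters, thin, expected):
        cfg = MCMCConfig(n_chains=chains, n_iter=iters, thin=thin)
        assert retained_draw_count(cfg) == expected

    def test_invalid_thin(self):
        cfg = MCMCConfig()
        cfg.thin = 0
        with pytest.raises(ValueError, match="thin"):
            retained_draw_count(cfg)


class TestGelmanRubin:
    def test_hand_computed_two_by_four(self):
        """W = 5/3, B = 2, V-hat = 1.75 -> R-hat = sqrt(1.05)."""
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]])
        assert gelman_rubin(chains) == pytest.approx(np.sqrt(1.05), abs=1e-12)

    def test_same_distribution_long_chains(self):
        rng = np.random.default_rng(42)
        chains = rng.normal(size=(3, 5000))
        assert 0.99 <= gelman_rubin(chains) <= 1.02

    def test_gross_nonconvergence(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert gelman_rubin(chains) > 1.1 * 5

    def test_constant_chains_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            gelman_rubin(np.ones((2, 10)))

    def test_requires_enough_chains_and_draws(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((2, 3)))


class TestRunMCMC:
    def test_seed_reproducibility_bit_identical(self, tiny_fixture):
        cfg = MCMCConfig(n_chains=2, n_burnin=50, n_iter=100, thin=10, seed=7)
        a = run_mcmc(tiny_fixture.data, config=cfg)
        b = run_mcmc(tiny_fixture.data, config=cfg)
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.z, b.z)

    def test_draw_count_and_masking_invariants(self, tiny_fit, tiny_fixture):
        _, res = tiny_fit
        assert res.draws.n_draws == retained_draw_count(res.config)
        E = tiny_fixture.data.existence.E
        assert not (res.draws.z.astype(bool) & ~E[None]).any()

    def test_all_zero_detections_shrink_occupancy(self, tiny_fixture):
        data = tiny_fixture.data
        y0 = np.where(np.isnan(data.y), np.nan, 0.0)
        from dataclasses import replace

        data0 = replace(data, y=y0)
        cfg = MCMCConfig(n_chains=2, n_burnin=200, n_iter=600, thin=10, seed=3)
        draws = run_mcmc(data0, config=cfg)
        E = data0.existence.E
        occ = draws.z.astype(float).sum(axis=(1, 2)).mean() / E.sum()
        assert occ < 0.3  # well below the ~0.5 prior-implied occupancy

    def test_cross_sampler_agreement(self):
        """latent_gibbs and marginal_mh agree on posterior means within
        3 Monte-Carlo standard errors (small dataset where both mix well)."""
        prior = PriorConfig(sigma_max=1.0, slope_bound=2.0)
        config = PRESETS["tiny"]
        sites_all = generate_landscape(config, seed=100)
        keep = np.zeros(sites_all.n_sites, bool)
        keep[:8] = True
        sites = sites_all.subset(keep)
        years = np.arange(1999, 2002)
        E = _existence_from_registry(sites, years)
        design = build_design_matrix(sites, E)
        rng = np.random.default_rng(9)
        truth = _draw_from_prior(prior, sites.regions, ("oA", "oB", "oC"), rng)
        z = simulate_dynamics(sites, E, design, truth, seed=1)
        visits = simulate_surveys(z, np.ones(E.E.shape, bool), E, sites,
                                  truth, config, seed=2)
        data = assemble_species_data(sites, visits, species="sp", years=years)
        model = DynamicOccupancyModel(data)

        common = dict(n_chains=3, n_burnin=800, n_iter=4000, thin=5,
                      prior=prior)
        res_g = model.fit(MCMCConfig(sampler="latent_gibbs", seed=1, **common))
        res_m = model.fit(MCMCConfig(sampler="marginal_mh", seed=2, **common))
        for name in ("alpha_p", "mu_alpha_gamma", "mu_alpha_phi", "beta_day",
                     "beta[log_area]"):
            ga = res_g.draws.chains_of(name)
            ma = res_m.draws.chains_of(name)
            se = np.sqrt(_mcse(ga) ** 2 + _mcse(ma) ** 2)
            diff = abs(ga.mean() - ma.mean())
            assert diff < 3 * se, f"{name}: diff {diff:.3f} vs mcse {se:.3f}"

    def test_rhat_table_covers_all_parameters(self, tiny_fit):
        _, res = tiny_fit
        table = rhat_table(res.draws)
        assert set(table.index) == set(res.draws.param_names)
        assert np.isfinite(table.drop(index=[n for n in table.index
                                             if np.isnan(table[n])])).all()


class TestPosteriorPredictive:
    def _degenerate_setup(self):
        """5 sites, 3 years, everything occupied and detected with p = 1."""
        frame = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(5)],
            "region": "A", "is_new": False,
            "construction_year": pd.NA, "destruction_year": pd.NA,
            "destroyed": False,
            "x_km": np.arange(5.0), "y_km": 0.0,
            "elevation": np.linspace(300, 500, 5),
            "surface_area": np.linspace(50, 250, 5),
            "water_fluctuation": [0, 1, 0, 1, 0],
            "forest_pct_100m": np.linspace(10, 90, 5),
            "road_area_1km": np.linspace(0, 400, 5),
        })
        sites = SiteRegistry(frame)
        rows = []
        for sid in frame["site_id"]:
            for yr in (2000, 2001, 2002):
                for j, is_day in ((1, False), (2, False), (3, True)):
                    rows.append({"site_id": sid, "year": yr, "visit": j,
                                 "is_day": is_day,
                                 "observer_id": None if is_day else "o1",
                                 "detected": 1})
        data = assemble_species_data(sites, pd.DataFrame(rows), species="sp",
                                     years=range(2000, 2003))
        ref = ModelParams(regions=("A",), observers=data.observers)
        ref.alpha_p = 50.0
        ref.beta_day = 0.0
        names = ref.flat_names()
        D = 20
        params = np.tile(ref.to_vector(), (D, 1))
        z = np.ones((D, 5, 3), dtype=np.int8)
        draws = PosteriorDraws(
            param_names=names, params=params, z=z,
            chain=np.zeros(D, dtype=int), iteration=np.arange(D),
            regions=("A",), observers=data.observers,
            site_ids=sites.site_ids, years=data.years,
        )
        return draws, data

    def test_degenerate_ties_give_half(self):
        draws, data = self._degenerate_setup()
        out = posterior_predictive_check(draws, data)
        assert len(out) == 3  # fully surveyed region-years
        assert (out["p_value"] == 0.5).all()
        assert (out["rep_mean"] == out["observed"]).all()

    def test_inflated_detections_give_extreme_p_values(self):
        draws, data = self._degenerate_setup()
        # same all-ones data, but the model believes detection is poor
        k = draws.param_names.index("alpha_p")
        draws.params[:, k] = -2.0
        out = posterior_predictive_check(draws, data, seed=4)
        assert (out["p_value"] < 0.05).all()

    def test_calibration_on_model_simulated_data(self, tiny_fit):
        """Fit to data simulated from the model: p-values mostly moderate."""
        _, res = tiny_fit
        out = res.ppc(seed=8)
        frac_moderate = ((out["p_value"] >= 0.05)
                         & (out["p_value"] <= 0.95)).mean()
        assert frac_moderate >= 0.8


class TestSimulationBasedCalibration:
    def test_rank_statistic_uniformity(self):
        """Prior-draw -> simulate -> fit rank statistics are uniform
        (reduced scale, narrowed prior; chi-square at alpha = 0.01)."""
        from scipy.stats import chisquare

        prior = PriorConfig(sigma_max=1.0, slope_bound=2.0)
        config = PRESETS["tiny"]
        sites = generate_landscape(config, seed=100)
        years = np.arange(1999, 2004)
        E = _existence_from_registry(sites, years)
        design = build_design_matrix(sites, E)
        observers = ("oA", "oB", "oC")

        n_reps, n_bins = 24, 6
        ranks = []
        for rep in range(n_reps):
            rng = np.random.default_rng([500, rep])
            truth = _draw_from_prior(prior, sites.regions, observers, rng)
            z = simulate_dynamics(sites, E, design, truth,
                                  seed=int(rng.integers(2**31)))
            schedule = np.ones(E.E.shape, dtype=bool)
            visits = simulate_surveys(z, schedule, E, sites, truth, config,
                                      seed=int(rng.integers(2**31)))
            data = assemble_species_data(sites, visits, species="sp",
                                         years=years)
            cfg = MCMCConfig(n_chains=1, n_burnin=250, n_iter=750, thin=5,
                             seed=rep, prior=prior)
            draws = run_mcmc(data, config=cfg)
            col = draws.column("alpha_p")
            rank = int((col < truth.alpha_p).sum())
            ranks.append(min(rank * n_bins // (len(col) + 1), n_bins - 1))
        counts = np.bincount(ranks, minlength=n_bins)
        _, p = chisquare(counts)
        assert p > 0.01


def _mcse(chains: np.ndarray) -> float:
    """Monte-Carlo standard error of the pooled mean via per-chain
    autocorrelation (initial positive sequence estimator)."""
    m, n = chains.shape
    sd = chains.std(ddof=1)
    if sd == 0:
        return 0.0
    ess_total = 0.0
    for c in chains:
        x = c - c.mean()
        acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1))
        acf = acf / max(acf[0], 1e-300)
        tau = 1.0
        for lag in range(1, n // 2):
            if acf[lag] <= 0:
                break
            tau += 2.0 * acf[lag]
        ess_total += n / tau
    return float(sd / np.sqrt(max(ess_total, 1.0)))


def _draw_from_prior(prior, regions, observers, rng):
    """One draw from the (narrowed) prior, matching log_prior's support."""
    from scipy.special import logit

    R = len(regions)
    p = ModelParams(regions=regions, observers=observers)
    p.alpha_p = logit(rng.uniform())
    p.beta_day = rng.uniform(-prior.slope_bound, prior.slope_bound)
    p.sigma_obs = rng.uniform(0.0, prior.sigma_max)
    p.beta_obs = rng.normal(0, p.sigma_obs, len(observers))
    for mu_name, sd_name, vec_name, is_prob in (
        ("mu_psi1", "sigma_psi1", "alpha_psi1", True),
        ("mu_alpha_gamma", "sigma_alpha_gamma", "alpha_gamma", True),
        ("mu_beta_new", "sigma_beta_new", "beta_new", False),
        ("mu_alpha_phi", "sigma_alpha_phi", "alpha_phi", True),
        ("mu_delta_new", "sigma_delta_new", "delta_new", False),
    ):
        mu = (logit(rng.uniform()) if is_prob
              else rng.uniform(-prior.slope_bound, prior.slope_bound))
        sd = rng.uniform(0.0, prior.sigma_max)
        setattr(p, mu_name, mu)
        setattr(p, sd_name, sd)
        setattr(p, vec_name, rng.normal(mu, sd, R))
    p.beta = rng.uniform(-prior.slope_bound, prior.slope_bound, 7)
    return p
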