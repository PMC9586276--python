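"""Posterior sampling, convergence diagnostics and posterior predictive checks.

Two samplers target the same posterior:

``latent_gibbs`` (default)
    Alternates (a) single-site Gibbs updates of every latent occupancy state
    z_it from its full conditional given its temporal neighbours, the year's
    detections and the current parameters, and (b) random-walk Metropolis
    updates of the parameters on the logit/log scales.  Conditioning on z
    makes every parameter block's likelihood a cheap Bernoulli sum, so this
    is the workhorse sampler.

``marginal_mh``
    Random-walk Metropolis on the parameters only, using the exact
    forward-marginalized likelihood (latent states summed out); retained
    draws get latent states by backward simulation.  Slower per iteration
    but free of the latent-state augmentation, which makes it the natural
    cross-check for the Gibbs sampler.

Proposal scales adapt toward standard acceptance targets during burn-in and
are frozen afterwards, preserving detailed balance for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import log_expit

from .covariates import COVARIATE_NAMES, DesignMatrix, build_design_matrix
from .likelihood import (PackedData, forward_loglik, inv_logit, log_prior,
                         norm_logpdf)
from .params import ModelParams, PriorConfig
from .survey import SpeciesSurveyData

__all__ = [
    "MCMCConfig",
    "PosteriorDraws",
    "retained_draw_count",
    "run_mcmc",
    "ffbs_latent_states",
    "gelman_rubin",
    "rhat_table",
    "posterior_predictive_check",
]


@dataclass
class MCMCConfig:
    """MCMC run configuration.

    The default mirrors the study protocol: three chains, 30,000 burn-in
    iterations, 100,000 post-burn-in iterations thinned by 250 (1,200
    retained draws).  Tests and the CLI use much reduced settings.
    """

    n_chains: int = 3
    n_burnin: int = 30_000
    n_iter: int = 100_000
    thin: int = 250
    seed: int = 0
    sampler: str = "latent_gibbs"  # or "marginal_mh"
    prior: PriorConfig = field(default_factory=PriorConfig)
    init_retries: int = 100

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.sampler not in ("latent_gibbs", "marginal_mh"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def retained_draw_count(config: MCMCConfig) -> int:
    """Total retained posterior draws: n_chains * floor(n_iter / thin)."""
    if config.thin <= 0:
        raise ValueError("thin must be a positive integer")
    return config.n_chains * (config.n_iter // config.thin)


@dataclass
class PosteriorDraws:
    """Retained MCMC samples of parameters and latent occupancy states."""

    param_names: list[str]
    params: np.ndarray      # (n_draws, n_params)
    z: np.ndarray           # (n_draws, n_sites, n_years) int8
    chain: np.ndarray       # (n_draws,)
    iteration: np.ndarray   # (n_draws,) post-burn-in iteration index
    regions: tuple[str, ...]
    observers: tuple[str, ...]
    site_ids: np.ndarray
    years: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.params.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1

    def column(self, name: str) -> np.ndarray:
        return self.params[:, self.param_names.index(name)]

    def chains_of(self, name: str) -> np.ndarray:
        """Trace of one parameter reshaped (n_chains, draws_per_chain)."""
        col = self.column(name)
        return np.stack([col[self.chain == c] for c in range(self.n_chains)])

    def params_at(self, i: int) -> ModelParams:
        return ModelParams.from_vector(self.params[i], self.regions, self.observers)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=self.param_names)
        df.insert(0, "iteration", self.iteration)
        df.insert(0, "chain", self.chain)
        return df

    # -- persistence (plain text, round-trip exact) ----------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "draws.csv", index=False,
                               float_format="%.17g")
        d, s, t = np.nonzero(self.z)
        pd.DataFrame({"draw": d, "site": s, "year": t}).to_csv(
            directory / "z_draws.csv", index=False
        )
        meta = pd.Series(
            {
                "regions": "|".join(self.regions),
                "observers": "|".join(self.observers),
                "site_ids": "|".join(map(str, self.site_ids)),
                "years": "|".join(map(str, self.years)),
                "n_sites": str(len(self.site_ids)),
                "n_years": str(len(self.years)),
            }
        )
        meta.to_csv(directory / "draws_meta.csv", header=False)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        directory = Path(directory)
        df = pd.read_csv(directory / "draws.csv")
        meta = pd.read_csv(directory / "draws_meta.csv", header=None,
                           index_col=0, dtype=str)[1]
        n_sites, n_years = int(meta["n_sites"]), int(meta["n_years"])
        zl = pd.read_csv(directory / "z_draws.csv")
        z = np.zeros((len(df), n_sites, n_years), dtype=np.int8)
        z[zl["draw"], zl["site"], zl["year"]] = 1
        return cls(
            param_names=[c for c in df.columns if c not in ("chain", "iteration")],
            params=df.drop(columns=["chain", "iteration"]).to_numpy(),
            z=z,
            chain=df["chain"].to_numpy(),
            iteration=df["iteration"].to_numpy(),
            regions=tuple(meta["regions"].split("|")),
            observers=tuple(str(meta["observers"]).split("|")) if meta["observers"] else (),
            site_ids=np.array(meta["site_ids"].split("|")),
            years=np.array([int(y) for y in meta["years"].split("|")]),
        )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _bern_ll(y: np.ndarray, lin: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli log-likelihood on the logit scale."""
    return y * log_expit(lin) + (1.0 - y) * log_expit(-lin)


def _intercept_lp(x: float, prior: PriorConfig) -> float:
    if prior.intercept_prior == "uniform_prob":
        return float(log_expit(x) + log_expit(-x))
    return 0.0 if abs(x) <= prior.slope_bound else -np.inf


def _flat_lp(x: float, prior: PriorConfig) -> float:
    return 0.0 if abs(x) <= prior.slope_bound else -np.inf


def _sigma_lp(s: float, prior: PriorConfig) -> float:
    return 0.0 if 0.0 < s <= prior.sigma_max else -np.inf


def _init_params(packed: PackedData, rng: np.random.Generator) -> ModelParams:
    """Jittered midpoint start: intercepts near probability 0.5, small SDs."""
    R = len(packed.regions)
    p = ModelParams(regions=packed.regions, observers=packed.observers)
    p.alpha_p = 0.3 * rng.standard_normal()
    p.beta_day = 0.3 * rng.standard_normal()
    p.sigma_obs = 0.4 + 0.2 * rng.random()
    p.beta_obs = 0.1 * rng.standard_normal(len(packed.observers))
    for mu_name, sd_name, vec_name in (
        ("mu_psi1", "sigma_psi1", "alpha_psi1"),
        ("mu_alpha_gamma", "sigma_alpha_gamma", "alpha_gamma"),
        ("mu_beta_new", "sigma_beta_new", "beta_new"),
        ("mu_alpha_phi", "sigma_alpha_phi", "alpha_phi"),
        ("mu_delta_new", "sigma_delta_new", "delta_new"),
    ):
        mu = 0.3 * rng.standard_normal()
        setattr(p, mu_name, mu)
        setattr(p, sd_name, 0.4 + 0.2 * rng.random())
        setattr(p, vec_name, mu + 0.2 * rng.standard_normal(R))
    p.beta = 0.1 * rng.standard_normal(len(COVARIATE_NAMES))
    return p


# ---------------------------------------------------------------------------
# latent-Gibbs sampler
# ---------------------------------------------------------------------------

class _GibbsChain:
    """One chain of the latent-Gibbs sampler (internal)."""

    _TARGET = 0.44
    _ADAPT_EVERY = 50

    def __init__(self, packed: PackedData, prior: PriorConfig,
                 rng: np.random.Generator, params: ModelParams):
        self.d = packed
        self.prior = prior
        self.rng = rng
        self.p = params
        n, T = packed.n_sites, packed.n_years
        self.z = (packed.any_det & packed.E).astype(np.int8)
        self.xb = packed.X @ self.p.beta
        # per-region counts of sites existing in year 1
        R = len(packed.regions)
        self.R = R
        e0 = packed.E[:, 0]
        self.n1 = np.bincount(packed.region_idx[e0], minlength=R).astype(float)
        # proposal scales
        self.step = {
            name: 0.3 for name in (
                "alpha_p", "beta_day", "sigma_obs",
                "mu_psi1", "sigma_psi1", "mu_alpha_gamma", "sigma_alpha_gamma",
                "mu_beta_new", "sigma_beta_new", "mu_alpha_phi",
                "sigma_alpha_phi", "mu_delta_new", "sigma_delta_new",
            )
        }
        self.vstep = {
            "beta_obs": np.full(len(packed.observers), 0.4),
            "alpha_psi1": np.full(R, 0.4),
            "alpha_gamma": np.full(R, 0.4),
            "beta_new": np.full(R, 0.4),
            "alpha_phi": np.full(R, 0.4),
            "delta_new": np.full(R, 0.4),
            "beta": np.full(len(COVARIATE_NAMES), 0.3),
        }
        self.acc = {k: 0.0 for k in self.step}
        self.tries = {k: 0 for k in self.step}
        self.vacc = {k: np.zeros_like(v) for k, v in self.vstep.items()}
        self.vtries = {k: 0 for k in self.vstep}
        self._refresh_stats()

    # -- latent states ---------------------------------------------------
    def sweep_z(self):
        d, p, rng = self.d, self.p, self.rng
        n, T = d.n_sites, d.n_years
        e1 = np.exp(d.emission_log1(p))
        e0 = np.where(d.any_det, 0.0, 1.0)
        gam = inv_logit(
            (p.alpha_gamma[d.region_idx]
             + d.is_new * p.beta_new[d.region_idx])[:, None] + self.xb
        )
        phi = inv_logit(p.alpha_phi[d.region_idx]
                        + d.is_new * p.delta_new[d.region_idx])
        psi1 = inv_logit(p.alpha_psi1[d.region_idx])
        Ef = d.E.astype(float)
        z = self.z
        for t in range(T):
            if t == 0:
                pl1 = psi1 * Ef[:, 0]
            else:
                zprev = z[:, t - 1]
                pl1 = ((1 - zprev) * gam[:, t] + zprev * phi) * Ef[:, t]
            w1 = pl1 * e1[:, t]
            w0 = (1.0 - pl1) * e0[:, t]
            if t < T - 1:
                znext = z[:, t + 1]
                q1 = phi * Ef[:, t + 1]
                q0 = gam[:, t + 1] * Ef[:, t + 1]
                w1 = w1 * np.where(znext == 1, q1, 1.0 - q1)
                w0 = w0 * np.where(znext == 1, q0, 1.0 - q0)
            tot = w0 + w1
            pr1 = np.where(tot > 0, w1 / np.maximum(tot, 1e-300),
                           d.any_det[:, t].astype(float))
            z[:, t] = (rng.random(n) < pr1) & d.E[:, t]
        self._refresh_stats()

    def _refresh_stats(self):
        d, z = self.d, self.z
        zv = z[d.v_site, d.v_year] == 1
        self.vs_y = d.v_y[zv]
        self.vs_day = d.v_is_day[zv]
        self.vs_obs = d.v_obs[zv]
        e0 = d.E[:, 0]
        self.k1 = np.bincount(
            d.region_idx[e0], weights=z[e0, 0].astype(float), minlength=self.R
        )
        prev, cur, act = z[:, :-1], z[:, 1:], d.E[:, 1:]
        m0 = act & (prev == 0)
        m1 = act & (prev == 1)
        i0, t0 = np.nonzero(m0)
        self.g_i, self.g_t = i0, t0 + 1
        self.g_cur = cur[m0].astype(float)
        self.g_r = d.region_idx[i0]
        self.g_new = d.is_new[i0].astype(float)
        i1, _ = np.nonzero(m1)
        self.f_cur = cur[m1].astype(float)
        self.f_r = d.region_idx[i1]
        self.f_new = d.is_new[i1].astype(float)

    # -- generic MH helpers ---------------------------------------------
    def _mh(self, name, current, logpost):
        prop = current + self.step[name] * self.rng.standard_normal()
        lp0, lp1 = logpost(current), logpost(prop)
        self.tries[name] += 1
        if math.log(self.rng.random() + 1e-300) < lp1 - lp0:
            self.acc[name] += 1
            return prop
        return current

    def _mh_vector(self, name, current, grouped_ll, prior_lp):
        """Element-wise MH for a vector whose likelihood factorizes by element."""
        prop = current + self.vstep[name] * self.rng.standard_normal(len(current))
        dll = grouped_ll(prop) - grouped_ll(current)
        dpr = prior_lp(prop) - prior_lp(current)
        accept = np.log(self.rng.random(len(current)) + 1e-300) < dll + dpr
        self.vtries[name] += 1
        self.vacc[name] += accept
        return np.where(accept, prop, current), accept

    # -- detection block -------------------------------------------------
    def _det_ll(self, alpha_p, beta_day, beta_obs):
        if len(beta_obs):
            offs = np.where(self.vs_day, beta_day, beta_obs[self.vs_obs])
        else:
            offs = np.where(self.vs_day, beta_day, 0.0)
        return float(_bern_ll(self.vs_y, alpha_p + offs).sum())

    def update_detection(self):
        p, prior = self.p, self.prior
        p.alpha_p = self._mh(
            "alpha_p", p.alpha_p,
            lambda a: self._det_ll(a, p.beta_day, p.beta_obs) + _intercept_lp(a, prior),
        )
        day = self.vs_day
        y_day = self.vs_y[day]

        def day_ll(b):
            if not math.isfinite(_flat_lp(b, prior)):
                return -np.inf
            return float(_bern_ll(y_day, p.alpha_p + b).sum())

        p.beta_day = self._mh("beta_day", p.beta_day, day_ll)

        if len(p.beta_obs):
            yn = self.vs_y[~day]
            on = self.vs_obs[~day]
            K = len(p.beta_obs)

            def obs_grouped(b):
                ll = _bern_ll(yn, p.alpha_p + b[on])
                return np.bincount(on, weights=ll, minlength=K)

            def obs_prior(b):
                return norm_logpdf(b, 0.0, max(p.sigma_obs, 1e-12))

            p.beta_obs, _ = self._mh_vector("beta_obs", p.beta_obs,
                                            obs_grouped, obs_prior)

            def sig_ll(s):
                lp = _sigma_lp(s, prior)
                if not math.isfinite(lp):
                    return -np.inf
                return lp + float(norm_logpdf(p.beta_obs, 0.0, s).sum())

            p.sigma_obs = self._mh("sigma_obs", p.sigma_obs, sig_ll)

    # -- initial occupancy block ------------------------------------------
    def update_psi1(self):
        p, prior = self.p, self.prior
        k1, n1 = self.k1, self.n1

        def grouped(a):
            return k1 * log_expit(a) + (n1 - k1) * log_expit(-a)

        def prior_lp(a):
            return norm_logpdf(a, p.mu_psi1, max(p.sigma_psi1, 1e-12))

        p.alpha_psi1, _ = self._mh_vector("alpha_psi1", p.alpha_psi1,
                                          grouped, prior_lp)
        self._update_hypers("psi1", p.alpha_psi1, "mu_psi1", "sigma_psi1",
                            intercept=True)

    def _update_hypers(self, _tag, effects, mu_name, sd_name, intercept):
        p, prior = self.p, self.prior
        mu_prior = _intercept_lp if intercept else _flat_lp

        def mu_ll(mu):
            lp = mu_prior(mu, prior)
            if not math.isfinite(lp):
                return -np.inf
            return lp + float(norm_logpdf(effects, mu, max(getattr(p, sd_name), 1e-12)).sum())

        setattr(p, mu_name, self._mh(mu_name, getattr(p, mu_name), mu_ll))

        def sd_ll(s):
            lp = _sigma_lp(s, prior)
            if not math.isfinite(lp):
                return -np.inf
            return lp + float(norm_logpdf(effects, getattr(p, mu_name), s).sum())

        setattr(p, sd_name, self._mh(sd_name, getattr(p, sd_name), sd_ll))

    # -- colonization block -----------------------------------------------
    def update_gamma(self):
        p, prior, R = self.p, self.prior, self.R
        lin = (p.alpha_gamma[self.g_r] + self.g_new * p.beta_new[self.g_r]
               + self.xb[self.g_i, self.g_t])
        cur = self.g_cur

        def grouped_from_lin(lin_vals):
            ll = _bern_ll(cur, lin_vals)
            return np.bincount(self.g_r, weights=ll, minlength=R)

        def a_grouped(a):
            return grouped_from_lin(lin + (a - p.alpha_gamma)[self.g_r])

        def a_prior(a):
            return norm_logpdf(a, p.mu_alpha_gamma, max(p.sigma_alpha_gamma, 1e-12))

        new_alpha, acc = self._mh_vector("alpha_gamma", p.alpha_gamma,
                                         a_grouped, a_prior)
        lin = lin + (new_alpha - p.alpha_gamma)[self.g_r]
        p.alpha_gamma = new_alpha

        def b_grouped(b):
            return grouped_from_lin(lin + self.g_new * (b - p.beta_new)[self.g_r])

        def b_prior(b):
            return norm_logpdf(b, p.mu_beta_new, max(p.sigma_beta_new, 1e-12))

        new_bnew, acc = self._mh_vector("beta_new", p.beta_new,
                                        b_grouped, b_prior)
        lin = lin + self.g_new * (new_bnew - p.beta_new)[self.g_r]
        p.beta_new = new_bnew

        # covariate slopes (global, scalar RW each; one adaptation try per
        # sweep since every coordinate is proposed exactly once)
        ll_cur = float(_bern_ll(cur, lin).sum())
        self.vtries["beta"] += 1
        for k in range(len(p.beta)):
            xk = self.d.X[self.g_i, self.g_t, k]
            delta = self.vstep["beta"][k] * self.rng.standard_normal()
            bk_new = p.beta[k] + delta
            if math.isfinite(_flat_lp(bk_new, prior)):
                lin_new = lin + delta * xk
                ll_new = float(_bern_ll(cur, lin_new).sum())
                if math.log(self.rng.random() + 1e-300) < ll_new - ll_cur:
                    p.beta[k] = bk_new
                    self.xb += delta * self.d.X[:, :, k]
                    lin, ll_cur = lin_new, ll_new
                    self.vacc["beta"][k] += 1

        self._update_hypers("gamma", p.alpha_gamma, "mu_alpha_gamma",
                            "sigma_alpha_gamma", intercept=True)
        self._update_hypers("bnew", p.beta_new, "mu_beta_new",
                            "sigma_beta_new", intercept=False)

    # -- persistence block --------------------------------------------------
    def update_phi(self):
        p, R = self.p, self.R
        cur = self.f_cur

        def grouped(alpha, delta):
            lin = alpha[self.f_r] + self.f_new * delta[self.f_r]
            return np.bincount(self.f_r, weights=_bern_ll(cur, lin), minlength=R)

        def a_prior(a):
            return norm_logpdf(a, p.mu_alpha_phi, max(p.sigma_alpha_phi, 1e-12))

        p.alpha_phi, _ = self._mh_vector(
            "alpha_phi", p.alpha_phi, lambda a: grouped(a, p.delta_new), a_prior
        )

        def d_prior(dl):
            return norm_logpdf(dl, p.mu_delta_new, max(p.sigma_delta_new, 1e-12))

        p.delta_new, _ = self._mh_vector(
            "delta_new", p.delta_new, lambda dl: grouped(p.alpha_phi, dl), d_prior
        )
        self._update_hypers("phi", p.alpha_phi, "mu_alpha_phi",
                            "sigma_alpha_phi", intercept=True)
        self._update_hypers("dnew", p.delta_new, "mu_delta_new",
                            "sigma_delta_new", intercept=False)

    # -- iteration / adaptation -------------------------------------------
    def iterate(self, adapt: bool):
        self.sweep_z()
        self.update_detection()
        self.update_psi1()
        self.update_gamma()
        self.update_phi()
        if adapt:
            self._maybe_adapt()

    def _maybe_adapt(self):
        for name in self.step:
            if self.tries[name] >= self._ADAPT_EVERY:
                rate = self.acc[name] / self.tries[name]
                self.step[name] *= float(
                    np.clip(np.exp(1.5 * (rate - self._TARGET)), 0.5, 2.0)
                )
                self.acc[name] = 0.0
                self.tries[name] = 0
        for name in self.vstep:
            if self.vtries[name] >= self._ADAPT_EVERY:
                rate = self.vacc[name] / self.vtries[name]
                self.vstep[name] *= np.clip(
                    np.exp(1.5 * (rate - self._TARGET)), 0.5, 2.0
                )
                self.vacc[name][:] = 0.0
                self.vtries[name] = 0


# ---------------------------------------------------------------------------
# marginal Metropolis–Hastings sampler
# ---------------------------------------------------------------------------

class _MarginalChain:
    """Random-walk MH on the forward-marginalized posterior (internal).

    Every likelihood-bearing parameter gets its own scalar random-walk move
    with an individually adapted step — costlier per iteration than joint
    proposals (one forward pass per move) but it mixes far better through
    the correlated posterior, which is what the cross-sampler check needs.
    Hyper-parameters are updated from their likelihood-free conditionals.
    """

    _ADAPT_EVERY = 50

    def __init__(self, packed, prior, rng, params):
        self.d = packed
        self.prior = prior
        self.rng = rng
        self.p = params
        self._ll = float(forward_loglik(params, packed).sum())
        self.moves = [("alpha_p", None), ("beta_day", None)]
        self.moves += [("beta", k) for k in range(len(COVARIATE_NAMES))]
        for vec in ("beta_obs", "alpha_psi1", "alpha_gamma", "beta_new",
                    "alpha_phi", "delta_new"):
            self.moves += [(vec, i) for i in range(len(getattr(params, vec)))]
        self.step = {m: 0.3 for m in self.moves}
        self.acc = {m: 0.0 for m in self.moves}
        self.tries = {m: 0 for m in self.moves}

    def _param_prior(self, p):
        return log_prior(p, self.prior)

    def _try_move(self, move):
        attr, idx = move
        prop = self.p.copy()
        delta = self.step[move] * self.rng.standard_normal()
        if idx is None:
            setattr(prop, attr, getattr(prop, attr) + delta)
        else:
            getattr(prop, attr)[idx] += delta
        self.tries[move] += 1
        lp_prop = self._param_prior(prop)
        if not math.isfinite(lp_prop):
            return
        ll_prop = float(forward_loglik(prop, self.d).sum())
        lp_cur = self._param_prior(self.p)
        if math.log(self.rng.random() + 1e-300) < (ll_prop + lp_prop) - (self._ll + lp_cur):
            self.p = prop
            self._ll = ll_prop
            self.acc[move] += 1

    def iterate(self, adapt: bool):
        for move in self.moves:
            self._try_move(move)
        # hyper-parameters: conditional on the effects, likelihood-free
        self._gibbs_hypers()
        if adapt:
            self._maybe_adapt()

    def _gibbs_hypers(self):
        p, prior, rng = self.p, self.prior, self.rng
        blocks = (
            ("alpha_psi1", "mu_psi1", "sigma_psi1", True),
            ("alpha_gamma", "mu_alpha_gamma", "sigma_alpha_gamma", True),
            ("beta_new", "mu_beta_new", "sigma_beta_new", False),
            ("alpha_phi", "mu_alpha_phi", "sigma_alpha_phi", True),
            ("delta_new", "mu_delta_new", "sigma_delta_new", False),
        )
        for vec_name, mu_name, sd_name, intercept in blocks:
            effects = getattr(p, vec_name)
            mu_prior = _intercept_lp if intercept else _flat_lp
            for par_name, other in ((mu_name, sd_name), (sd_name, mu_name)):
                cur = getattr(p, par_name)
                propv = cur + 0.3 * rng.standard_normal()
                if par_name.startswith("sigma"):
                    lp_p = _sigma_lp(propv, prior)
                    lp_c = _sigma_lp(cur, prior)
                    mu, s_p, s_c = getattr(p, other), propv, cur
                    if math.isfinite(lp_p):
                        d = (norm_logpdf(effects, mu, s_p).sum()
                             - norm_logpdf(effects, mu, max(s_c, 1e-12)).sum())
                        if math.log(rng.random() + 1e-300) < d + lp_p - lp_c:
                            setattr(p, par_name, propv)
                else:
                    lp_p = mu_prior(propv, prior)
                    lp_c = mu_prior(cur, prior)
                    s = max(getattr(p, other), 1e-12)
                    if math.isfinite(lp_p):
                        d = (norm_logpdf(effects, propv, s).sum()
                             - norm_logpdf(effects, cur, s).sum())
                        if math.log(rng.random() + 1e-300) < d + lp_p - lp_c:
                            setattr(p, par_name, propv)
        # sigma_obs given beta_obs
        if len(p.beta_obs):
            cur = p.sigma_obs
            propv = cur + 0.3 * rng.standard_normal()
            if math.isfinite(_sigma_lp(propv, prior)):
                d = (norm_logpdf(p.beta_obs, 0, propv).sum()
                     - norm_logpdf(p.beta_obs, 0, max(cur, 1e-12)).sum())
                if math.log(rng.random() + 1e-300) < d:
                    p.sigma_obs = propv

    def _maybe_adapt(self):
        for move in self.step:
            if self.tries[move] >= self._ADAPT_EVERY:
                rate = self.acc[move] / self.tries[move]
                self.step[move] *= float(
                    np.clip(np.exp(1.5 * (rate - 0.44)), 0.5, 2.0)
                )
                self.acc[move] = 0.0
                self.tries[move] = 0


def ffbs_latent_states(params: ModelParams, packed: PackedData,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw latent states from their joint posterior by backward simulation."""
    n, T = packed.n_sites, packed.n_years
    e1 = np.exp(packed.emission_log1(params))
    e0 = np.where(packed.any_det, 0.0, 1.0)
    gam = packed.gamma_matrix(params)
    phi = packed.phi_vector(params)
    psi1 = packed.psi1_vector(params)
    Ef = packed.E.astype(float)

    A1 = np.empty((n, T))
    p1 = psi1 * Ef[:, 0]
    a1 = p1 * e1[:, 0]
    a0 = (1 - p1) * e0[:, 0]
    s = np.maximum(a0 + a1, 1e-300)
    a1 /= s
    a0 = 1.0 - a1
    A1[:, 0] = a1
    for t in range(1, T):
        p01 = gam[:, t] * Ef[:, t]
        p11 = phi * Ef[:, t]
        b1 = (a0 * p01 + a1 * p11) * e1[:, t]
        b0 = (a0 * (1 - p01) + a1 * (1 - p11)) * e0[:, t]
        s = np.maximum(b0 + b1, 1e-300)
        a1 = b1 / s
        a0 = 1.0 - a1
        A1[:, t] = a1

    z = np.zeros((n, T), dtype=np.int8)
    z[:, T - 1] = rng.random(n) < A1[:, T - 1]
    for t in range(T - 2, -1, -1):
        p01 = gam[:, t + 1] * Ef[:, t + 1]
        p11 = phi * Ef[:, t + 1]
        zn = z[:, t + 1] == 1
        l1 = np.where(zn, p11, 1 - p11) * A1[:, t]
        l0 = np.where(zn, p01, 1 - p01) * (1 - A1[:, t])
        tot = np.maximum(l0 + l1, 1e-300)
        z[:, t] = rng.random(n) < l1 / tot
    z[~packed.E] = 0
    return z


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_mcmc(
    data: SpeciesSurveyData,
    design: DesignMatrix | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Sample the posterior of the dynamic occupancy model.

    Reproducible given ``config.seed``: identical data and configuration give
    bit-identical draw sequences.
    """
    config = config or MCMCConfig()
    if design is None:
        design = build_design_matrix(data.sites, data.existence)
    packed = PackedData.from_data(data, design)
    per_chain = config.n_iter // config.thin
    total = retained_draw_count(config)

    names = ModelParams(packed.regions, packed.observers).flat_names()
    params_out = np.empty((total, len(names)))
    z_out = np.empty((total, packed.n_sites, packed.n_years), dtype=np.int8)
    chain_out = np.empty(total, dtype=np.int64)
    iter_out = np.empty(total, dtype=np.int64)

    pos = 0
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        init = None
        for _ in range(config.init_retries):
            cand = _init_params(packed, rng)
            ll = float(forward_loglik(cand, packed).sum())
            if math.isfinite(ll) and math.isfinite(log_prior(cand, config.prior)):
                init = cand
                break
        if init is None:
            raise RuntimeError("non-finite posterior at initialization "
                               f"after {config.init_retries} retries")

        if config.sampler == "latent_gibbs":
            chain = _GibbsChain(packed, config.prior, rng, init)
        else:
            chain = _MarginalChain(packed, config.prior, rng, init)

        for _ in range(config.n_burnin):
            chain.iterate(adapt=True)
        for it in range(1, config.n_iter + 1):
            chain.iterate(adapt=False)
            if it % config.thin == 0 and pos < (c + 1) * per_chain:
                params_out[pos] = chain.p.to_vector()
                if config.sampler == "latent_gibbs":
                    z_out[pos] = chain.z
                else:
                    z_out[pos] = ffbs_latent_states(chain.p, packed, rng)
                chain_out[pos] = c
                iter_out[pos] = it
                pos += 1

    return PosteriorDraws(
        param_names=names,
        params=params_out,
        z=z_out,
        chain=chain_out,
        iteration=iter_out,
        regions=packed.regions,
        observers=packed.observers,
        site_ids=packed.site_ids,
        years=packed.years,
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor (Brooks–Gelman–Rubin).

    ``chains`` is (n_chains, n_draws).  R-hat = sqrt(V-hat / W) with
    V-hat the pooled posterior-variance estimate ((n-1)/n W + B/n).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = x.shape
    if n < 4:
        raise ValueError("need >= 4 draws per chain")
    W = float(x.var(axis=1, ddof=1).mean())
    if W == 0.0:
        raise ValueError("degenerate trace: zero within-chain variance")
    B = n * float(x.mean(axis=1).var(ddof=1))
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def rhat_table(draws: PosteriorDraws) -> pd.Series:
    """R-hat per parameter (NaN where the trace is degenerate)."""
    out = {}
    for name in draws.param_names:
        try:
            out[name] = gelman_rubin(draws.chains_of(name))
        except ValueError:
            out[name] = np.nan
    return pd.Series(out, name="rhat")


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------

def posterior_predictive_check(
    draws: PosteriorDraws,
    data: SpeciesSurveyData,
    design: DesignMatrix | None = None,
    min_frac_surveyed: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare observed vs replicated occupied-site counts per region-year.

    "Core-area survey years" are region-year cells where at least
    ``min_frac_surveyed`` of the region's existing sites were surveyed.  The
    discrepancy statistic is the count of sites with >= 1 detection; the
    Bayesian p-value is the fraction of draws whose replicate exceeds the
    observation, with ties contributing 1/2.
    """
    if design is None:
        design = build_design_matrix(data.sites, data.existence)
    packed = PackedData.from_data(data, design)
    rng = np.random.default_rng(seed)
    n, T = packed.n_sites, packed.n_years
    regions = packed.regions
    R = len(regions)

    exist_counts = np.zeros((R, T))
    surv_counts = np.zeros((R, T))
    obs_counts = np.zeros((R, T))
    np.add.at(exist_counts, (packed.region_idx[:, None].repeat(T, 1),
                             np.arange(T)[None].repeat(n, 0)),
              packed.E.astype(float))
    np.add.at(surv_counts, (packed.region_idx[:, None].repeat(T, 1),
                            np.arange(T)[None].repeat(n, 0)),
              packed.surveyed.astype(float))
    np.add.at(obs_counts, (packed.region_idx[:, None].repeat(T, 1),
                           np.arange(T)[None].repeat(n, 0)),
              packed.any_det.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        core = (surv_counts / np.maximum(exist_counts, 1)) >= min_frac_surveyed
    core &= exist_counts > 0

    D = draws.n_draws
    rep = np.zeros((D, R, T))
    for di in range(D):
        p = draws.params_at(di)
        lp = packed.visit_logit_p(p)
        z_visit = draws.z[di][packed.v_site, packed.v_year]
        y_rep = (rng.random(len(lp)) < inv_logit(lp)) & (z_visit == 1)
        rep_any = np.zeros((n, T), dtype=bool)
        np.logical_or.at(rep_any, (packed.v_site, packed.v_year), y_rep)
        np.add.at(rep[di], (packed.region_idx[:, None].repeat(T, 1),
                            np.arange(T)[None].repeat(n, 0)),
                  rep_any.astype(float))

    rows = []
    for r in range(R):
        for t in range(T):
            if not core[r, t]:
                continue
            reps = rep[:, r, t]
            obs = obs_counts[r, t]
            pval = float(np.mean(reps > obs) + 0.5 * np.mean(reps == obs))
            rows.append({
                "region": regions[r],
                "year": int(packed.years[t]),
                "observed": int(obs),
                "rep_mean": float(reps.mean()),
                "rep_lo": float(np.quantile(reps, 0.025)),
                "rep_hi": float(np.quantile(reps, 0.975)),
                "p_value": pval,
            })
    return pd.DataFrame(rows)
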