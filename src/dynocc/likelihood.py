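"""Model probabilities and the exact marginal likelihood over latent states.

The data model: latent occupancy ``z_it`` evolves as a two-state Markov chain
per site, masked by site existence ``E_it``:

    z_i1 ~ Bernoulli(psi1_region * E_i1)
    z_it ~ Bernoulli([(1 - z_{i,t-1}) * gamma_it + z_{i,t-1} * phi_i] * E_it)

and detections are conditionally independent Bernoulli given occupancy,
``y_ijt ~ Bernoulli(z_it * p_ijt)`` — false positives are structurally
impossible.  Because the chain has two states, the likelihood with latent
states summed out is available exactly by a forward recursion over years;
this is what :func:`site_log_marginal_likelihood` and
:func:`forward_loglik` compute (the MCMC samplers use it both for
marginal-space Metropolis updates and, combined with backward simulation,
to draw latent states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit, logit  # noqa: F401  (logit re-exported)

from .covariates import DesignMatrix
from .params import ModelParams, PriorConfig
from .survey import SpeciesSurveyData

__all__ = [
    "inv_logit",
    "detection_prob",
    "colonization_prob",
    "persistence_prob",
    "initial_occupancy_prob",
    "PackedData",
    "site_log_marginal_likelihood",
    "forward_loglik",
    "log_prior",
]

_EPS = 1e-12
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def norm_logpdf(x, loc=0.0, scale=1.0):
    """Normal log-density (plain formula; avoids scipy dispatch overhead
    in the samplers' inner loops)."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI


def inv_logit(x):
    """Inverse-logit clamped to [1e-12, 1 - 1e-12] for numerical safety."""
    return np.clip(expit(x), _EPS, 1.0 - _EPS)


def _region_idx(params: ModelParams, region: str) -> int:
    try:
        return params.regions.index(region)
    except ValueError:
        raise ValueError(f"unknown region {region!r}") from None


def detection_prob(params: ModelParams, is_day: bool, observer: str | None = None):
    """Per-visit detection probability.

    Night visits (j = 1, 2) use the night intercept plus the observer's
    random offset; the day visit (j = 3) uses the daytime offset instead.
    """
    if is_day:
        return float(inv_logit(params.alpha_p + params.beta_day))
    if observer is None:
        raise ValueError("night visits require an observer identity")
    k = params.observers.index(observer)
    return float(inv_logit(params.alpha_p + params.beta_obs[k]))


def colonization_prob(
    params: ModelParams, x_row: np.ndarray, region: str, is_new: bool
) -> float:
    """Colonization probability gamma_it for one site-year.

    ``x_row`` is the standardized covariate vector X_{.it}; the new-pond
    contrast enters only for new ponds.
    """
    r = _region_idx(params, region)
    lin = params.alpha_gamma[r] + float(np.dot(params.beta, x_row))
    if is_new:
        lin += params.beta_new[r]
    return float(inv_logit(lin))


def persistence_prob(params: ModelParams, region: str, is_new: bool) -> float:
    """Persistence probability phi_i (time-constant per site)."""
    r = _region_idx(params, region)
    return float(inv_logit(params.alpha_phi[r] + (params.delta_new[r] if is_new else 0.0)))


def initial_occupancy_prob(params: ModelParams, region: str) -> float:
    """First-year occupancy probability psi1 for an existing site."""
    return float(inv_logit(params.alpha_psi1[_region_idx(params, region)]))


# ---------------------------------------------------------------------------
# packed arrays for vectorized likelihood evaluation
# ---------------------------------------------------------------------------

@dataclass
class PackedData:
    """Dense arrays binding one species' surveys to its design matrix."""

    region_idx: np.ndarray  # (n,) int
    is_new: np.ndarray      # (n,) bool
    E: np.ndarray           # (n, T) bool
    X: np.ndarray           # (n, T, K)
    any_det: np.ndarray     # (n, T) bool — >=1 detection among that year's visits
    surveyed: np.ndarray    # (n, T) bool
    # long-format visits
    v_site: np.ndarray
    v_year: np.ndarray      # 0-based year index
    v_is_day: np.ndarray
    v_obs: np.ndarray       # observer index, -1 for day visits
    v_y: np.ndarray         # float 0/1
    n_observers: int
    regions: tuple[str, ...]
    observers: tuple[str, ...]
    years: np.ndarray
    site_ids: np.ndarray

    @classmethod
    def from_data(cls, data: SpeciesSurveyData, design: DesignMatrix) -> "PackedData":
        if not np.array_equal(design.site_ids, data.sites.site_ids):
            raise ValueError("design matrix and survey data index different sites")
        surveyed_visits = ~np.isnan(data.y)
        si, ji, ti = np.nonzero(surveyed_visits)
        return cls(
            region_idx=data.sites.region_index,
            is_new=data.sites.is_new,
            E=data.existence.E,
            X=design.X,
            any_det=np.nan_to_num(data.y, nan=0.0).sum(axis=1) > 0,
            surveyed=surveyed_visits.any(axis=1),
            v_site=si,
            v_year=ti,
            v_is_day=(ji == 2),
            v_obs=data.observer_idx[si, ji, ti],
            v_y=data.y[si, ji, ti],
            n_observers=len(data.observers),
            regions=data.sites.regions,
            observers=data.observers,
            years=data.years,
            site_ids=data.sites.site_ids,
        )

    @property
    def n_sites(self) -> int:
        return self.E.shape[0]

    @property
    def n_years(self) -> int:
        return self.E.shape[1]

    # -- per-parameter-set probability arrays ---------------------------
    def visit_logit_p(self, params: ModelParams) -> np.ndarray:
        offs = np.where(
            self.v_is_day,
            params.beta_day,
            params.beta_obs[self.v_obs] if self.n_observers else 0.0,
        )
        return params.alpha_p + offs

    def emission_log1(self, params: ModelParams) -> np.ndarray:
        """log Pr(visits in year t | z_it = 1), shape (n, T); 0 if unsurveyed."""
        lp = self.visit_logit_p(params)
        ll = self.v_y * log_expit(lp) + (1.0 - self.v_y) * log_expit(-lp)
        out = np.zeros((self.n_sites, self.n_years))
        np.add.at(out, (self.v_site, self.v_year), ll)
        return out

    def gamma_matrix(self, params: ModelParams) -> np.ndarray:
        lin = (
            params.alpha_gamma[self.region_idx]
            + self.is_new * params.beta_new[self.region_idx]
        )[:, None] + self.X @ params.beta
        return inv_logit(lin)

    def phi_vector(self, params: ModelParams) -> np.ndarray:
        return inv_logit(
            params.alpha_phi[self.region_idx]
            + self.is_new * params.delta_new[self.region_idx]
        )

    def psi1_vector(self, params: ModelParams) -> np.ndarray:
        return inv_logit(params.alpha_psi1[self.region_idx])


def forward_loglik(params: ModelParams, packed: PackedData) -> np.ndarray:
    """Exact per-site log marginal likelihood, latent states summed out.

    Two-state scaled forward recursion over years.  Detections at
    nonexistent site-years are rejected (false positives are impossible
    under the model, and a detection where E = 0 is a data error, not a
    zero-likelihood event).
    """
    if np.any(packed.any_det & ~packed.E):
        raise ValueError("detection recorded at a site-year where E = 0")

    n, T = packed.n_sites, packed.n_years
    e1 = np.exp(packed.emission_log1(params))
    e0 = np.where(packed.any_det, 0.0, 1.0)
    gam = packed.gamma_matrix(params)
    phi = packed.phi_vector(params)
    psi1 = packed.psi1_vector(params)
    Ef = packed.E.astype(float)

    p1 = psi1 * Ef[:, 0]
    a1 = p1 * e1[:, 0]
    a0 = (1.0 - p1) * e0[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = a0 + a1
        ll = np.where(s > 0, np.log(np.maximum(s, 1e-300)), -np.inf)
        a0, a1 = np.where(s > 0, a0 / s, 0.5), np.where(s > 0, a1 / s, 0.5)
        for t in range(1, T):
            p01 = gam[:, t] * Ef[:, t]
            p11 = phi * Ef[:, t]
            b1 = (a0 * p01 + a1 * p11) * e1[:, t]
            b0 = (a0 * (1.0 - p01) + a1 * (1.0 - p11)) * e0[:, t]
            s = b0 + b1
            ll += np.where(s > 0, np.log(np.maximum(s, 1e-300)), -np.inf)
            a0, a1 = np.where(s > 0, b0 / s, 0.5), np.where(s > 0, b1 / s, 0.5)
    return ll


def site_log_marginal_likelihood(
    params: ModelParams,
    y_site: np.ndarray,
    observer_idx_site: np.ndarray,
    E_site: np.ndarray,
    X_site: np.ndarray,
    region: str,
    is_new: bool,
) -> float:
    """Log marginal likelihood of one site's detection history.

    ``y_site`` is the (3, T) visit array with NaN for unmade visits,
    ``observer_idx_site`` the matching observer indices (-1 where none),
    ``E_site`` the (T,) existence vector and ``X_site`` the (T, K)
    standardized covariates.
    """
    y = np.asarray(y_site, dtype=float)[None]
    obs = np.asarray(observer_idx_site, dtype=np.int64)[None]
    surveyed = ~np.isnan(y)
    si, ji, ti = np.nonzero(surveyed)
    packed = PackedData(
        region_idx=np.array([_region_idx(params, region)]),
        is_new=np.array([bool(is_new)]),
        E=np.asarray(E_site, dtype=bool)[None],
        X=np.asarray(X_site, dtype=float)[None],
        any_det=np.nan_to_num(y, nan=0.0).sum(axis=1) > 0,
        surveyed=surveyed.any(axis=1),
        v_site=si,
        v_year=ti,
        v_is_day=(ji == 2),
        v_obs=obs[si, ji, ti],
        v_y=y[si, ji, ti],
        n_observers=len(params.observers),
        regions=params.regions,
        observers=params.observers,
        years=np.arange(y.shape[2]),
        site_ids=np.array(["site"]),
    )
    return float(forward_loglik(params, packed)[0])


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _logistic_logpdf(x: float) -> float:
    # density of logit(U), U ~ Uniform(0,1): the standard logistic
    return float(log_expit(x) + log_expit(-x))


def log_prior(params: ModelParams, prior: PriorConfig | None = None) -> float:
    """Joint log prior density; -inf outside the support.

    Probability-scale intercept means (alpha_p and the mu's of psi1, gamma,
    phi) get Uniform(0,1) on the probability scale by default; SDs get
    Uniform(0, sigma_max); slopes, the day offset and contrast means get
    Uniform(-slope_bound, slope_bound).  Region effects and observer offsets
    contribute their Normal hierarchical densities.
    """
    prior = prior or PriorConfig()
    lp = 0.0
    b = prior.slope_bound

    prob_means = (params.alpha_p, params.mu_psi1, params.mu_alpha_gamma,
                  params.mu_alpha_phi)
    if prior.intercept_prior == "uniform_prob":
        lp += sum(_logistic_logpdf(x) for x in prob_means)
    else:  # flat on the logit scale
        if any(abs(x) > b for x in prob_means):
            return -np.inf
        lp += len(prob_means) * -np.log(2 * b)

    flat = (params.beta_day, params.mu_beta_new, params.mu_delta_new,
            *params.beta)
    if any(abs(x) > b for x in flat):
        return -np.inf
    lp += len(flat) * -np.log(2 * b)

    sigmas = (params.sigma_obs, params.sigma_psi1, params.sigma_alpha_gamma,
              params.sigma_beta_new, params.sigma_alpha_phi, params.sigma_delta_new)
    if any(s <= 0 or s > prior.sigma_max for s in sigmas):
        return -np.inf
    lp += len(sigmas) * -np.log(prior.sigma_max)

    hier = (
        (params.alpha_psi1, params.mu_psi1, params.sigma_psi1),
        (params.alpha_gamma, params.mu_alpha_gamma, params.sigma_alpha_gamma),
        (params.beta_new, params.mu_beta_new, params.sigma_beta_new),
        (params.alpha_phi, params.mu_alpha_phi, params.sigma_alpha_phi),
        (params.delta_new, params.mu_delta_new, params.sigma_delta_new),
    )
    for vals, mu, sigma in hier:
        lp += float(norm_logpdf(vals, mu, sigma).sum())
    if len(params.observers):
        lp += float(norm_logpdf(params.beta_obs, 0.0, params.sigma_obs).sum())
    return float(lp)
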