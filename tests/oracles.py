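"""Independent oracles for tests: brute-force enumerations and closed forms.

Everything here deliberately avoids the package's computational paths:
probabilities come straight from scipy's expit, likelihoods from explicit
enumeration over all latent sequences, connectivity from a double loop.
"""

import itertools
import math

import numpy as np
from scipy.special import expit


def enum_site_loglik(params, y, obs_idx, E, X, region_pos, is_new):
    """Log marginal likelihood by exhaustive enumeration over z sequences.

    ``y``/``obs_idx`` are (3, T) with NaN / -1 for unmade visits; ``E`` is
    the (T,) existence vector, ``X`` the (T, K) covariates.  Feasible for
    T <= ~14.
    """
    T = len(E)
    psi1 = expit(params.alpha_psi1[region_pos])
    gamma = expit(
        params.alpha_gamma[region_pos]
        + (params.beta_new[region_pos] if is_new else 0.0)
        + X @ params.beta
    )
    phi = expit(
        params.alpha_phi[region_pos]
        + (params.delta_new[region_pos] if is_new else 0.0)
    )
    # per-visit detection probabilities
    p = np.full((3, T), np.nan)
    for j in range(3):
        for t in range(T):
            if np.isnan(y[j, t]):
                continue
            if j == 2:
                p[j, t] = expit(params.alpha_p + params.beta_day)
            else:
                p[j, t] = expit(params.alpha_p + params.beta_obs[obs_idx[j, t]])

    total = 0.0
    for bits in itertools.product((0, 1), repeat=T):
        pr = 1.0
        for t, zt in enumerate(bits):
            if t == 0:
                p_occ = psi1 * E[0]
            else:
                zp = bits[t - 1]
                p_occ = ((1 - zp) * gamma[t] + zp * phi) * E[t]
            pr *= p_occ if zt else 1.0 - p_occ
            if pr == 0.0:
                break
            for j in range(3):
                if np.isnan(y[j, t]):
                    continue
                pp = p[j, t] * zt
                pr *= pp if y[j, t] == 1 else 1.0 - pp
        total += pr
    return math.log(total) if total > 0 else -math.inf


def random_site_instance(rng, max_years=12, n_observers=3):
    """Random single-site instance (params + data) for likelihood tests."""
    from dynocc import ModelParams

    T = int(rng.integers(1, max_years + 1))
    start = int(rng.integers(0, T))
    end = int(rng.integers(start, T))
    E = np.zeros(T)
    E[start : end + 1] = 1.0

    y = np.full((3, T), np.nan)
    obs = np.full((3, T), -1, dtype=np.int64)
    for t in range(start, end + 1):
        if rng.random() < 0.75:  # surveyed year
            for j in range(3):
                if rng.random() < 0.8:
                    y[j, t] = float(rng.random() < 0.4)
                    if j < 2:
                        obs[j, t] = int(rng.integers(0, n_observers))
    X = rng.normal(0.0, 0.7, size=(T, 7))

    observers = tuple(f"o{k}" for k in range(n_observers))
    params = ModelParams(regions=("A", "B"), observers=observers)
    params.alpha_p = rng.normal(0, 1)
    params.beta_day = rng.normal(0, 1)
    params.sigma_obs = 0.5
    params.beta_obs = rng.normal(0, 0.5, n_observers)
    for name in ("alpha_psi1", "alpha_gamma", "beta_new", "alpha_phi", "delta_new"):
        setattr(params, name, rng.normal(0, 1.2, 2))
    params.beta = rng.normal(0, 0.5, 7)
    is_new = bool(rng.random() < 0.5)
    region_pos = int(rng.integers(0, 2))
    return params, y, obs, E, X, region_pos, is_new


def brute_force_connectivity(coords, existing, scale=1.0):
    """Double-loop connectivity for existing sites, zeros elsewhere."""
    n = len(coords)
    C = np.zeros(n)
    for i in range(n):
        if not existing[i]:
            continue
        for j in range(n):
            if j == i or not existing[j]:
                continue
            d = math.dist(coords[i], coords[j])
            C[i] += math.exp(-d / scale)
    return C
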