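"""Parameter containers for the hierarchical dynamic occupancy model.

Naming follows the field's conventional symbols: detection intercept
``alpha_p`` (night) with a daytime offset ``beta_day`` and observer random
effects ``beta_obs ~ N(0, sigma_obs^2)``; region-specific intercepts for
initial occupancy (``alpha_psi1``), colonization (``alpha_gamma``) and
persistence (``alpha_phi``), each with Normal hyperpriors; region-specific
new-pond contrasts ``beta_new`` (colonization) and ``delta_new``
(persistence); and seven global covariate slopes ``beta`` on colonization.
All linear predictors live on the logit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import COVARIATE_NAMES

__all__ = ["ModelParams", "PriorConfig"]


@dataclass
class PriorConfig:
    """Prior specification (vague by default).

    Probability-scale intercept means get Uniform(0,1) priors on the
    probability scale (``intercept_prior="uniform_prob"``, i.e. a standard
    logistic density on the logit scale); a flat-logit alternative bounds the
    logit in ``(-slope_bound, slope_bound)``.  Standard deviations get
    Uniform(0, ``sigma_max``); slopes, offsets and contrast means get
    Uniform(-``slope_bound``, ``slope_bound``) on the logit scale.
    """

    sigma_max: float = 10.0
    slope_bound: float = 10.0
    intercept_prior: str = "uniform_prob"  # or "flat_logit"

    def __post_init__(self):
        if self.intercept_prior not in ("uniform_prob", "flat_logit"):
            raise ValueError(f"unknown intercept_prior {self.intercept_prior!r}")


@dataclass
class ModelParams:
    """Every parameter of the model, on its sampling scale.

    Scalars are floats; region- and observer-level effects are 1-D arrays
    aligned with ``regions`` / ``observers``.
    """

    regions: tuple[str, ...]
    observers: tuple[str, ...]

    # detection
    alpha_p: float = 0.0
    beta_day: float = 0.0
    sigma_obs: float = 0.5
    beta_obs: np.ndarray = None

    # initial occupancy
    alpha_psi1: np.ndarray = None
    mu_psi1: float = 0.0
    sigma_psi1: float = 0.5

    # colonization
    alpha_gamma: np.ndarray = None
    mu_alpha_gamma: float = 0.0
    sigma_alpha_gamma: float = 0.5
    beta_new: np.ndarray = None
    mu_beta_new: float = 0.0
    sigma_beta_new: float = 0.5
    beta: np.ndarray = None  # slopes, order = COVARIATE_NAMES

    # persistence
    alpha_phi: np.ndarray = None
    mu_alpha_phi: float = 0.0
    sigma_alpha_phi: float = 0.5
    delta_new: np.ndarray = None
    mu_delta_new: float = 0.0
    sigma_delta_new: float = 0.5

    def __post_init__(self):
        R, K = len(self.regions), len(COVARIATE_NAMES)
        defaults = {
            "beta_obs": len(self.observers),
            "alpha_psi1": R,
            "alpha_gamma": R,
            "beta_new": R,
            "alpha_phi": R,
            "delta_new": R,
            "beta": K,
        }
        for name, size in defaults.items():
            v = getattr(self, name)
            v = np.zeros(size) if v is None else np.asarray(v, dtype=float).copy()
            if v.shape != (size,):
                raise ValueError(f"{name} must have shape ({size},), got {v.shape}")
            setattr(self, name, v)
        for name in ("sigma_obs", "sigma_psi1", "sigma_alpha_gamma",
                     "sigma_beta_new", "sigma_alpha_phi", "sigma_delta_new"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- flat serialization ---------------------------------------------
    _SCALARS = (
        "alpha_p", "beta_day", "sigma_obs",
        "mu_psi1", "sigma_psi1",
        "mu_alpha_gamma", "sigma_alpha_gamma",
        "mu_beta_new", "sigma_beta_new",
        "mu_alpha_phi", "sigma_alpha_phi",
        "mu_delta_new", "sigma_delta_new",
    )
    _REGION_VECS = ("alpha_psi1", "alpha_gamma", "beta_new", "alpha_phi", "delta_new")

    def flat_names(self, include_observers: bool = True) -> list[str]:
        names = list(self._SCALARS)
        for vec in self._REGION_VECS:
            names += [f"{vec}[{r}]" for r in self.regions]
        names += [f"beta[{c}]" for c in COVARIATE_NAMES]
        if include_observers:
            names += [f"beta_obs[{o}]" for o in self.observers]
        return names

    def to_vector(self, include_observers: bool = True) -> np.ndarray:
        parts = [np.array([getattr(self, s) for s in self._SCALARS])]
        parts += [getattr(self, vec) for vec in self._REGION_VECS]
        parts.append(self.beta)
        if include_observers:
            parts.append(self.beta_obs)
        return np.concatenate(parts)

    @classmethod
    def from_vector(
        cls,
        vec: np.ndarray,
        regions: tuple[str, ...],
        observers: tuple[str, ...],
    ) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        R, K = len(regions), len(COVARIATE_NAMES)
        out = cls(regions=tuple(regions), observers=tuple(observers))
        pos = len(cls._SCALARS)
        for i, s in enumerate(cls._SCALARS):
            setattr(out, s, float(vec[i]))
        for v in cls._REGION_VECS:
            setattr(out, v, vec[pos:pos + R].copy())
            pos += R
        out.beta = vec[pos:pos + K].copy()
        pos += K
        if pos < len(vec):
            out.beta_obs = vec[pos:pos + len(observers)].copy()
        return out

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_vector(), index=self.flat_names())

    def to_json(self, path) -> None:
        payload = {
            "regions": list(self.regions),
            "observers": list(self.observers),
            "params": {k: float(v) for k, v in self.to_series().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            payload = json.load(fh)
        regions = tuple(payload["regions"])
        observers = tuple(payload["observers"])
        ref = cls(regions=regions, observers=observers)
        vec = np.array([payload["params"][n] for n in ref.flat_names()])
        return cls.from_vector(vec, regions, observers)

    def copy(self) -> "ModelParams":
        return replace(self)
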