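"""Synthetic study generator: landscape, dynamics and rotating-panel surveys.

Generates complete synthetic monitoring studies with known parameters so
every pipeline stage can be tested end to end.  The default ("study_scale")
scenario emulates the real program's conditions: 5 regions holding 434 old +
422 new ponds, years 1999-2019, subregions surveyed on a rotating panel with
mean revisit period 3.8 y (SD 1.38), ~2.8 visits per survey year (two night
visits with observers drawn from a pool, one day visit), staggered pond
construction since 1991, and mean within-region nearest-neighbour pond
spacing in the several-hundred-metre range.

Smaller presets ("tiny", "recovery") keep the same structure at a scale
suitable for fast tests and parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .covariates import COVARIATE_NAMES, DesignMatrix, build_design_matrix
from .likelihood import PackedData, inv_logit
from .params import ModelParams
from .survey import (
    ExistenceMatrix,
    SiteRegistry,
    SpeciesSurveyData,
    assemble_species_data,
    build_existence,
)

__all__ = [
    "ScenarioConfig",
    "PRESETS",
    "default_true_params",
    "generate_landscape",
    "simulate_dynamics",
    "simulate_surveys",
    "make_fixture",
    "Fixture",
]


@dataclass
class ScenarioConfig:
    """Everything that defines a synthetic study."""

    name: str = "custom"
    region_names: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")
    old_sites_per_region: tuple[int, ...] = (131, 72, 149, 49, 33)
    new_sites_per_region: tuple[int, ...] = (198, 98, 79, 36, 11)
    year_range: tuple[int, int] = (1999, 2019)
    construction_year_range: tuple[int, int] = (1991, 2015)
    unknown_construction_frac: float = 0.14
    destruction_hazard: float = 0.0  # per site-year; off in CI presets
    # rotating panel
    n_subregions: int = 4
    survey_interval_mean: float = 3.8
    survey_interval_sd: float = 1.38
    p_third_visit: float = 0.8  # 2 night visits always; day visit with this prob
    observer_pool_size: int = 50
    # covariate distributions
    log_area_mean: float = 4.6  # log m^2 (~100 m^2 ponds)
    log_area_sd: float = 1.0
    forest_beta: tuple[float, float] = (2.0, 2.0)
    road_gamma: tuple[float, float] = (2.0, 5000.0)  # shape, scale (m^2)
    elevation_range: tuple[float, float] = (300.0, 700.0)
    fluctuation_rate: float = 0.3
    nn_spacing_km: float = 0.6  # target mean nearest-neighbour distance
    kernel_scale_km: float = 1.0

    def __post_init__(self):
        if self.year_range[1] <= self.year_range[0]:
            raise ValueError("year_range must span >= 2 years")
        for counts in (self.old_sites_per_region, self.new_sites_per_region):
            if len(counts) != len(self.region_names):
                raise ValueError("per-region site counts must match region_names")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


def default_true_params(
    regions: tuple[str, ...],
    observers: tuple[str, ...],
    rng: np.random.Generator,
) -> ModelParams:
    """Generating parameters for synthetic studies.

    Hyper-means and SDs are fixed, field-plausible values (night detection
    ~0.62, lower day detection, colonization ~0.2, persistence ~0.75, new
    ponds colonized more but persisting less); region effects and observer
    offsets are drawn from those hyperpriors with the supplied generator.
    """
    R = len(regions)
    p = ModelParams(regions=regions, observers=observers)
    p.alpha_p = 0.5
    p.beta_day = -1.0
    p.sigma_obs = 0.3
    p.beta_obs = rng.normal(0.0, p.sigma_obs, len(observers))
    p.mu_psi1, p.sigma_psi1 = -0.4, 0.3
    p.mu_alpha_gamma, p.sigma_alpha_gamma = -1.4, 0.3
    p.mu_beta_new, p.sigma_beta_new = 0.6, 0.3
    p.mu_alpha_phi, p.sigma_alpha_phi = 1.1, 0.3
    p.mu_delta_new, p.sigma_delta_new = -0.5, 0.3
    p.alpha_psi1 = rng.normal(p.mu_psi1, p.sigma_psi1, R)
    p.alpha_gamma = rng.normal(p.mu_alpha_gamma, p.sigma_alpha_gamma, R)
    p.beta_new = rng.normal(p.mu_beta_new, p.sigma_beta_new, R)
    p.alpha_phi = rng.normal(p.mu_alpha_phi, p.sigma_alpha_phi, R)
    p.delta_new = rng.normal(p.mu_delta_new, p.sigma_delta_new, R)
    p.beta = np.array([0.5, -0.3, 0.3, -0.2, -0.4, 0.4, 0.2])
    assert len(p.beta) == len(COVARIATE_NAMES)
    return p


def generate_landscape(config: ScenarioConfig, seed: int = 0) -> SiteRegistry:
    """Place ponds and draw their covariates and construction schedule.

    Sites are uniform in per-region squares sized so that the expected mean
    nearest-neighbour spacing matches ``config.nn_spacing_km`` (for n uniform
    points in a square of side L the mean NN distance is ~ L / (2 sqrt n)).
    Regions are offset 50 km apart, far beyond the dispersal kernel.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cy_lo, cy_hi = config.construction_year_range
    for r, region in enumerate(config.region_names):
        n_old = config.old_sites_per_region[r]
        n_new = config.new_sites_per_region[r]
        n = n_old + n_new
        side = 2.0 * config.nn_spacing_km * np.sqrt(max(n, 1))
        xy = rng.uniform(0.0, side, size=(n, 2))
        xy[:, 0] += 50.0 * r
        is_new = np.repeat([False, True], [n_old, n_new])
        cyears = np.full(n, np.nan)
        cyears[n_old:] = rng.integers(cy_lo, cy_hi + 1, size=n_new)

        dyears = np.full(n, np.nan)
        if config.destruction_hazard > 0:
            horizon = config.year_range[1] - config.year_range[0] + 1
            dead = rng.random(n) < 1 - (1 - config.destruction_hazard) ** horizon
            dyears[dead] = rng.integers(
                config.year_range[0] + 2, config.year_range[1] + 1, size=dead.sum()
            )
            # destruction must not precede construction
            bad = ~np.isnan(cyears) & ~np.isnan(dyears) & (dyears < cyears)
            dyears[bad] = np.nan

        for i in range(n):
            rows.append({
                "site_id": f"{region}-{i:04d}",
                "region": region,
                "is_new": bool(is_new[i]),
                "construction_year": (int(cyears[i]) if not np.isnan(cyears[i])
                                      else pd.NA),
                "destruction_year": (int(dyears[i]) if not np.isnan(dyears[i])
                                     else pd.NA),
                "destroyed": not np.isnan(dyears[i]),
                "x_km": xy[i, 0],
                "y_km": xy[i, 1],
                "elevation": rng.uniform(*config.elevation_range),
                "surface_area": float(np.exp(rng.normal(config.log_area_mean,
                                                        config.log_area_sd))),
                "water_fluctuation": int(rng.random() < config.fluctuation_rate),
                "forest_pct_100m": 100.0 * rng.beta(*config.forest_beta),
                "road_area_1km": rng.gamma(config.road_gamma[0],
                                           config.road_gamma[1]),
            })
    return SiteRegistry(pd.DataFrame(rows))


def _existence_from_registry(sites: SiteRegistry, years: np.ndarray) -> ExistenceMatrix:
    """True existence (construction/destruction known to the simulator)."""
    empty = pd.DataFrame({"site_id": [], "year": [], "visit": [], "is_day": []})
    return build_existence(sites, empty, years)


def simulate_dynamics(
    sites: SiteRegistry,
    E: ExistenceMatrix,
    X: DesignMatrix,
    params: ModelParams,
    seed: int = 0,
) -> np.ndarray:
    """Forward-simulate latent occupancy, with exact existence masking."""
    rng = np.random.default_rng(seed)
    r_idx = sites.region_index
    is_new = sites.is_new
    n, T = E.E.shape
    psi1 = inv_logit(params.alpha_psi1[r_idx])
    gam = inv_logit(
        (params.alpha_gamma[r_idx] + is_new * params.beta_new[r_idx])[:, None]
        + X.X @ params.beta
    )
    phi = inv_logit(params.alpha_phi[r_idx] + is_new * params.delta_new[r_idx])

    z = np.zeros((n, T), dtype=np.int8)
    z[:, 0] = (rng.random(n) < psi1) & E.E[:, 0]
    for t in range(1, T):
        p_occ = np.where(z[:, t - 1] == 1, phi, gam[:, t]) * E.E[:, t]
        z[:, t] = rng.random(n) < p_occ
    return z


def _survey_schedule(sites: SiteRegistry, config: ScenarioConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Rotating-panel schedule: (n_sites, n_years) bool, surveyed or not.

    Sites are grouped into subregions within each region; each subregion is
    surveyed in years spaced by draws from Normal(interval_mean, interval_sd)
    rounded and clipped to >= 1 year.
    """
    years = config.years
    T = len(years)
    n = sites.n_sites
    surveyed = np.zeros((n, T), dtype=bool)
    for region in sites.regions:
        in_region = np.flatnonzero(sites.frame["region"].to_numpy() == region)
        sub = rng.integers(0, config.n_subregions, size=len(in_region))
        for s in range(config.n_subregions):
            members = in_region[sub == s]
            if not len(members):
                continue
            t = int(rng.integers(0, max(int(round(config.survey_interval_mean)), 1)))
            while t < T:
                surveyed[members, t] = True
                gap = int(round(rng.normal(config.survey_interval_mean,
                                           config.survey_interval_sd)))
                t += max(gap, 1)
    return surveyed


def simulate_surveys(
    z: np.ndarray,
    schedule: np.ndarray,
    E: ExistenceMatrix,
    sites: SiteRegistry,
    params: ModelParams,
    config: ScenarioConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate visit records for the scheduled (site, year) pairs.

    Each surveyed pair gets two night visits (observers drawn from the pool)
    and, with probability ``p_third_visit``, the day visit.  Detections are
    Bernoulli(z * p): no false positives by construction.
    """
    rng = np.random.default_rng(seed)
    observers = params.observers
    years = E.years
    rows = []
    sched = schedule & E.E  # cannot survey a pond that does not exist
    si, ti = np.nonzero(sched)
    for i, t in zip(si, ti):
        visits = [1, 2] + ([3] if rng.random() < config.p_third_visit else [])
        for j in visits:
            is_day = j == 3
            if is_day:
                obs_id, lp = pd.NA, params.alpha_p + params.beta_day
            else:
                k = int(rng.integers(0, len(observers)))
                obs_id = observers[k]
                lp = params.alpha_p + params.beta_obs[k]
            p = float(inv_logit(lp))
            y = int(z[i, t] == 1 and rng.random() < p)
            rows.append({
                "site_id": sites.site_ids[i],
                "year": int(years[t]),
                "visit": j,
                "is_day": is_day,
                "observer_id": obs_id,
                "detected": y,
            })
    return pd.DataFrame(rows)


class Fixture(NamedTuple):
    """A packaged synthetic study with its generating truth."""

    data: SpeciesSurveyData
    design: DesignMatrix
    truth: ModelParams
    z_true: np.ndarray
    sites_df: pd.DataFrame
    visits_df: pd.DataFrame
    config: ScenarioConfig


PRESETS: dict[str, ScenarioConfig] = {
    "study_scale": ScenarioConfig(
        name="study_scale",
        destruction_hazard=0.004,
    ),
    "tiny": ScenarioConfig(
        name="tiny",
        region_names=("R1", "R2"),
        old_sites_per_region=(8, 7),
        new_sites_per_region=(8, 7),
        year_range=(1999, 2008),
        construction_year_range=(1999, 2005),
        unknown_construction_frac=0.0,
        n_subregions=2,
        survey_interval_mean=2.0,
        survey_interval_sd=1.0,
        observer_pool_size=6,
    ),
    "recovery": ScenarioConfig(
        name="recovery",
        region_names=("R1", "R2", "R3"),
        old_sites_per_region=(5, 5, 5),
        new_sites_per_region=(5, 5, 5),
        year_range=(1999, 2006),
        construction_year_range=(1999, 2003),
        unknown_construction_frac=0.0,
        n_subregions=1,
        survey_interval_mean=1.0,   # full panel: every site every year
        survey_interval_sd=0.0,
        p_third_visit=1.0,
        observer_pool_size=5,
    ),
}


def make_fixture(preset: str, seed: int = 0) -> Fixture:
    """Generate a complete synthetic study with known truth.

    Presets: ``tiny`` (fast end-to-end runs), ``recovery`` (30 sites x 8
    years, full panel, for parameter-recovery experiments), ``study_scale``
    (study-scale smoke tests).
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = PRESETS[preset]
    rng = np.random.default_rng([seed, 17])

    sites = generate_landscape(config, seed=int(rng.integers(2**31)))
    years = config.years
    E = _existence_from_registry(sites, years)
    design = build_design_matrix(sites, E, years, config.kernel_scale_km)
    observers = tuple(f"obs{k:03d}" for k in range(config.observer_pool_size))
    truth = default_true_params(sites.regions, observers,
                                np.random.default_rng(int(rng.integers(2**31))))
    z = simulate_dynamics(sites, E, design, truth,
                          seed=int(rng.integers(2**31)))
    schedule = _survey_schedule(sites, config, rng)
    visits = simulate_surveys(z, schedule, E, sites, truth, config,
                              seed=int(rng.integers(2**31)))

    # the analyst does not know every construction year: mask a fraction in
    # the site table handed to the pipeline (the truth above used them all)
    sites_df = sites.frame.copy()
    if config.unknown_construction_frac > 0:
        new_rows = np.flatnonzero(sites_df["is_new"].to_numpy())
        mask = new_rows[
            np.random.default_rng([seed, 23]).random(len(new_rows))
            < config.unknown_construction_frac
        ]
        sites_df.loc[mask, "construction_year"] = pd.NA
    sites_obs = SiteRegistry(sites_df)

    data = assemble_species_data(
        sites_obs, visits, species="synthetic_species", years=years
    )
    # the fitted observer set is whoever actually surveyed; align the truth
    fitted_obs = data.observers
    obs_map = {o: k for k, o in enumerate(observers)}
    truth_fit = truth.copy()
    truth_fit.observers = fitted_obs
    truth_fit.beta_obs = np.array([truth.beta_obs[obs_map[o]] for o in fitted_obs])
    return Fixture(data=data, design=design, truth=truth_fit, z_true=z,
                   sites_df=sites_df, visits_df=visits, config=config)
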