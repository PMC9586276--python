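"""The user-facing model object, statsmodels-style.

``DynamicOccupancyModel`` binds one species' survey data to its covariate
design; ``fit`` runs MCMC and returns a :class:`DynamicOccupancyResults`
carrying the posterior draws, diagnostics and the derived trend
functionals.

Example
-------
>>> from dynocc import make_fixture, DynamicOccupancyModel, MCMCConfig
>>> fx = make_fixture("tiny", seed=1)
>>> model = DynamicOccupancyModel(fx.data)
>>> res = model.fit(MCMCConfig(n_chains=3, n_burnin=300, n_iter=1000, thin=10))
>>> res.summary().head()  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import DesignMatrix, build_design_matrix
from .likelihood import PackedData, forward_loglik, log_prior
from .mcmc import (
    MCMCConfig,
    PosteriorDraws,
    posterior_predictive_check,
    rhat_table,
    run_mcmc,
)
from .params import ModelParams, PriorConfig
from .survey import (
    SiteRegistry,
    SpeciesSurveyData,
    apply_region_exclusion,
    assemble_species_data,
)
from .trends import (
    classify_change,
    colonization_persistence_contrast,
    metapop_trajectory,
    assign_pattern,
    trend_report,
)

__all__ = ["DynamicOccupancyModel", "DynamicOccupancyResults"]


class DynamicOccupancyModel:
    """Hierarchical dynamic occupancy model for one species.

    Parameters
    ----------
    data
        Assembled detection/nondetection data (after region exclusion).
    design
        Standardized covariate design; built from the data's site registry
        and existence matrix when omitted.
    kernel_scale_km
        Dispersal-kernel scale for connectivity (mean dispersal distance),
        used only when the design is built here.
    """

    def __init__(
        self,
        data: SpeciesSurveyData,
        design: DesignMatrix | None = None,
        kernel_scale_km: float = 1.0,
    ):
        self.data = data
        self.design = design or build_design_matrix(
            data.sites, data.existence, kernel_scale_km=kernel_scale_km
        )
        self.packed = PackedData.from_data(data, self.design)

    @classmethod
    def from_tables(
        cls,
        sites: SiteRegistry | pd.DataFrame,
        visits: pd.DataFrame,
        detections: pd.DataFrame | None = None,
        species: str = "species",
        years=None,
        exclude_sparse_regions: bool = True,
        kernel_scale_km: float = 1.0,
        truncate_extra_visits: bool = False,
    ) -> "DynamicOccupancyModel":
        """Build the model straight from the site/visit/detection tables."""
        if isinstance(sites, pd.DataFrame):
            sites = SiteRegistry(sites)
        data = assemble_species_data(
            sites, visits, detections, species=species, years=years,
            truncate_extra_visits=truncate_extra_visits,
        )
        if exclude_sparse_regions:
            data = apply_region_exclusion(data)
        return cls(data, kernel_scale_km=kernel_scale_km)

    # -- likelihood surface ----------------------------------------------
    def loglike(self, params: ModelParams) -> float:
        """Exact marginal log-likelihood (latent states summed out)."""
        return float(forward_loglik(params, self.packed).sum())

    def site_loglike(self, params: ModelParams) -> np.ndarray:
        return forward_loglik(params, self.packed)

    def logpost(self, params: ModelParams,
                prior: PriorConfig | None = None) -> float:
        return self.loglike(params) + log_prior(params, prior)

    def null_params(self) -> ModelParams:
        return ModelParams(self.packed.regions, self.packed.observers)

    # -- fitting -----------------------------------------------------------
    def fit(self, config: MCMCConfig | None = None, **kwargs) -> "DynamicOccupancyResults":
        """Run MCMC and wrap the draws in a results object.

        Keyword arguments override fields of :class:`MCMCConfig` (e.g.
        ``model.fit(n_iter=2000, thin=10, seed=3)``).
        """
        if config is None:
            config = MCMCConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword overrides, not both")
        draws = run_mcmc(self.data, self.design, config)
        return DynamicOccupancyResults(self, draws, config)


class DynamicOccupancyResults:
    """Posterior draws plus diagnostics and derived quantities."""

    def __init__(self, model: DynamicOccupancyModel, draws: PosteriorDraws,
                 config: MCMCConfig):
        self.model = model
        self.draws = draws
        self.config = config

    # -- summaries ---------------------------------------------------------
    def summary(self) -> pd.DataFrame:
        """Posterior mean, SD, central 95% interval and R-hat per parameter."""
        p = self.draws.params
        rhat = rhat_table(self.draws) if self.draws.n_chains >= 2 else np.nan
        out = pd.DataFrame(
            {
                "mean": p.mean(axis=0),
                "sd": p.std(axis=0, ddof=1),
                "q2.5": np.quantile(p, 0.025, axis=0),
                "q97.5": np.quantile(p, 0.975, axis=0),
            },
            index=self.draws.param_names,
        )
        out["rhat"] = rhat
        return out

    def rhat(self) -> pd.Series:
        return rhat_table(self.draws)

    def max_rhat(self) -> float:
        return float(self.rhat().max())

    def ppc(self, min_frac_surveyed: float = 0.5, seed: int = 0) -> pd.DataFrame:
        return posterior_predictive_check(
            self.draws, self.model.data, self.model.design,
            min_frac_surveyed=min_frac_surveyed, seed=seed,
        )

    # -- trend functionals -------------------------------------------------
    def trajectory(self, region: str, subset: str = "all"):
        return metapop_trajectory(self.draws, self.model.data, region, subset)

    def change(self, region: str, subset: str = "all",
               start_year: int | None = None, end_year: int | None = None,
               threshold: float = 0.90):
        years = list(self.model.data.years)
        i0 = 0 if start_year is None else years.index(start_year)
        i1 = len(years) - 1 if end_year is None else years.index(end_year)
        tr = self.trajectory(region, subset)
        return classify_change(tr.counts[:, i0], tr.counts[:, i1], threshold)

    def pattern(self, region: str, threshold: float = 0.90):
        return assign_pattern(
            self.change(region, "all", threshold=threshold),
            self.change(region, "old", threshold=threshold),
            self.change(region, "new", threshold=threshold),
        )

    def trend_report(self, start_year=None, end_year=None,
                     threshold: float = 0.90) -> pd.DataFrame:
        return trend_report(self.draws, self.model.data, start_year,
                            end_year, threshold)

    def contrast(self, region: str | None = None) -> pd.DataFrame:
        return colonization_persistence_contrast(self.draws, region)

    # -- plotting ----------------------------------------------------------
    def plot_trajectory(self, region: str, ax=None):
        """Plot the total trajectory split into old and new ponds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"all": "black", "old": "tab:blue", "new": "tab:red"}
        for subset, color in colors.items():
            tr = self.trajectory(region, subset)
            ax.plot(tr.years, tr.mean, color=color, label=subset)
            ax.fill_between(tr.years, tr.lo, tr.hi, color=color, alpha=0.15)
        ax.set_xlabel("year")
        ax.set_ylabel("occupied sites")
        ax.set_title(f"{self.model.data.species} — {region}")
        ax.legend()
        return ax

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        self.draws.save(directory)
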