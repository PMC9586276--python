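"""Reproducible simulation experiments: parameter recovery.

Generates replicate synthetic studies with known truth, fits each with the
same pipeline a real analysis would use, and tabulates credible-interval
coverage of the generating parameters.  Used by the test suite and the
acceptance script; also handy for sensitivity analyses at other scales.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .covariates import COVARIATE_NAMES
from .mcmc import MCMCConfig
from .model import DynamicOccupancyModel
from .simulate import make_fixture

__all__ = ["RECOVERY_PARAMETERS", "parameter_recovery", "coverage_table"]

#: parameters whose recovery the experiment tracks: the detection intercept,
#: the colonization and persistence hyper-means, and every covariate slope
RECOVERY_PARAMETERS = (
    "alpha_p",
    "mu_alpha_gamma",
    "mu_alpha_phi",
    *(f"beta[{c}]" for c in COVARIATE_NAMES),
)


def parameter_recovery(
    preset: str = "recovery",
    n_replicates: int = 20,
    seed: int = 0,
    mcmc: MCMCConfig | None = None,
    parameters: tuple[str, ...] = RECOVERY_PARAMETERS,
) -> pd.DataFrame:
    """Fit ``n_replicates`` synthetic studies and record 95% CI coverage.

    Each replicate draws a fresh landscape, region/observer effects and
    survey realization from the preset's generating distribution, then fits
    with the given (reduced) MCMC configuration.  Returns one row per
    replicate x parameter with the truth, the interval and a coverage flag.
    """
    mcmc = mcmc or MCMCConfig(n_chains=3, n_burnin=500, n_iter=2000, thin=10)
    rows = []
    for k in range(n_replicates):
        fx = make_fixture(preset, seed=seed + k)
        model = DynamicOccupancyModel(fx.data)
        res = model.fit(replace(mcmc, seed=seed + 100_000 + k))
        summary = res.summary()
        truth = fx.truth.to_series()
        for name in parameters:
            lo, hi = summary.loc[name, "q2.5"], summary.loc[name, "q97.5"]
            rows.append({
                "replicate": k,
                "parameter": name,
                "truth": truth[name],
                "lo": lo,
                "hi": hi,
                "covered": bool(lo <= truth[name] <= hi),
            })
    return pd.DataFrame(rows)


def coverage_table(recovery: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter coverage counts from a recovery experiment table."""
    out = (
        recovery.groupby("parameter")["covered"]
        .agg(["sum", "count"])
        .rename(columns={"sum": "covered", "count": "replicates"})
    )
    out["rate"] = out["covered"] / out["replicates"]
    return out.reset_index()
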