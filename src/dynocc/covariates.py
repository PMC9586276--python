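"""Time-varying design matrix for the colonization model.

Seven covariates enter the colonization linear predictor: log pond surface
area (m^2), water-table fluctuation (0/1), percent forest within 100 m,
elevation (m a.s.l.), area of large roads within 1 km (m^2), structural
connectivity, and pond age (years since construction, new ponds only).

Connectivity follows the metapopulation-theory kernel
``C_it = sum_{j != i} exp(-d_ij / s)`` over all sites existing in year t,
with pairwise Euclidean distances d_ij in km and kernel scale s defaulting
to a mean dispersal distance of 1 km.

All continuous covariates are centred and scaled to mean zero and unit
variance (sample SD, n-1) over the site-years used for fitting, i.e. pooled
over all existing site-years.  The binary fluctuation indicator is left 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .survey import ExistenceMatrix, SiteRegistry

__all__ = [
    "COVARIATE_NAMES",
    "DesignMatrix",
    "connectivity",
    "connectivity_matrix",
    "pond_age",
    "standardize",
    "build_design_matrix",
]

COVARIATE_NAMES = (
    "log_area",
    "water_fluctuation",
    "forest_pct",
    "elevation",
    "road_area",
    "connectivity",
    "age",
)

#: columns left on their natural 0/1 scale
_BINARY = frozenset({"water_fluctuation"})


def connectivity(
    coords_km: np.ndarray,
    E: ExistenceMatrix,
    t: int,
    kernel_scale_km: float = 1.0,
) -> np.ndarray:
    """Structural connectivity of every site in year ``t``.

    Returns ``C_i = sum_{j != i, E_jt = 1} exp(-d_ij / s)`` for existing
    sites; nonexistent sites get 0 (the value is never used downstream, being
    masked by E in the likelihood).  An isolated existing site has C = 0.
    """
    ti = E.year_index(t)
    return connectivity_matrix(coords_km, E, kernel_scale_km)[:, ti]


def connectivity_matrix(
    coords_km: np.ndarray,
    E: ExistenceMatrix,
    kernel_scale_km: float = 1.0,
) -> np.ndarray:
    """Connectivity of every site in every year, shape (n_sites, n_years)."""
    coords = np.asarray(coords_km, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("site coordinates must be finite")
    n = coords.shape[0]
    if n == 1:
        K = np.zeros((1, 1))
    else:
        K = squareform(np.exp(-pdist(coords) / kernel_scale_km))
    C = K @ E.E.astype(float)  # diagonal of K is 0, so j != i automatically
    C[~E.E] = 0.0
    return C


def pond_age(site: pd.Series, t: int) -> float:
    """Years since construction for a single (new, dated) pond in year t.

    Old ponds and new ponds of unknown construction year have no defined age;
    they are imputed at the mean raw age of new ponds inside
    :func:`build_design_matrix` (standardized value 0) and return NaN here.
    """
    cy = site["construction_year"]
    if not site["is_new"] or cy is pd.NA:
        return float("nan")
    if t < cy:
        raise ValueError(f"year {t} precedes construction year {int(cy)}")
    return float(t - cy)


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Centre and scale to mean 0, unit sample variance (n-1 convention).

    Returns ``(standardized, center, scale)`` so effects can be reported on
    natural scales.  Constant input has no scale and is rejected.
    """
    x = np.asarray(values, dtype=float)
    center = float(np.mean(x))
    scale = float(np.std(x, ddof=1))
    if scale == 0.0 or np.unique(x).size < 2:
        raise ValueError("zero variance covariate")
    return (x - center) / scale, center, scale


@dataclass(frozen=True)
class DesignMatrix:
    """Standardized covariate array ``X`` indexed (site, year, covariate).

    ``centers``/``scales`` hold the per-covariate standardization constants
    (NaN / 1 for the binary fluctuation column).  ``raw`` keeps the
    pre-standardization values for audit export.
    """

    X: np.ndarray  # (n_sites, n_years, 7)
    raw: np.ndarray
    names: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray
    site_ids: np.ndarray
    years: np.ndarray
    kernel_scale_km: float = 1.0

    @property
    def n_covariates(self) -> int:
        return len(self.names)

    def to_long_frame(self, E: ExistenceMatrix | None = None) -> pd.DataFrame:
        """Long-format audit table (site_id, year, covariate, raw, std)."""
        n, T, K = self.X.shape
        rows = {
            "site_id": np.repeat(self.site_ids, T * K),
            "year": np.tile(np.repeat(self.years, K), n),
            "covariate": np.tile(np.array(self.names), n * T),
            "raw_value": self.raw.ravel(),
            "std_value": self.X.ravel(),
        }
        df = pd.DataFrame(rows)
        if E is not None:
            df = df.loc[np.repeat(E.E.ravel(), K)].reset_index(drop=True)
        return df


def build_design_matrix(
    sites: SiteRegistry,
    E: ExistenceMatrix,
    years: np.ndarray | None = None,
    kernel_scale_km: float = 1.0,
) -> DesignMatrix:
    """Assemble and standardize the (site, year, covariate) design array.

    Surface area enters as log(m^2).  Connectivity is recomputed per year
    from the existence matrix.  Age is raw years since construction for dated
    new ponds and the mean raw new-pond age elsewhere, so its standardized
    value is 0 outside the new ponds that identify the slope.  Standardization
    is pooled over all site-years with E = 1.
    """
    years = E.years if years is None else np.asarray(years, dtype=np.int64)
    n, T = sites.n_sites, len(years)
    f = sites.frame

    raw = np.empty((n, T, len(COVARIATE_NAMES)))
    static = {
        "log_area": np.log(f["surface_area"].to_numpy(dtype=float)),
        "water_fluctuation": f["water_fluctuation"].to_numpy(dtype=float),
        "forest_pct": f["forest_pct_100m"].to_numpy(dtype=float),
        "elevation": f["elevation"].to_numpy(dtype=float),
        "road_area": f["road_area_1km"].to_numpy(dtype=float),
    }
    for k, name in enumerate(COVARIATE_NAMES):
        if name in static:
            raw[:, :, k] = static[name][:, None]
    raw[:, :, COVARIATE_NAMES.index("connectivity")] = connectivity_matrix(
        sites.coords_km, E, kernel_scale_km
    )

    # age: defined for dated new ponds; the rest imputed at the mean new-pond age
    k_age = COVARIATE_NAMES.index("age")
    cy = f["construction_year"].to_numpy(dtype=float, na_value=np.nan)
    dated_new = sites.is_new & ~np.isnan(cy)
    age = np.full((n, T), np.nan)
    age[dated_new] = years[None, :] - cy[dated_new, None]
    age[dated_new] = np.where(E.E[dated_new], age[dated_new], np.nan)
    defined = ~np.isnan(age) & E.E
    if defined.any():
        neutral = float(np.mean(age[defined]))
    else:
        neutral = 0.0
    age = np.where(np.isnan(age), neutral, age)
    raw[:, :, k_age] = age

    X = np.zeros_like(raw)
    centers = np.full(len(COVARIATE_NAMES), np.nan)
    scales = np.ones(len(COVARIATE_NAMES))
    mask = E.E  # pooled standardization population
    for k, name in enumerate(COVARIATE_NAMES):
        if name in _BINARY:
            X[:, :, k] = raw[:, :, k]
            continue
        col = raw[:, :, k]
        if name == "age" and np.unique(col[mask]).size < 2:
            # no dated new ponds: the age column is all-neutral and carries
            # no information; keep it at standardized 0 rather than erroring
            centers[k], scales[k] = float(col[mask].mean()) if mask.any() else 0.0, 1.0
            X[:, :, k] = col - centers[k]
            continue
        std_pop, centers[k], scales[k] = standardize(col[mask])
        X[:, :, k] = (col - centers[k]) / scales[k]
    X[~mask] = 0.0  # never used: masked by E in the likelihood

    return DesignMatrix(
        X=X,
        raw=raw,
        names=COVARIATE_NAMES,
        centers=centers,
        scales=scales,
        site_ids=sites.site_ids,
        years=years,
        kernel_scale_km=kernel_scale_km,
    )
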