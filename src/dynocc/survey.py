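"""Pond-network survey data: site registry, visit records, existence bookkeeping.

The monitoring design is a rotating panel: subregions of each region are
surveyed in some years and skipped in others, and every surveyed (site, year)
pair receives up to three visits -- two at night (``j = 1, 2``, each with an
observer identity) and one during the day (``j = 3``).  Sites enter and leave
the network through construction and destruction; where those years are
uncertain we conservatively assume the minimum duration of existence (a site
exists from the first, or until the last, year with survey data for it).

All tabular I/O is delimited text (CSV, UTF-8).  Empty cells encode unknown
values (e.g. unknown construction years).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRegistry",
    "ExistenceMatrix",
    "SpeciesSurveyData",
    "load_sites",
    "write_sites",
    "load_visits",
    "write_visits",
    "validate_visits",
    "build_existence",
    "assemble_species_data",
    "apply_region_exclusion",
    "SITE_COLUMNS",
    "VISIT_COLUMNS",
]

SITE_COLUMNS = (
    "site_id",
    "region",
    "is_new",
    "construction_year",
    "destruction_year",
    "destroyed",
    "x_km",
    "y_km",
    "elevation",
    "surface_area",
    "water_fluctuation",
    "forest_pct_100m",
    "road_area_1km",
)

VISIT_COLUMNS = ("site_id", "year", "visit", "is_day", "observer_id", "detected")

#: pooled level for night visits whose observer identity was not recorded
UNKNOWN_OBSERVER = "unknown"


class SurveyDataError(ValueError):
    """Raised for malformed or internally inconsistent survey tables."""


def _err(row, field_, msg) -> SurveyDataError:
    return SurveyDataError(f"site {row!r}, field {field_!r}: {msg}")


@dataclass(frozen=True)
class SiteRegistry:
    """Validated registry of ponds with their static attributes.

    Wraps a DataFrame with one row per site (columns :data:`SITE_COLUMNS`).
    ``is_new`` marks ponds constructed since 1991; old ponds have no
    construction year.  ``destroyed`` flags sites known to have been removed
    even when the destruction year itself is unknown.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "frame", self.frame.reset_index(drop=True))
        _validate_sites(self.frame)

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.frame)

    @property
    def site_ids(self) -> np.ndarray:
        return self.frame["site_id"].to_numpy()

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["region"].unique()))

    @property
    def region_index(self) -> np.ndarray:
        """Integer region index per site, following :attr:`regions` order."""
        lookup = {r: k for k, r in enumerate(self.regions)}
        return self.frame["region"].map(lookup).to_numpy(dtype=np.int64)

    @property
    def is_new(self) -> np.ndarray:
        return self.frame["is_new"].to_numpy(dtype=bool)

    @property
    def coords_km(self) -> np.ndarray:
        return self.frame[["x_km", "y_km"]].to_numpy(dtype=float)

    def index_of(self, site_ids: Iterable) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.site_ids)}
        try:
            return np.array([lookup[s] for s in site_ids], dtype=np.int64)
        except KeyError as exc:
            raise SurveyDataError(f"unknown site_id {exc.args[0]!r}") from exc

    def subset(self, mask: np.ndarray) -> "SiteRegistry":
        return SiteRegistry(self.frame.loc[np.asarray(mask, dtype=bool)])


def _validate_sites(df: pd.DataFrame) -> None:
    missing = set(SITE_COLUMNS) - {"destroyed"} - set(df.columns)
    if missing:
        raise SurveyDataError(f"site table missing columns: {sorted(missing)}")
    if "destroyed" not in df.columns:
        df["destroyed"] = df["destruction_year"].notna()

    dup = df["site_id"][df["site_id"].duplicated()]
    if len(dup):
        raise SurveyDataError(f"duplicate site_id(s): {sorted(set(dup))}")

    for col in ("construction_year", "destruction_year"):
        df[col] = pd.array(df[col], dtype="Int64")
    df["is_new"] = df["is_new"].astype(bool)
    df["destroyed"] = df["destroyed"].astype(bool)

    for _, row in df.iterrows():
        sid = row["site_id"]
        for c in ("x_km", "y_km", "elevation"):
            if not np.isfinite(row[c]):
                raise _err(sid, c, "must be finite")
        if not row["surface_area"] > 0:
            raise _err(sid, "surface_area", "must be > 0")
        if row["water_fluctuation"] not in (0, 1):
            raise _err(sid, "water_fluctuation", "must be 0/1")
        if not 0 <= row["forest_pct_100m"] <= 100:
            raise _err(sid, "forest_pct_100m", "must lie in [0, 100]")
        if row["road_area_1km"] < 0:
            raise _err(sid, "road_area_1km", "must be >= 0")
        cy, dy = row["construction_year"], row["destruction_year"]
        if row["is_new"]:
            if cy is not pd.NA and cy < 1991:
                raise _err(sid, "construction_year", "new sites are built >= 1991")
        elif cy is not pd.NA:
            raise _err(sid, "construction_year", "old sites must not have one")
        if cy is not pd.NA and dy is not pd.NA and dy < cy:
            raise _err(sid, "destruction_year", "precedes construction_year")
        if dy is not pd.NA and not row["destroyed"]:
            raise _err(sid, "destroyed", "destruction_year set but flag False")


def load_sites(path, format: str = "csv") -> SiteRegistry:
    """Read and validate a site table.  Empty cells encode unknown years."""
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown tabular dialect {format!r}")
    df = pd.read_csv(path, sep=sep)
    return SiteRegistry(df)


def write_sites(registry: SiteRegistry, path, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[format]
    registry.frame.to_csv(path, sep=sep, index=False)


def load_visits(path, format: str = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}[format]
    return pd.read_csv(path, sep=sep)


def write_visits(visits: pd.DataFrame, path, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[format]
    visits.to_csv(path, sep=sep, index=False)


def validate_visits(
    visits: pd.DataFrame,
    sites: SiteRegistry,
    truncate_extra_visits: bool = False,
) -> pd.DataFrame:
    """Validate (and optionally normalize) a visit table.

    The protocol indexes visits ``j in {1, 2, 3}`` with ``is_day`` true iff
    ``j = 3``.  Records beyond the protocol (j > 3) are rejected unless
    ``truncate_extra_visits`` keeps the first two night and the first day
    visit.  Night visits with missing observer identity are pooled into the
    :data:`UNKNOWN_OBSERVER` level.
    """
    v = visits.copy()
    required = {"site_id", "year", "visit", "is_day"}
    missing = required - set(v.columns)
    if missing:
        raise SurveyDataError(f"visit table missing columns: {sorted(missing)}")
    if "observer_id" not in v.columns:
        v["observer_id"] = pd.NA

    sites.index_of(v["site_id"].unique())  # raises on unknown sites
    v["is_day"] = v["is_day"].astype(bool)

    if (v["visit"] > 3).any() or (v["visit"] < 1).any():
        if not truncate_extra_visits:
            bad = v.loc[(v["visit"] > 3) | (v["visit"] < 1)].iloc[0]
            raise SurveyDataError(
                f"site {bad['site_id']!r}, year {bad['year']}: visit index "
                f"{bad['visit']} outside protocol (j in 1..3); "
                "set truncate_extra_visits=True to keep 2 night + 1 day visits"
            )
        v = _truncate_protocol(v)

    # counts per (site, year): duplicates or >3 visits violate the protocol
    dup = v.duplicated(subset=["site_id", "year", "visit"])
    if dup.any():
        bad = v.loc[dup].iloc[0]
        raise SurveyDataError(
            f"duplicate visit record for site {bad['site_id']!r}, "
            f"year {bad['year']}, j={bad['visit']}"
        )
    counts = v.groupby(["site_id", "year"]).size()
    if (counts > 3).any():
        sid, yr = counts.idxmax()
        raise SurveyDataError(f"site {sid!r}, year {yr}: more than 3 visits recorded")

    day_mismatch = v["is_day"] != (v["visit"] == 3)
    if day_mismatch.any():
        bad = v.loc[day_mismatch].iloc[0]
        raise SurveyDataError(
            f"site {bad['site_id']!r}, year {bad['year']}, j={bad['visit']}: "
            "day/night flag inconsistent with visit index (day iff j = 3)"
        )

    night = ~v["is_day"]
    v.loc[night, "observer_id"] = v.loc[night, "observer_id"].fillna(UNKNOWN_OBSERVER)

    if "detected" in v.columns and not v["detected"].isin((0, 1)).all():
        raise SurveyDataError("detected must be binary 0/1")
    return v


def _truncate_protocol(v: pd.DataFrame) -> pd.DataFrame:
    """Keep the first two night visits and the first day visit per (site, year)."""
    v = v.sort_values(["site_id", "year", "visit"], kind="stable")
    parts = []
    for (sid, yr), grp in v.groupby(["site_id", "year"], sort=False):
        nights = grp.loc[~grp["is_day"]].head(2).copy()
        nights["visit"] = range(1, len(nights) + 1)
        day = grp.loc[grp["is_day"]].head(1).copy()
        day["visit"] = 3
        parts.append(pd.concat([nights, day]))
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class ExistenceMatrix:
    """Binary site-by-year indicator that a pond physically exists.

    Existence is contiguous per site: once constructed a pond exists until
    (exclusive of) its destruction year.
    """

    E: np.ndarray  # (n_sites, n_years) bool
    years: np.ndarray  # ordered integer years
    site_ids: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "E", np.asarray(self.E, dtype=bool))
        object.__setattr__(self, "years", np.asarray(self.years, dtype=np.int64))
        for i in range(self.E.shape[0]):
            on = np.flatnonzero(self.E[i])
            if len(on) and not np.array_equal(on, np.arange(on[0], on[-1] + 1)):
                raise SurveyDataError(
                    f"site {self.site_ids[i]!r}: existence interval not contiguous"
                )

    def year_index(self, t: int) -> int:
        idx = np.flatnonzero(self.years == t)
        if not len(idx):
            raise ValueError(f"year {t} outside study range "
                             f"{self.years[0]}..{self.years[-1]}")
        return int(idx[0])


def build_existence(
    sites: SiteRegistry,
    visits: pd.DataFrame,
    years: Sequence[int],
) -> ExistenceMatrix:
    """Derive the site-existence matrix from construction records and surveys.

    A site exists from ``max(first study year, construction_year)`` through
    ``min(last study year, destruction_year - 1)`` (destruction year
    exclusive).  Unknown construction years (new sites) fall back to the first
    year with survey data; unknown destruction years of flagged-destroyed
    sites fall back to the last year with survey data — the minimum-duration
    convention.
    """
    years = np.asarray(sorted(years), dtype=np.int64)
    t0, t1 = int(years[0]), int(years[-1])
    n, T = sites.n_sites, len(years)

    first_visit = visits.groupby("site_id")["year"].min()
    last_visit = visits.groupby("site_id")["year"].max()

    E = np.zeros((n, T), dtype=bool)
    for i, row in sites.frame.iterrows():
        sid = row["site_id"]
        cy, dy = row["construction_year"], row["destruction_year"]
        if cy is not pd.NA and dy is not pd.NA:
            bad = visits.loc[
                (visits["site_id"] == sid)
                & ((visits["year"] < cy) | (visits["year"] >= dy))
            ]
            if len(bad):
                raise SurveyDataError(
                    f"site {sid!r}: survey in year {int(bad['year'].iloc[0])} "
                    f"outside existence interval [{cy}, {dy})"
                )
        if cy is not pd.NA:
            start = max(t0, int(cy))
        elif row["is_new"]:
            if sid not in first_visit.index:
                continue  # unknown construction, never surveyed: assume absent
            start = int(first_visit[sid])
        else:
            start = t0
        if dy is not pd.NA:
            end = min(t1, int(dy) - 1)
        elif row["destroyed"]:
            end = int(last_visit[sid]) if sid in last_visit.index else t0 - 1
        else:
            end = t1
        if end >= start:
            E[i, start - t0 : end - t0 + 1] = True

    # every surveyed (site, year) must fall inside the existence interval
    vi = sites.index_of(visits["site_id"])
    vt = visits["year"].to_numpy(dtype=np.int64) - t0
    in_range = (vt >= 0) & (vt < T)
    if not E[vi[in_range], vt[in_range]].all():
        k = np.flatnonzero(~E[vi[in_range], vt[in_range]])[0]
        raise SurveyDataError(
            f"site {visits['site_id'].iloc[k]!r}: survey recorded in a year "
            "the site does not exist"
        )
    return ExistenceMatrix(E=E, years=years, site_ids=sites.site_ids)


@dataclass(frozen=True)
class SpeciesSurveyData:
    """Detection/nondetection data for one species on the pond network.

    ``y`` is a dense ``(site, visit j, year)`` array with NaN for visits that
    did not happen (the rotating panel's structured missingness).
    ``observer_idx`` maps night visits into the observer pool (-1 where not
    applicable) and ``regions_included`` records the regions surviving the
    sparse-region exclusion rule.
    """

    species: str
    sites: SiteRegistry
    y: np.ndarray  # (n_sites, 3, n_years) float, NaN = not surveyed
    observer_idx: np.ndarray  # (n_sites, 3, n_years) int, -1 = none
    observers: tuple[str, ...]
    existence: ExistenceMatrix
    years: np.ndarray
    regions_included: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.regions_included:
            object.__setattr__(self, "regions_included", self.sites.regions)
        surveyed = ~np.isnan(self.y)
        if np.any(surveyed & ~self.existence.E[:, None, :]):
            raise SurveyDataError("visit recorded where the site does not exist")
        det = np.nan_to_num(self.y, nan=0.0).astype(bool)
        if np.any(det & ~surveyed):
            raise SurveyDataError("detection outside a recorded visit")

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites

    @property
    def n_years(self) -> int:
        return len(self.years)

    def detection_sites_per_region(self) -> dict[str, int]:
        """Count of sites with >= 1 detection (any year/visit), per region."""
        any_det = np.nan_to_num(self.y, nan=0.0).sum(axis=(1, 2)) > 0
        out = {r: 0 for r in self.sites.regions}
        for r, d in zip(self.sites.frame["region"], any_det):
            out[r] += int(d)
        return out


def assemble_species_data(
    sites: SiteRegistry,
    visits: pd.DataFrame,
    species_detections: pd.DataFrame | None = None,
    species: str = "species",
    years: Sequence[int] | None = None,
    truncate_extra_visits: bool = False,
) -> SpeciesSurveyData:
    """Assemble the dense detection array for one species.

    ``visits`` gives the survey structure (and, for single-species use, may
    carry a ``detected`` column directly).  ``species_detections`` is the
    long-format table ``(site_id, year, visit, species, detected)``.  The year
    range defaults to 1999–2019 so that trajectories align across species.
    """
    if years is None:
        years = range(1999, 2020)
    years = np.asarray(sorted(years), dtype=np.int64)

    v = validate_visits(visits, sites, truncate_extra_visits=truncate_extra_visits)
    if species_detections is not None:
        det = species_detections.loc[species_detections["species"] == species]
        v = v.drop(columns=["detected"], errors="ignore").merge(
            det[["site_id", "year", "visit", "detected"]],
            on=["site_id", "year", "visit"],
            how="left",
        )
        v["detected"] = v["detected"].fillna(0)
    if "detected" not in v.columns:
        raise SurveyDataError(
            "no detection data: pass species_detections or a 'detected' column"
        )

    E = build_existence(sites, v, years)
    n, T = sites.n_sites, len(years)
    y = np.full((n, 3, T), np.nan)
    obs_idx = np.full((n, 3, T), -1, dtype=np.int64)

    observers = tuple(
        sorted(v.loc[~v["is_day"], "observer_id"].dropna().astype(str).unique())
    )
    obs_lookup = {o: k for k, o in enumerate(observers)}

    si = sites.index_of(v["site_id"])
    ti = v["year"].to_numpy(dtype=np.int64) - years[0]
    keep = (ti >= 0) & (ti < T)
    ji = v["visit"].to_numpy(dtype=np.int64) - 1
    y[si[keep], ji[keep], ti[keep]] = v["detected"].to_numpy(dtype=float)[keep]
    night = keep & ~v["is_day"].to_numpy()
    obs_idx[si[night], ji[night], ti[night]] = np.array(
        [obs_lookup[str(o)] for o in v.loc[night, "observer_id"]], dtype=np.int64
    )

    return SpeciesSurveyData(
        species=species,
        sites=sites,
        y=y,
        observer_idx=obs_idx,
        observers=observers,
        existence=E,
        years=years,
    )


def apply_region_exclusion(data: SpeciesSurveyData, min_sites: int = 10) -> SpeciesSurveyData:
    """Drop regions with too few detection sites for this species.

    Regions with ``<= min_sites`` sites having at least one detection are
    excluded from modelling (default 10).  Idempotent.
    """
    counts = data.detection_sites_per_region()
    keep_regions = tuple(sorted(r for r, c in counts.items() if c > min_sites))
    if not keep_regions:
        raise SurveyDataError(f"no data for species {data.species!r}: "
                              "all regions excluded")
    if keep_regions == data.sites.regions:
        return replace(data, regions_included=keep_regions)

    mask = data.sites.frame["region"].isin(keep_regions).to_numpy()
    return SpeciesSurveyData(
        species=data.species,
        sites=data.sites.subset(mask),
        y=data.y[mask],
        observer_idx=data.observer_idx[mask],
        observers=data.observers,
        existence=ExistenceMatrix(
            E=data.existence.E[mask],
            years=data.existence.years,
            site_ids=data.sites.site_ids[mask],
        ),
        years=data.years,
        regions_included=keep_regions,
    )
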