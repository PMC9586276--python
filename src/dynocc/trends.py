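"""Posterior functionals: metapopulation trajectories and trend classification.

Metapopulation size is the number of occupied sites in a region in a year,
computed draw-wise from the posterior latent states (not from plug-in
probabilities).  Changes between a start and end year are classified as
increase / stable / decline from the posterior distribution of the
difference, with a certainty threshold (default 90%).  Each metapopulation's
overall change combines with the changes in its old- and new-pond subsets
into one of eight patterns of change describing how newly constructed ponds
contributed to the trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import inv_logit
from .mcmc import PosteriorDraws
from .survey import SpeciesSurveyData

__all__ = [
    "Trajectory",
    "ChangeClassification",
    "ChangePattern",
    "metapop_trajectory",
    "classify_change",
    "assign_pattern",
    "summarize_percentages",
    "colonization_persistence_contrast",
    "trend_report",
    "PATTERNS",
]

logger = logging.getLogger(__name__)

SUBSETS = ("all", "old", "new")
CATEGORIES = ("increase", "stable", "decline")


@dataclass(frozen=True)
class Trajectory:
    """Posterior summary of occupied-site counts over years for one subset."""

    region: str
    subset: str
    years: np.ndarray
    mean: np.ndarray
    lo: np.ndarray   # 2.5% quantile
    hi: np.ndarray   # 97.5% quantile
    counts: np.ndarray  # (n_draws, n_years) draw-wise counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": self.region,
            "subset": self.subset,
            "year": self.years,
            "mean": self.mean,
            "lo": self.lo,
            "hi": self.hi,
        })


@dataclass(frozen=True)
class ChangeClassification:
    """Sign-of-change classification of a metapopulation between two years."""

    category: str
    prob_increase: float
    prob_decline: float
    threshold: float = 0.90

    def __post_init__(self):
        assert self.category in CATEGORIES


@dataclass(frozen=True)
class ChangePattern:
    """Combination of overall / old-pond / new-pond changes."""

    overall: str
    old: str
    new: str
    pattern_id: str
    description: str


def _site_mask(data: SpeciesSurveyData, region: str, subset: str) -> np.ndarray:
    mask = data.sites.frame["region"].to_numpy() == region
    if subset == "old":
        mask &= ~data.sites.is_new
    elif subset == "new":
        mask &= data.sites.is_new
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    return mask


def metapop_trajectory(
    draws: PosteriorDraws,
    data: SpeciesSurveyData,
    region: str,
    subset: str = "all",
) -> Trajectory:
    """Draw-wise occupied-site counts for one region (optionally old/new only).

    An empty subset yields an all-zero trajectory.
    """
    if region not in data.sites.regions:
        raise ValueError(f"unknown region {region!r}")
    mask = _site_mask(data, region, subset)
    counts = draws.z[:, mask, :].sum(axis=1).astype(float)
    return Trajectory(
        region=region,
        subset=subset,
        years=draws.years.copy(),
        mean=counts.mean(axis=0),
        lo=np.quantile(counts, 0.025, axis=0),
        hi=np.quantile(counts, 0.975, axis=0),
        counts=counts,
    )


def classify_change(
    count_start: np.ndarray,
    count_end: np.ndarray,
    threshold: float = 0.90,
) -> ChangeClassification:
    """Classify the posterior difference (end - start) at a certainty threshold.

    ``increase`` iff Pr(d > 0) >= threshold, ``decline`` iff
    Pr(d < 0) >= threshold (inclusive comparisons), otherwise ``stable``.
    Zero-difference draws count toward neither direction.
    """
    start = np.asarray(count_start, dtype=float)
    end = np.asarray(count_end, dtype=float)
    if start.size == 0 or start.shape != end.shape:
        raise ValueError("need equal, nonzero numbers of draws")
    d = end - start
    p_inc = float(np.mean(d > 0))
    p_dec = float(np.mean(d < 0))
    if p_inc >= threshold:
        cat = "increase"
    elif p_dec >= threshold:
        cat = "decline"
    else:
        cat = "stable"
    return ChangeClassification(cat, p_inc, p_dec, threshold)


#: the eight patterns of change, keyed by (overall, old, new) categories
PATTERNS: dict[tuple[str, str, str], tuple[str, str]] = {
    ("increase", "increase", "increase"):
        ("concurrent_increase", "old and new ponds increase together"),
    ("increase", "stable", "increase"):
        ("new_driven_increase",
         "colonization of new ponds drives the increase; old ponds stable"),
    ("increase", "decline", "increase"):
        ("overcompensation",
         "new ponds overcompensate declines in old ponds"),
    ("increase", "increase", "stable"):
        ("old_driven_increase", "increase carried by old ponds"),
    ("stable", "stable", "stable"):
        ("stable_throughout", "no change overall nor in either pond subset"),
    ("stable", "decline", "increase"):
        ("compensation",
         "new ponds compensate declines in old ponds, keeping the total stable"),
    ("decline", "decline", "stable"):
        ("insufficient_compensation",
         "new ponds not colonized in sufficient numbers to compensate "
         "declines in old ponds"),
    ("decline", "decline", "decline"):
        ("decline_throughout", "old and new ponds both decline"),
}


def assign_pattern(
    overall: ChangeClassification,
    old: ChangeClassification,
    new: ChangeClassification,
) -> ChangePattern:
    """Map the (overall, old, new) category triple to a pattern of change.

    Triples outside the eight enumerated patterns are labelled ``other``
    and logged.
    """
    triple = (overall.category, old.category, new.category)
    if triple in PATTERNS:
        pid, desc = PATTERNS[triple]
    else:
        pid, desc = "other", "combination outside the eight enumerated patterns"
        logger.info("pattern triple %s not in the taxonomy; labelled 'other'",
                    triple)
    return ChangePattern(*triple, pattern_id=pid, description=desc)


def summarize_percentages(
    classifications: list[ChangeClassification],
) -> pd.DataFrame:
    """Counts and integer-rounded percentages per change category.

    Percentages are reported rounded to the nearest integer; the exact
    fractions stay available via counts / total.
    """
    if not classifications:
        raise ValueError("empty collection of classifications")
    total = len(classifications)
    rows = []
    for cat in CATEGORIES:
        count = sum(c.category == cat for c in classifications)
        rows.append({
            "category": cat,
            "count": count,
            "fraction": count / total,
            "percent": int(round(100.0 * count / total)),
        })
    out = pd.DataFrame(rows)
    out.attrs["total"] = total
    return out


def colonization_persistence_contrast(
    draws: PosteriorDraws,
    region: str | None = None,
) -> pd.DataFrame:
    """Posterior old-vs-new colonization and persistence probabilities.

    Evaluated at mean covariates (standardized X = 0).  With ``region=None``
    the regional probabilities are averaged draw-wise across modelled
    regions.
    """
    if region is not None:
        if region not in draws.regions:
            raise ValueError(f"unknown region {region!r}")
        sel = [draws.regions.index(region)]
    else:
        sel = list(range(len(draws.regions)))

    def stack(vec_name):
        return np.stack([draws.column(f"{vec_name}[{r}]")
                         for r in np.array(draws.regions)[sel]], axis=1)

    a_gam = stack("alpha_gamma")
    b_new = stack("beta_new")
    a_phi = stack("alpha_phi")
    d_new = stack("delta_new")

    quantities = {
        ("colonization", "old"): inv_logit(a_gam).mean(axis=1),
        ("colonization", "new"): inv_logit(a_gam + b_new).mean(axis=1),
        ("persistence", "old"): inv_logit(a_phi).mean(axis=1),
        ("persistence", "new"): inv_logit(a_phi + d_new).mean(axis=1),
    }
    rows = []
    for (process, group), vals in quantities.items():
        rows.append({
            "process": process,
            "group": group,
            "mean": float(vals.mean()),
            "lo": float(np.quantile(vals, 0.025)),
            "hi": float(np.quantile(vals, 0.975)),
        })
    return pd.DataFrame(rows)


def trend_report(
    draws: PosteriorDraws,
    data: SpeciesSurveyData,
    start_year: int | None = None,
    end_year: int | None = None,
    threshold: float = 0.90,
) -> pd.DataFrame:
    """Full per-region trend table: classification per subset plus pattern.

    One row per region x subset (all/old/new) with start/end posterior
    means and credible intervals, the change category and probabilities,
    and — on the ``all`` rows — the assigned pattern of change.
    """
    years = list(data.years)
    start_year = years[0] if start_year is None else start_year
    end_year = years[-1] if end_year is None else end_year
    i0, i1 = years.index(start_year), years.index(end_year)

    rows = []
    for region in data.sites.regions:
        cls = {}
        traj = {}
        for subset in SUBSETS:
            tr = metapop_trajectory(draws, data, region, subset)
            traj[subset] = tr
            cls[subset] = classify_change(tr.counts[:, i0], tr.counts[:, i1],
                                          threshold)
        pattern = assign_pattern(cls["all"], cls["old"], cls["new"])
        for subset in SUBSETS:
            tr, c = traj[subset], cls[subset]
            rows.append({
                "species": data.species,
                "region": region,
                "subset": subset,
                "start_year": start_year,
                "end_year": end_year,
                "start_mean": tr.mean[i0],
                "start_lo": tr.lo[i0],
                "start_hi": tr.hi[i0],
                "end_mean": tr.mean[i1],
                "end_lo": tr.lo[i1],
                "end_hi": tr.hi[i1],
                "category": c.category,
                "prob_increase": c.prob_increase,
                "prob_decline": c.prob_decline,
                "pattern_id": pattern.pattern_id if subset == "all" else "",
            })
    return pd.DataFrame(rows)
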