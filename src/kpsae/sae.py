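"""Small-area extrapolation of key-population proportions.

Region-level size estimates from surveyed ("on-sample") regions are turned
into proportions of a census denominator (survey-year population of the
matching sex, ages 18-49), imputed to every region either as a single
national mean (simple imputation) or as per-stratum means after a
median split on an auxiliary covariate (HIV prevalence or population
density), and finally multiplied by projected target-year denominators
(ages 15-49) to yield regional and national size estimates.  On-sample
regions also receive the imputed proportion at the extrapolation step, so
every region in a variant shares the same proportion (or stratum
proportion) — this is what makes regional estimates exactly proportional
to the projections.

The imputers follow the scikit-learn estimator protocol (``fit`` on
on-sample proportions, ``predict`` proportions for arbitrary regions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "VARIANTS",
    "DATA_MODES",
    "StratificationRule",
    "round_half_up",
    "proportions_from_estimates",
    "SimpleProportionImputer",
    "StratifiedProportionImputer",
    "simple_impute",
    "assign_strata",
    "stratified_impute",
    "extrapolate",
    "national_total",
    "compare_variants",
]

VARIANTS = ("simple", "stratified_hiv", "stratified_density")
DATA_MODES = ("pre_program", "post_program")


@dataclass(frozen=True)
class StratificationRule:
    """Median-split rule: value strictly greater than threshold -> high."""

    variable: str
    threshold: float
    high_if: str = "strictly greater than threshold"


def round_half_up(x: float) -> int:
    """Round a non-negative value half-up (28.5 -> 29)."""
    if x < 0:
        raise ValueError("sizes are non-negative")
    return int(math.floor(x + 0.5))


def _as_series(mapping, name="value") -> pd.Series:
    if isinstance(mapping, pd.Series):
        return mapping.astype(float)
    return pd.Series(dict(mapping), dtype=float, name=name)


def proportions_from_estimates(
    estimates,
    denominators,
    population: str = "",
    source: str = "consensus",
) -> pd.DataFrame:
    """Convert region-level size estimates to proportions of a denominator.

    ``estimates`` is either a region-indexed Series of sizes (one per
    region, e.g. consensus output — ``source="consensus"``) or a DataFrame
    with columns region_id and point carrying several method-level
    estimates per region (``source="all_estimates"``), in which case each
    method is converted separately and the per-region mean of the method
    proportions is returned, so every region contributes equally however
    many methods it has.  ``denominators`` is a region-indexed Series of
    survey-year census counts.
    """
    den = _as_series(denominators)
    if (den <= 0).any():
        bad = den.index[den <= 0][0]
        raise ValueError(f"non-positive denominator for region {bad!r}")
    if isinstance(estimates, pd.DataFrame):
        missing = set(estimates["region_id"]) - set(den.index)
        if missing:
            raise KeyError(f"missing denominator for regions {sorted(missing)}")
        per_method = estimates["point"].astype(float).to_numpy() / den.loc[
            estimates["region_id"]
        ].to_numpy()
        frame = pd.DataFrame(
            {"region_id": estimates["region_id"].to_numpy(), "proportion": per_method}
        )
        prop = frame.groupby("region_id", sort=True)["proportion"].mean()
    else:
        est = _as_series(estimates)
        missing = set(est.index) - set(den.index)
        if missing:
            raise KeyError(f"missing denominator for regions {sorted(missing)}")
        prop = (est / den.loc[est.index]).sort_index()
    if (prop >= 1).any():
        bad = prop.index[prop >= 1][0]
        raise ValueError(
            f"estimate >= denominator for region {bad!r}: proportion must be < 1"
        )
    if (prop <= 0).any():
        bad = prop.index[prop <= 0][0]
        raise ValueError(f"non-positive proportion for region {bad!r}")
    out = pd.DataFrame(
        {
            "region_id": prop.index,
            "population": population,
            "proportion": prop.to_numpy(),
            "source": source,
            "stratum": "none",
        }
    )
    return out.reset_index(drop=True)


class SimpleProportionImputer(BaseEstimator):
    """Impute one national proportion: the unweighted mean of the
    on-sample regional proportions, assigned to every region."""

    def fit(self, proportions, y=None) -> "SimpleProportionImputer":
        props = _as_series(proportions)
        if props.empty:
            raise ValueError("at least one on-sample proportion is required")
        self.mean_ = float(props.mean())
        self.n_onsample_ = int(props.size)
        return self

    def predict(self, regions) -> pd.Series:
        if not hasattr(self, "mean_"):
            raise ValueError("imputer is not fitted")
        idx = pd.Index(list(regions), name="region_id")
        return pd.Series(self.mean_, index=idx, name="proportion")


class StratifiedProportionImputer(BaseEstimator):
    """Impute per-stratum proportions after a median split.

    ``fit(X, y)`` takes on-sample region -> stratum labels (``X``) and the
    matching proportions (``y``); ``predict`` maps any region -> stratum
    labelling to proportions.  Any stratum that must be predicted needs at
    least one on-sample donor region.
    """

    def fit(self, strata, proportions) -> "StratifiedProportionImputer":
        s = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
        props = _as_series(proportions)
        if props.empty:
            raise ValueError("at least one on-sample proportion is required")
        missing = set(props.index) - set(s.index)
        if missing:
            raise KeyError(f"no stratum label for on-sample regions {sorted(missing)}")
        self.stratum_means_ = {
            str(level): float(props.loc[[r for r in props.index if s[r] == level]].mean())
            for level in sorted(s.loc[props.index].unique())
        }
        self.n_onsample_ = int(props.size)
        return self

    def predict(self, strata) -> pd.Series:
        if not hasattr(self, "stratum_means_"):
            raise ValueError("imputer is not fitted")
        s = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
        empty = sorted(set(map(str, s.unique())) - set(self.stratum_means_))
        if empty:
            raise ValueError(
                f"stratum {empty[0]!r} has off-sample regions but no on-sample donor"
            )
        out = s.map(self.stratum_means_).astype(float)
        out.index.name = "region_id"
        out.name = "proportion"
        return out


def simple_impute(onsample_proportions, all_regions) -> pd.Series:
    """Functional wrapper: mean on-sample proportion for every region."""
    return SimpleProportionImputer().fit(onsample_proportions).predict(all_regions)


def assign_strata(
    values, threshold: float | None = None, variable: str = ""
) -> tuple[StratificationRule, pd.Series]:
    """Median-split regions on a covariate.

    The threshold defaults to the median of the supplied values across all
    regions; values strictly greater than the threshold go to the ``high``
    stratum, ties and below to ``low`` (matching the reporting convention
    "less than or equal to median").
    """
    vals = _as_series(values)
    if vals.isna().any():
        bad = vals.index[vals.isna()][0]
        raise ValueError(f"missing covariate value for region {bad!r}")
    if threshold is None:
        if vals.size < 2:
            raise ValueError("need >= 2 regions to compute a median threshold")
        threshold = float(np.median(vals.to_numpy()))
    rule = StratificationRule(variable=variable, threshold=float(threshold))
    labels = pd.Series(
        np.where(vals.to_numpy() > rule.threshold, "high", "low"),
        index=vals.index,
        name="stratum",
    )
    return rule, labels


def stratified_impute(onsample_proportions, strata) -> pd.Series:
    """Functional wrapper: per-stratum mean proportion for every region."""
    s = pd.Series(dict(strata)) if not isinstance(strata, pd.Series) else strata
    imp = StratifiedProportionImputer().fit(s, onsample_proportions)
    return imp.predict(s)


def extrapolate(
    proportions,
    projections,
    population: str = "",
    variant: str = "simple",
    data_mode: str = "post_program",
) -> pd.DataFrame:
    """Apply regional proportions to target-year projections.

    estimate = round_half_up(proportion * projection), one row per region.
    """
    props = _as_series(proportions)
    proj = _as_series(projections)
    missing = set(props.index) - set(proj.index)
    if missing:
        raise KeyError(f"missing projection for regions {sorted(missing)}")
    rows = [
        {
            "region_id": rid,
            "population": population,
            "estimate": round_half_up(props[rid] * proj[rid]),
            "variant": variant,
            "data_mode": data_mode,
        }
        for rid in props.index
    ]
    return pd.DataFrame(rows).sort_values("region_id", kind="mergesort").reset_index(drop=True)


def national_total(results: pd.DataFrame) -> int:
    """Sum one variant/mode's regional estimates into a national total.

    Requires exactly one row per region (duplicates or an inconsistent
    variant/mode mix raise).
    """
    if results.empty:
        raise ValueError("no regional results to total")
    for col in ("variant", "data_mode", "population"):
        if col in results.columns and results[col].nunique() > 1:
            raise ValueError(f"mixed {col} values in national_total input")
    if results["region_id"].duplicated().any():
        dup = results.loc[results["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"duplicate region {dup!r} in national_total input")
    return int(results["estimate"].sum())


def compare_variants(pre: pd.DataFrame, post: pd.DataFrame) -> pd.DataFrame:
    """Merge matched pre-/post-program results and flag decreases.

    Both inputs must cover the same (region, population, variant) cells;
    the output carries estimate_pre, estimate_post, ratio (post/pre) and a
    ``decrease`` flag.
    """
    keys = ["region_id", "population", "variant"]
    a = pre[keys + ["estimate"]].rename(columns={"estimate": "estimate_pre"})
    b = post[keys + ["estimate"]].rename(columns={"estimate": "estimate_post"})
    merged = a.merge(b, on=keys, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", keys].to_dict("records")[0]
        raise ValueError(f"variant mismatch between pre and post results: {missing}")
    merged = merged.drop(columns="_merge")
    merged["ratio"] = merged["estimate_post"] / merged["estimate_pre"]
    merged["decrease"] = merged["ratio"] < 1
    return merged.sort_values(keys, kind="mergesort").reset_index(drop=True)
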