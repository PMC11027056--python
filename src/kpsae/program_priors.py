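"""Priors for population size elicited from routine HIV program data.

Quarterly counts of key-population members reached by services (reported
through DATIM- and KP-STAR-like systems) are compared across sources with a
two-sample t test, pooled, and reduced to four summary values — minimum,
maximum, median, and standard deviation.  The median and SD are moment-
matched to a log-normal distribution that serves as the prior belief about
population size in the consensus estimator; the min/max travel along as
plausibility bounds and trigger warnings, not truncation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import POPULATIONS, quarter_sort_key

__all__ = [
    "TTestResult",
    "PriorSummary",
    "LogNormalPrior",
    "compare_sources",
    "pool_and_summarize",
    "fit_lognormal_prior",
    "priors_by_region",
]


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t test between two sets of quarterly counts."""

    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class PriorSummary:
    """The four pooled-count summary values plus the number of quarters."""

    minimum: float
    maximum: float
    median: float
    sd: float
    n_quarters: int

    def __post_init__(self) -> None:
        if not (self.minimum <= self.median <= self.maximum):
            raise ValueError("require minimum <= median <= maximum")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior on population size.

    ``mu_log``/``sigma_log`` parameterize size ~ LogNormal(mu_log,
    sigma_log**2); ``support_min``/``support_max`` are the pooled count
    extremes carried as plausibility bounds.
    """

    mu_log: float
    sigma_log: float
    support_min: float | None = None
    support_max: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        med = math.exp(self.mu_log)
        if self.support_min is not None and self.support_max is not None:
            tol = 1e-9 * max(1.0, abs(med))  # exp/log round-trip slack
            if not (self.support_min - tol <= med <= self.support_max + tol):
                warnings.warn(
                    f"prior median {med:.1f} outside support "
                    f"[{self.support_min:g}, {self.support_max:g}]",
                    stacklevel=3,
                )

    @property
    def median(self) -> float:
        return math.exp(self.mu_log)


def compare_sources(
    counts_a, counts_b, log_scale: bool = False
) -> TTestResult:
    """Two-tailed two-sample Welch t test between two reporting systems.

    Tests whether the quarterly counts from two source systems share an
    underlying distribution before pooling.  Uses the unequal-variance
    (Welch) variant with Welch–Satterthwaite degrees of freedom.  With
    ``log_scale`` the test is run on natural-log counts (all counts must
    then be positive).
    """
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each source needs at least 2 quarterly counts")
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale test requires strictly positive counts")
        a, b = np.log(a), np.log(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError(
            "degenerate input: zero variance in both sources, t test undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _select(
    records: pd.DataFrame,
    population: str,
    quarter_range: tuple[str, str] | None,
    region_id: str | None = None,
) -> pd.DataFrame:
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    sel = records[records["population"] == population]
    if region_id is not None:
        sel = sel[sel["region_id"] == region_id]
    if quarter_range is not None:
        lo, hi = (quarter_sort_key(q) for q in quarter_range)
        keys = sel["fiscal_quarter"].map(quarter_sort_key)
        sel = sel[(keys >= lo) & (keys <= hi)]
    return sel


def pool_and_summarize(
    records: pd.DataFrame,
    population: str,
    quarter_range: tuple[str, str] | None = None,
    region_id: str | None = None,
) -> PriorSummary:
    """Pool quarterly counts across sources and compute the four summaries.

    Pooling is plain concatenation of the per-quarter counts from all
    source systems (quarters are treated as exchangeable observations).
    The SD is the sample SD (n-1 denominator); a single pooled count yields
    sd = 0 with a warning so single-quarter pilots still run.
    """
    sel = _select(records, population, quarter_range, region_id)
    if sel.empty:
        where = f"population {population!r}"
        if quarter_range:
            where += f", quarters {quarter_range[0]}..{quarter_range[1]}"
        if region_id:
            where += f", region {region_id!r}"
        raise ValueError(f"no program records for {where}")
    counts = sel["count"].astype(float).to_numpy()
    if counts.size == 1:
        warnings.warn("single pooled count: SD undefined, returning 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(counts.std(ddof=1))
    return PriorSummary(
        minimum=float(counts.min()),
        maximum=float(counts.max()),
        median=float(np.median(counts)),
        sd=sd,
        n_quarters=int(counts.size),
    )


def fit_lognormal_prior(summary: PriorSummary) -> LogNormalPrior:
    """Moment-match a log-normal prior to the pooled-count summary.

    The median fixes the log-scale location, mu = ln(median); the log-scale
    spread comes from matching the coefficient of variation,
    sigma^2 = ln(1 + (sd/median)^2).  sd = 0 gives a point-mass prior
    (sigma = 0), which the consensus estimator refuses — widen upstream.
    """
    if summary.median <= 0:
        raise ValueError("prior median must be > 0 to fit a log-normal")
    mu = math.log(summary.median)
    cv = summary.sd / summary.median
    sigma = math.sqrt(math.log1p(cv * cv))
    return LogNormalPrior(
        mu_log=mu,
        sigma_log=sigma,
        support_min=summary.minimum,
        support_max=summary.maximum,
    )


def priors_by_region(
    records: pd.DataFrame,
    population: str,
    quarter_range: tuple[str, str] | None = None,
) -> dict[str, LogNormalPrior]:
    """Fit one log-normal prior per region carrying regional program counts."""
    sel = _select(records, population, quarter_range)
    sel = sel[sel["region_id"].notna()]
    out: dict[str, LogNormalPrior] = {}
    for rid in sorted(sel["region_id"].unique()):
        out[rid] = fit_lognormal_prior(
            pool_and_summarize(records, population, quarter_range, region_id=rid)
        )
    return out
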