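"""Bayesian triangulation of multiple direct size estimates.

Each estimation method yields a point estimate and 95% CI for one region.
On the natural-log scale every input is treated as a Gaussian observation
of the true log size: its mean is ln(point), its SD is recovered from the
CI half-width, and its precision is down-weighted by a confidence weight
reflecting the method's rigor (SS-PSE highest, wisdom of the crowds
lowest).  An optional log-normal prior elicited from program data enters
as one more Gaussian term.  The posterior is conjugate normal-normal:
posterior precision is the sum of the weighted input precisions plus the
prior precision, and the posterior mean is the precision-weighted average.
Mapping back through exp gives a single consensus estimate with a 95%
credible interval.

A rank-sensitivity harness re-runs the triangulation under alternative
confidence-weight vectors and order permutations to quantify how much the
consensus point depends on the numeric weights versus the rank order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core_data import METHOD_RANKING
from .program_priors import LogNormalPrior

__all__ = [
    "Z_95",
    "ConfidenceScheme",
    "ConsensusResult",
    "default_confidence_scheme",
    "ci_to_log_sd",
    "BayesianConsensus",
    "consensus_estimate",
    "consensus_by_group",
    "rank_sensitivity",
]

#: normal quantile used for all 95% intervals on the log scale
Z_95 = 1.96


@dataclass(frozen=True)
class ConfidenceScheme:
    """Method -> confidence weight in (0, 1].

    A scheme is *order preserving* when its weights are non-increasing
    along the canonical method ranking; :func:`default_confidence_scheme`
    builds the linear-decay scheme (8 - rank)/7.
    """

    weights: Mapping[str, float]
    label: str = "custom"

    def __post_init__(self) -> None:
        for m, w in self.weights.items():
            if m not in METHOD_RANKING:
                raise ValueError(f"unknown method {m!r}")
            if not (0 < w <= 1):
                raise ValueError(f"weight for {m!r} must be in (0, 1], got {w}")

    def __getitem__(self, method: str) -> float:
        return self.weights[method]

    def is_order_preserving(self) -> bool:
        ws = [self.weights[m] for m in METHOD_RANKING if m in self.weights]
        return all(a >= b for a, b in zip(ws, ws[1:]))

    def require_order_preserving(self) -> "ConfidenceScheme":
        if not self.is_order_preserving():
            raise ValueError(
                "confidence weights must be non-increasing along the method ranking"
            )
        return self

    @classmethod
    def from_ordering(
        cls, ordering: Sequence[str], label: str | None = None
    ) -> "ConfidenceScheme":
        """Linear-decay weights (8 - rank)/7 assigned along ``ordering``."""
        n = len(ordering)
        ws = {m: (n + 1 - r) / n for r, m in enumerate(ordering, start=1)}
        return cls(ws, label=label or "ordering:" + ">".join(ordering))


def default_confidence_scheme() -> ConfidenceScheme:
    """Linear-decay weights down the canonical ranking: SS-PSE 1 ... 1/7."""
    return ConfidenceScheme.from_ordering(METHOD_RANKING, label="default_linear").require_order_preserving()


def geometric_confidence_scheme(ratio: float = 0.7) -> ConfidenceScheme:
    """Geometric-decay weights ratio**rank down the canonical ranking."""
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    ws = {m: ratio**r for r, m in enumerate(METHOD_RANKING)}
    return ConfidenceScheme(ws, label=f"geometric_{ratio:g}")


@dataclass(frozen=True)
class ConsensusResult:
    """Triangulated single estimate for one region and population."""

    region_id: str
    population: str
    point: float
    ci_lower: float
    ci_upper: float
    mu_post: float
    sigma_post: float
    n_inputs: int
    prior_used: bool


def ci_to_log_sd(
    point: float,
    ci_lower: float | None,
    ci_upper: float | None,
    fallback_factor: float = 4.0,
) -> float:
    """Log-scale SD implied by a 95% CI, (ln U - ln L) / (2 * 1.96).

    When either bound is missing (a published "no bounds" row) the SD falls
    back to ln(fallback_factor)/1.96, i.e. a symmetric multiplicative
    factor-``fallback_factor`` interval around the point.
    """
    if point <= 0:
        raise ValueError("point estimate must be > 0")
    lo_missing = ci_lower is None or (isinstance(ci_lower, float) and math.isnan(ci_lower))
    hi_missing = ci_upper is None or (isinstance(ci_upper, float) and math.isnan(ci_upper))
    if lo_missing or hi_missing:
        if fallback_factor <= 1:
            raise ValueError("fallback_factor must be > 1")
        return math.log(fallback_factor) / Z_95
    if ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("CI bounds must be > 0 on a positive size scale")
    if ci_upper < ci_lower:
        raise ValueError("ci_upper < ci_lower")
    return (math.log(ci_upper) - math.log(ci_lower)) / (2 * Z_95)


def _as_frame(estimates) -> pd.DataFrame:
    if isinstance(estimates, pd.DataFrame):
        return estimates
    return pd.DataFrame(list(estimates))


class BayesianConsensus(BaseEstimator):
    """Precision- and confidence-weighted log-scale pooling of estimates.

    Parameters
    ----------
    scheme
        Confidence weights per method; defaults to the canonical
        linear-decay scheme.
    prior
        Optional :class:`~kpsae.program_priors.LogNormalPrior`; must have
        ``sigma_log > 0`` (a point-mass prior is refused).
    fallback_factor
        Multiplicative width of the pseudo-CI used when an input has no
        published bounds.

    After :meth:`fit` on the estimates of a single region/population the
    posterior is available as ``mu_post_``, ``sigma_post_``, ``point_``,
    ``ci_lower_``, ``ci_upper_``; ``fallback_methods_`` lists inputs that
    used the missing-CI fallback.
    """

    def __init__(
        self,
        scheme: ConfidenceScheme | None = None,
        prior: LogNormalPrior | None = None,
        fallback_factor: float = 4.0,
    ):
        self.scheme = scheme
        self.prior = prior
        self.fallback_factor = fallback_factor

    def fit(self, estimates, y=None) -> "BayesianConsensus":
        """Fit the conjugate posterior; ``estimates`` is a DataFrame (or
        iterable of mappings) with columns method, point, ci_lower,
        ci_upper for one region/population."""
        df = _as_frame(estimates)
        if df.empty:
            raise ValueError("at least one direct estimate is required")
        scheme = self.scheme if self.scheme is not None else default_confidence_scheme()
        prior = self.prior
        if prior is not None and prior.sigma_log == 0:
            raise ValueError(
                "point-mass prior (sigma_log = 0): widen the prior before use"
            )
        mus, precs, fallback = [], [], []
        for _, r in df.iterrows():
            point = float(r["point"])
            if point <= 0:
                raise ValueError("all point estimates must be > 0")
            lo = r.get("ci_lower")
            hi = r.get("ci_upper")
            sd = ci_to_log_sd(point, lo, hi, self.fallback_factor)
            if (lo is None or (isinstance(lo, float) and math.isnan(lo))) or (
                hi is None or (isinstance(hi, float) and math.isnan(hi))
            ):
                fallback.append(str(r.get("method")))
            if sd == 0:
                raise ValueError(
                    "degenerate input CI (zero width) gives infinite precision"
                )
            w = float(scheme[r["method"]]) if "method" in r else 1.0
            mus.append(math.log(point))
            precs.append(w / sd**2)
        mus_arr = np.asarray(mus)
        precs_arr = np.asarray(precs)
        prior_prec = 0.0
        num = float(precs_arr @ mus_arr)
        if prior is not None:
            prior_prec = 1.0 / prior.sigma_log**2
            num += prior_prec * prior.mu_log
        total_prec = float(precs_arr.sum()) + prior_prec
        self.input_mus_ = mus_arr
        self.input_precisions_ = precs_arr
        self.prior_precision_ = prior_prec
        self.mu_post_ = num / total_prec
        self.sigma_post_ = math.sqrt(1.0 / total_prec)
        self.point_ = math.exp(self.mu_post_)
        self.ci_lower_ = math.exp(self.mu_post_ - Z_95 * self.sigma_post_)
        self.ci_upper_ = math.exp(self.mu_post_ + Z_95 * self.sigma_post_)
        self.n_inputs_ = len(df)
        self.prior_used_ = prior is not None
        self.fallback_methods_ = fallback
        return self

    def result(self, region_id: str = "", population: str = "") -> ConsensusResult:
        return ConsensusResult(
            region_id=region_id,
            population=population,
            point=self.point_,
            ci_lower=self.ci_lower_,
            ci_upper=self.ci_upper_,
            mu_post=self.mu_post_,
            sigma_post=self.sigma_post_,
            n_inputs=self.n_inputs_,
            prior_used=self.prior_used_,
        )


def consensus_estimate(
    estimates,
    scheme: ConfidenceScheme | None = None,
    prior: LogNormalPrior | None = None,
    fallback_factor: float = 4.0,
    region_id: str = "",
    population: str = "",
) -> ConsensusResult:
    """One-shot functional wrapper around :class:`BayesianConsensus`."""
    est = BayesianConsensus(scheme=scheme, prior=prior, fallback_factor=fallback_factor)
    return est.fit(estimates).result(region_id, population)


def consensus_by_group(
    direct_estimates: pd.DataFrame,
    scheme: ConfidenceScheme | None = None,
    priors: Mapping[tuple[str, str], LogNormalPrior]
    | Mapping[str, LogNormalPrior]
    | LogNormalPrior
    | None = None,
    fallback_factor: float = 4.0,
) -> pd.DataFrame:
    """Consensus estimate per (region_id, population) group.

    ``priors`` may be a single prior applied everywhere, a mapping keyed by
    population, or a mapping keyed by (region_id, population); groups with
    no matching prior are combined without one.
    """
    rows = []
    for (rid, pop), grp in direct_estimates.groupby(
        ["region_id", "population"], sort=True
    ):
        prior = None
        if isinstance(priors, LogNormalPrior):
            prior = priors
        elif priors is not None:
            prior = priors.get((rid, pop), priors.get(pop))  # type: ignore[union-attr]
        res = consensus_estimate(
            grp, scheme, prior, fallback_factor, region_id=rid, population=pop
        )
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def rank_sensitivity(
    estimates,
    prior: LogNormalPrior | None = None,
    schemes: Iterable[ConfidenceScheme] = (),
    permutations: Iterable[Sequence[str]] = (),
    fallback_factor: float = 4.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Re-run the consensus under alternative weightings.

    ``schemes`` are explicit weight vectors (typically order preserving);
    each entry of ``permutations`` is a method ordering that receives
    linear-decay weights via :meth:`ConfidenceScheme.from_ordering`.
    Returns the per-cell result table plus spread statistics: the max/min
    ratio of the consensus point within the order-preserving cells and
    within the non-order-preserving cells.
    """
    cells: list[tuple[ConfidenceScheme, str]] = [(s, "scheme") for s in schemes]
    cells += [
        (ConfidenceScheme.from_ordering(p), "permutation") for p in permutations
    ]
    if not cells:
        raise ValueError("no schemes or permutations supplied")
    rows = []
    for scheme, kind in cells:
        res = consensus_estimate(
            estimates, scheme, prior, fallback_factor=fallback_factor
        )
        rows.append(
            {
                "label": scheme.label,
                "kind": kind,
                "order_preserving": scheme.is_order_preserving(),
                "point": res.point,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
            }
        )
    table = pd.DataFrame(rows)
    spreads: dict[str, float] = {}
    for flag, name in ((True, "order_preserving"), (False, "order_violating")):
        pts = table.loc[table["order_preserving"] == flag, "point"]
        if len(pts):
            spreads[f"spread_{name}"] = float(pts.max() / pts.min())
    return table, spreads


def all_order_permutations(methods: Sequence[str] | None = None) -> list[tuple[str, ...]]:
    """All orderings of ``methods`` (default: full canonical set); intended
    for small subsets — the full set has 7! = 5040 orderings."""
    ms = tuple(methods) if methods is not None else METHOD_RANKING
    return list(itertools.permutations(ms))
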