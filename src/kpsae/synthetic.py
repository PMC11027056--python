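"""Synthetic datasets with known ground truth for the whole pipeline.

The generator emulates the statistical structure the pipeline assumes: a
region's true key-population proportion follows a log-linear model in
standardized auxiliary covariates (or a two-level stratum model), each
estimation method observes the true size with method-specific
multiplicative bias and log-normal noise (noisier and more biased down the
confidence ranking), and program systems report quarterly counts that are
a partial coverage of the true size, never exceeding it.  Everything is
drawn from a single seeded :class:`numpy.random.Generator` (PCG64) in a
fixed documented order, so a seed fully determines the dataset.

Draw order per dataset: (1) for each region in index order — the five
covariates (HIV prevalence, density, literacy, employment, growth), the
survey-year denominator, and the projection growth factor; (2) the
on-sample region selection; (3) for each on-sample region x method in
ranking order — one missingness uniform and one standard normal; (4) for
each source x on-sample region x quarter — one coverage draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import Dataset, METHOD_RANKING, POPULATIONS
from .sae import round_half_up

__all__ = [
    "MethodProfile",
    "DEFAULT_METHOD_PROFILES",
    "SyntheticConfig",
    "generate",
    "true_values",
    "score_consensus",
]


@dataclass(frozen=True)
class MethodProfile:
    """Error model for one estimation method.

    ``bias`` is multiplicative on the true size, ``sigma`` the log-scale
    SD of the observation noise, ``missing_prob`` the chance the method
    was never fielded in a region.
    """

    bias: float = 1.0
    sigma: float = 0.1
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.bias <= 0:
            raise ValueError("bias must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.missing_prob <= 1):
            raise ValueError("missing_prob must be in [0, 1]")


#: Default method error profiles: noise SD and |log bias| both increase
#: down the confidence ranking, mirroring why the ranking exists.
DEFAULT_METHOD_PROFILES: dict[str, MethodProfile] = {
    "ss_pse": MethodProfile(bias=1.00, sigma=0.10, missing_prob=0.05),
    "unique_object_multiplier": MethodProfile(bias=1.03, sigma=0.18, missing_prob=0.05),
    "mapping": MethodProfile(bias=0.95, sigma=0.26, missing_prob=0.05),
    "stakeholder_consensus": MethodProfile(bias=1.08, sigma=0.34, missing_prob=0.05),
    "literature_review": MethodProfile(bias=0.90, sigma=0.45, missing_prob=0.05),
    "key_informant": MethodProfile(bias=0.85, sigma=0.60, missing_prob=0.10),
    "wisdom_of_crowds": MethodProfile(bias=1.25, sigma=0.80, missing_prob=0.10),
}

_COVARIATE_RANGES = {
    "hiv_prevalence": (5.0, 30.0),  # %
    "literacy": (60.0, 95.0),  # %
    "employment": (30.0, 70.0),  # %
    "pop_growth": (0.5, 3.0),  # % per year
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth configuration for one synthetic dataset.

    ``intercept``/``coefficients`` define the true log proportion,
    p_r = exp(intercept + sum_j beta_j z_jr) with z the covariate z-scores
    across regions; alternatively ``stratum_proportions`` fixes p_r by a
    median split on one covariate, e.g.
    ``{"variable": "hiv_prevalence", "high": 0.04, "low": 0.01}``.
    Proportions are clipped to (0, 0.2].
    """

    n_regions: int = 13
    n_onsample: int = 4
    population: str = "FSW"
    intercept: float = math.log(0.02)
    coefficients: dict[str, float] = field(default_factory=dict)
    stratum_proportions: dict | None = None
    method_profiles: dict[str, MethodProfile] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_PROFILES)
    )
    coverage_mean: float = 0.35
    coverage_sd: float = 0.10
    n_quarters: int = 8
    sources: tuple[str, ...] = ("DATIM", "KP_STAR")
    denominator_range: tuple[int, int] = (20_000, 120_000)
    survey_year: int = 2014
    target_year: int = 2021
    seed: int = 0
    rng_algorithm: str = "numpy PCG64 (default_rng)"

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not (1 <= self.n_onsample <= self.n_regions):
            raise ValueError("n_onsample must be in [1, n_regions]")
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if not (0 < self.coverage_mean <= 1):
            raise ValueError("coverage_mean must be in (0, 1]")
        if self.coverage_sd < 0:
            raise ValueError("coverage_sd must be >= 0")
        if self.n_quarters < 1:
            raise ValueError("n_quarters must be >= 1")
        lo, hi = self.denominator_range
        if not (0 < lo <= hi):
            raise ValueError("invalid denominator_range")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


def _quarter_labels(n: int, start_year: int = 2019, start_q: int = 3) -> list[str]:
    out = []
    y, q = start_year, start_q
    for _ in range(n):
        out.append(f"FY{y}Q{q}")
        q += 1
        if q > 4:
            q, y = 1, y + 1
    return out


def _truncated_coverage(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to (0, 1] by rejection; sd = 0 degenerates
    to the mean."""
    if sd == 0:
        return mean
    while True:
        c = rng.normal(mean, sd)
        if 0 < c <= 1:
            return c


def generate(config: SyntheticConfig, seed: int | None = None) -> Dataset:
    """Generate a complete synthetic dataset bundle with a truth table."""
    if seed is not None:
        config = config.with_seed(seed)
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    region_ids = [f"r{i + 1:02d}" for i in range(n)]
    sex = "female" if config.population == "FSW" else "male"

    # (1) per-region covariates, denominators, projection growth
    cov_rows, denom, proj = [], {}, {}
    cov_values: dict[str, list[float]] = {v: [] for v in
                                          ("hiv_prevalence", "population_density",
                                           "literacy", "employment", "pop_growth")}
    for rid in region_ids:
        lo, hi = _COVARIATE_RANGES["hiv_prevalence"]
        hiv = rng.uniform(lo, hi)
        dens = math.exp(rng.uniform(math.log(1.0), math.log(100.0)))
        lit = rng.uniform(*_COVARIATE_RANGES["literacy"])
        emp = rng.uniform(*_COVARIATE_RANGES["employment"])
        grw = rng.uniform(*_COVARIATE_RANGES["pop_growth"])
        den = int(rng.integers(config.denominator_range[0], config.denominator_range[1] + 1))
        growth = rng.uniform(1.05, 1.35)
        for var, val in (
            ("hiv_prevalence", hiv),
            ("population_density", dens),
            ("literacy", lit),
            ("employment", emp),
            ("pop_growth", grw),
        ):
            cov_values[var].append(val)
            cov_rows.append(
                {"region_id": rid, "variable": var, "sex_stratum": "all", "value": val}
            )
        denom[rid] = den
        proj[rid] = int(round(den * growth))

    # true proportions
    if config.stratum_proportions is not None:
        sp = config.stratum_proportions
        vals = np.asarray(cov_values[sp["variable"]])
        threshold = float(np.median(vals))
        strata = np.where(vals > threshold, "high", "low")
        p_true = np.where(strata == "high", float(sp["high"]), float(sp["low"]))
    else:
        eta = np.full(n, config.intercept)
        for var, beta in config.coefficients.items():
            vals = np.asarray(cov_values[var])
            z = (vals - vals.mean()) / vals.std(ddof=1)
            eta = eta + beta * z
        p_true = np.exp(eta)
    p_true = np.clip(p_true, 1e-6, 0.2)
    true_size = np.array(
        [round_half_up(p * denom[rid]) for p, rid in zip(p_true, region_ids)]
    )

    # (2) on-sample selection; with a stratum model both strata get donors
    if config.stratum_proportions is not None:
        hiv_vals = np.asarray(cov_values[config.stratum_proportions["variable"]])
        med = float(np.median(hiv_vals))
        high_idx = [i for i, v in enumerate(hiv_vals) if v > med]
        low_idx = [i for i, v in enumerate(hiv_vals) if v <= med]
        n_high = min(len(high_idx), max(1, config.n_onsample // 2 + config.n_onsample % 2))
        n_low = min(len(low_idx), config.n_onsample - n_high)
        chosen = list(rng.choice(high_idx, size=n_high, replace=False))
        chosen += list(rng.choice(low_idx, size=n_low, replace=False))
        onsample_idx = sorted(int(i) for i in chosen)
    else:
        onsample_idx = sorted(
            int(i) for i in rng.choice(n, size=config.n_onsample, replace=False)
        )
    onsample = np.zeros(n, dtype=bool)
    onsample[onsample_idx] = True

    # (3) method-level direct estimates for on-sample regions
    est_rows = []
    z95 = 1.96
    for i in onsample_idx:
        rid = region_ids[i]
        for method in METHOD_RANKING:
            prof = config.method_profiles.get(method)
            u = rng.uniform()
            zdraw = rng.standard_normal()
            if prof is None or u < prof.missing_prob:
                continue
            point = max(
                1, round_half_up(true_size[i] * prof.bias * math.exp(prof.sigma * zdraw))
            )
            est_rows.append(
                {
                    "region_id": rid,
                    "population": config.population,
                    "method": method,
                    "point": float(point),
                    "ci_lower": point * math.exp(-z95 * prof.sigma),
                    "ci_upper": point * math.exp(z95 * prof.sigma),
                    "year": config.survey_year,
                }
            )

    # (4) quarterly program counts (partial coverage of the true size)
    quarters = _quarter_labels(config.n_quarters)
    prog_rows = []
    for source in config.sources:
        for i in onsample_idx:
            rid = region_ids[i]
            for q in quarters:
                cov = _truncated_coverage(rng, config.coverage_mean, config.coverage_sd)
                prog_rows.append(
                    {
                        "source": source,
                        "population": config.population,
                        "region_id": rid,
                        "fiscal_quarter": q,
                        "count": round_half_up(cov * true_size[i]),
                    }
                )

    # stratum memberships recorded for both stratification covariates
    def _split(var: str) -> np.ndarray:
        vals = np.asarray(cov_values[var])
        return np.where(vals > np.median(vals), "high", "low")

    regions = pd.DataFrame(
        {"region_id": region_ids, "name": [f"Region {i + 1:02d}" for i in range(n)]}
    )
    denominators = pd.DataFrame(
        [
            {"region_id": rid, "sex": sex, "age_band": "18-49",
             "year": config.survey_year, "count": denom[rid]}
            for rid in region_ids
        ]
        + [
            {"region_id": rid, "sex": sex, "age_band": "15-49",
             "year": config.target_year, "count": proj[rid]}
            for rid in region_ids
        ]
    )
    truth = pd.DataFrame(
        {
            "region_id": region_ids,
            "onsample": onsample,
            "true_proportion": p_true,
            "true_size": true_size,
            "denominator": [denom[r] for r in region_ids],
            "projection": [proj[r] for r in region_ids],
            "stratum_hiv": _split("hiv_prevalence"),
            "stratum_density": _split("population_density"),
        }
    )
    return Dataset(
        regions=regions,
        denominators=denominators,
        direct_estimates=pd.DataFrame(
            est_rows,
            columns=["region_id", "population", "method", "point", "ci_lower",
                     "ci_upper", "year"],
        ),
        program_records=pd.DataFrame(
            prog_rows,
            columns=["source", "population", "region_id", "fiscal_quarter", "count"],
        ),
        covariates=pd.DataFrame(cov_rows),
        truth=truth,
    )


def true_values(dataset: Dataset) -> pd.DataFrame:
    """Region-level ground truth of a synthetic dataset (errors on real data)."""
    if dataset.truth is None:
        raise ValueError("dataset carries no ground truth (not synthetic)")
    return dataset.truth


def score_consensus(consensus: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Recovery metrics of consensus output against ground truth.

    Returns log-scale mean bias and RMSE of the consensus point, plus the
    empirical coverage of the 95% credible intervals.
    """
    merged = consensus.merge(truth, on="region_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping regions between consensus and truth")
    log_err = np.log(merged["point"]) - np.log(merged["true_size"])
    covered = (merged["ci_lower"] <= merged["true_size"]) & (
        merged["true_size"] <= merged["ci_upper"]
    )
    return {
        "bias_log": float(log_err.mean()),
        "rmse_log": float(np.sqrt((log_err**2).mean())),
        "coverage": float(covered.mean()),
        "n": int(len(merged)),
    }
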