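"""Offset-Poisson regression for small-area extrapolation.

The full set of method-level direct estimates (rounded to integer counts)
is modelled as log E[count] = b0 + sum_j b_j x_j + ln(denominator), so the
linear predictor is a log *proportion* of the reference population.
Estimating equations are solved with region clusters (GEE, independence or
exchangeable working correlation, robust variance); AIC/BIC for model
selection are computed from the ordinary independence-likelihood Poisson
fit of the same design.  Covariates are z-scored across regions before
fitting; coefficients are reported on both the standardized and the raw
scale.  Predicted proportions exp(b0 + sum b_j x_j) are applied to
target-year projections with the same half-up rounding as the imputation
variants, capped at the projection with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .core_data import COVARIATE_VARIABLES
from .sae import round_half_up

__all__ = [
    "PoissonModelSpec",
    "FitResult",
    "OffsetPoissonGEE",
    "fit_poisson",
    "select_model",
    "predict_regions",
]


@dataclass(frozen=True)
class PoissonModelSpec:
    """Candidate model: covariate subset + working correlation."""

    covariates: tuple[str, ...] = ()
    correlation: str = "independence"

    def __post_init__(self) -> None:
        unknown = [c for c in self.covariates if c not in COVARIATE_VARIABLES]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}")
        if self.correlation not in ("independence", "exchangeable"):
            raise ValueError(f"unknown working correlation {self.correlation!r}")

    @property
    def label(self) -> str:
        return "+".join(self.covariates) if self.covariates else "intercept_only"


@dataclass
class FitResult:
    """Fitted offset-Poisson model summary.

    ``coefficients`` are on the raw covariate scale (log-rate per unit);
    ``coefficients_std`` on the z-scored scale actually fitted.
    """

    spec: PoissonModelSpec
    coefficients: dict[str, float]
    coefficients_std: dict[str, float]
    aic: float
    bic: float
    converged: bool
    n_obs: int
    n_clusters: int
    qic: float | None = None
    estimator: "OffsetPoissonGEE | None" = field(default=None, repr=False)


class OffsetPoissonGEE(BaseEstimator):
    """Region-clustered Poisson regression with a log-denominator offset.

    Parameters
    ----------
    covariates
        Names of regional covariate columns to include.
    correlation
        GEE working correlation: ``"independence"`` or ``"exchangeable"``.
    standardize
        Z-score covariates across *regions* (not observations) before
        fitting; raw-scale coefficients are recovered afterwards.

    ``fit(data)`` expects a DataFrame with columns region_id, count,
    denominator, plus one column per covariate (constant within region).
    Fitted attributes: ``coef_`` / ``intercept_`` (raw scale),
    ``coef_std_``/``intercept_std_``, ``aic_``, ``bic_`` (independence-
    likelihood), ``qic_``, ``converged_``.
    """

    def __init__(
        self,
        covariates: tuple[str, ...] = (),
        correlation: str = "independence",
        standardize: bool = True,
    ):
        self.covariates = covariates
        self.correlation = correlation
        self.standardize = standardize

    def _design(self, data: pd.DataFrame, fit: bool) -> np.ndarray:
        cols = list(self.covariates)
        X = data[cols].astype(float).to_numpy() if cols else np.empty((len(data), 0))
        if self.standardize and cols:
            if fit:
                region_vals = data.drop_duplicates("region_id")[cols].astype(float)
                self.center_ = region_vals.mean().to_numpy()
                scale = region_vals.std(ddof=1).to_numpy()
                if np.any(scale == 0):
                    bad = cols[int(np.argmax(scale == 0))]
                    raise ValueError(f"covariate {bad!r} is constant across regions")
                self.scale_ = scale
            X = (X - self.center_) / self.scale_
        elif fit:
            self.center_ = np.zeros(len(cols))
            self.scale_ = np.ones(len(cols))
        return sm.add_constant(X, has_constant="add")

    def fit(self, data: pd.DataFrame, y=None) -> "OffsetPoissonGEE":
        spec = PoissonModelSpec(tuple(self.covariates), self.correlation)
        data = data.reset_index(drop=True)
        groups = data["region_id"].to_numpy()
        n_clusters = len(pd.unique(groups))
        if n_clusters < 2:
            raise ValueError("need >= 2 region clusters for clustered estimation")
        counts = data["count"].astype(float).to_numpy()
        if (counts < 0).any() or np.any(counts % 1 != 0):
            raise ValueError("counts must be non-negative integers (round points first)")
        offset = np.log(data["denominator"].astype(float).to_numpy())
        X = self._design(data, fit=True)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")

        cov_struct = (
            sm.cov_struct.Exchangeable()
            if spec.correlation == "exchangeable"
            else sm.cov_struct.Independence()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gee = sm.GEE(
                counts, X, groups=groups, family=sm.families.Poisson(), offset=offset,
                cov_struct=cov_struct,
            )
            res = gee.fit(maxiter=200)
            # independence-likelihood fit of the same design for AIC/BIC
            glm_res = sm.GLM(
                counts, X, family=sm.families.Poisson(), offset=offset
            ).fit()
        params = np.asarray(res.params, dtype=float)
        self.converged_ = bool(np.all(np.isfinite(params)))
        if not self.converged_:
            raise RuntimeError("estimating equations did not converge")
        self.intercept_std_ = float(params[0])
        self.coef_std_ = {c: float(b) for c, b in zip(self.covariates, params[1:])}
        raw = params[1:] / self.scale_ if len(self.covariates) else params[1:]
        self.coef_ = {c: float(b) for c, b in zip(self.covariates, raw)}
        self.intercept_ = float(params[0] - (raw @ self.center_ if len(raw) else 0.0))
        k = X.shape[1]
        self.aic_ = float(2 * k - 2 * glm_res.llf)
        self.bic_ = float(k * np.log(len(data)) - 2 * glm_res.llf)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.qic_ = float(res.qic()[0])
        except Exception:
            self.qic_ = None
        self.n_obs_ = len(data)
        self.n_clusters_ = n_clusters
        self.result_ = res
        self.spec_ = spec
        return self

    def predict_proportion(self, covariates: pd.DataFrame) -> pd.Series:
        """Predicted proportion per region from a region-indexed covariate
        frame (columns must include every fitted covariate)."""
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        missing = [c for c in self.covariates if c not in covariates.columns]
        if missing:
            raise KeyError(f"missing covariate columns {missing}")
        eta = np.full(len(covariates), self.intercept_)
        for c in self.covariates:
            eta = eta + self.coef_[c] * covariates[c].astype(float).to_numpy()
        return pd.Series(np.exp(eta), index=covariates.index, name="proportion")

    def predict(
        self, covariates: pd.DataFrame, projections: pd.Series
    ) -> pd.DataFrame:
        """Regional size predictions: round_half_up(proportion * projection),
        capped at the projection with a warning."""
        props = self.predict_proportion(covariates)
        rows = []
        for rid, p in props.items():
            if rid not in projections.index:
                raise KeyError(f"missing projection for region {rid!r}")
            proj = float(projections[rid])
            size = p * proj
            if size >= proj:
                warnings.warn(
                    f"prediction for region {rid!r} reaches its projection; capping",
                    stacklevel=2,
                )
                size = proj
            rows.append(
                {
                    "region_id": rid,
                    "population": "",
                    "estimate": round_half_up(size),
                    "variant": "regression",
                    "data_mode": "pre_program",
                }
            )
        return pd.DataFrame(rows)

    def to_fit_result(self) -> FitResult:
        coefs = {"intercept": self.intercept_, **self.coef_}
        coefs_std = {"intercept": self.intercept_std_, **self.coef_std_}
        return FitResult(
            spec=self.spec_,
            coefficients=coefs,
            coefficients_std=coefs_std,
            aic=self.aic_,
            bic=self.bic_,
            converged=self.converged_,
            n_obs=self.n_obs_,
            n_clusters=self.n_clusters_,
            qic=self.qic_,
            estimator=self,
        )


def _assemble(
    estimates: pd.DataFrame, denominators: pd.Series, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Join method-level points (rounded to counts) with denominators and
    region covariates into a model frame."""
    df = estimates[["region_id", "point"]].copy()
    df["count"] = df["point"].map(round_half_up)
    df["denominator"] = df["region_id"].map(denominators.astype(float))
    if df["denominator"].isna().any():
        rid = df.loc[df["denominator"].isna(), "region_id"].iloc[0]
        raise KeyError(f"missing denominator for region {rid!r}")
    for c in covariates.columns:
        df[c] = df["region_id"].map(covariates[c].astype(float))
        if df[c].isna().any():
            rid = df.loc[df[c].isna(), "region_id"].iloc[0]
            raise KeyError(f"missing covariate {c!r} for region {rid!r}")
    return df


def fit_poisson(
    estimates: pd.DataFrame,
    denominators: pd.Series,
    covariates: pd.DataFrame,
    spec: PoissonModelSpec,
    standardize: bool = True,
) -> FitResult:
    """Fit one candidate model from raw pipeline tables.

    ``estimates``: method-level direct estimates (region_id, point);
    ``denominators``: region-indexed survey-year counts; ``covariates``:
    region-indexed frame of auxiliary variables.
    """
    data = _assemble(estimates, denominators, covariates[list(spec.covariates)] if spec.covariates else covariates.iloc[:, :0])
    est = OffsetPoissonGEE(
        covariates=spec.covariates,
        correlation=spec.correlation,
        standardize=standardize,
    )
    return est.fit(data).to_fit_result()


def select_model(
    candidates: list[PoissonModelSpec],
    estimates: pd.DataFrame,
    denominators: pd.Series,
    covariates: pd.DataFrame,
    standardize: bool = True,
) -> tuple[FitResult, pd.DataFrame]:
    """Fit all candidates; return the AIC-minimizing fit (BIC tiebreak)
    plus the full ranking table (non-converged candidates noted)."""
    if not candidates:
        raise ValueError("no candidate models supplied")
    rows, fits = [], {}
    for spec in candidates:
        try:
            fr = fit_poisson(estimates, denominators, covariates, spec, standardize)
            fits[spec.label] = fr
            rows.append(
                {
                    "model": spec.label,
                    "correlation": spec.correlation,
                    "aic": fr.aic,
                    "bic": fr.bic,
                    "qic": fr.qic,
                    "converged": True,
                    "note": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - record per-candidate failure
            rows.append(
                {
                    "model": spec.label,
                    "correlation": spec.correlation,
                    "aic": np.nan,
                    "bic": np.nan,
                    "qic": np.nan,
                    "converged": False,
                    "note": str(exc),
                }
            )
    ranking = pd.DataFrame(rows).sort_values(
        ["aic", "bic"], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    ok = ranking[ranking["converged"]]
    if ok.empty:
        raise RuntimeError("all candidate models failed to fit")
    return fits[ok.iloc[0]["model"]], ranking


def predict_regions(
    fit: FitResult, covariates: pd.DataFrame, projections: pd.Series, population: str = ""
) -> pd.DataFrame:
    """Predict regional sizes for every region with covariates available."""
    if fit.estimator is None:
        raise ValueError("FitResult lacks its fitted estimator")
    out = fit.estimator.predict(covariates, projections)
    out["population"] = population
    return out
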