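"""Offset-Poisson GEE fits, model selection, and prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from kpsae.regression import (
    OffsetPoissonGEE,
    PoissonModelSpec,
    fit_poisson,
    predict_regions,
    select_model,
)


def _frame(region_ids, counts, denominators, **covs):
    df = pd.DataFrame(
        {"region_id": region_ids, "count": counts, "denominator": denominators}
    )
    for k, v in covs.items():
        df[k] = v
    return df


def _simulate(rng, n_regions=13, n_methods=7, b0=np.log(0.02), beta=0.4):
    rows = []
    for i in range(n_regions):
        z = rng.normal()
        den = rng.integers(20_000, 80_000)
        lam = np.exp(b0 + beta * z) * den
        for _ in range(n_methods):
            rows.append(
                {"region_id": f"r{i:02d}", "count": rng.poisson(lam),
                 "denominator": den, "hiv_prevalence": 17 + 5 * z}
            )
    return pd.DataFrame(rows)


class TestClosedForms:
    def test_intercept_only_is_pooled_ratio(self):
        data = _frame(["a", "b"], [2, 4], [100, 100])
        m = OffsetPoissonGEE().fit(data)
        assert m.intercept_ == pytest.approx(np.log(6 / 200), abs=1e-8)

    def test_binary_covariate_saturated(self):
        data = _frame(
            ["a", "a", "b", "b"], [2, 2, 4, 4], [100] * 4, hiv_prevalence=[0, 0, 1, 1]
        )
        m = OffsetPoissonGEE(covariates=("hiv_prevalence",)).fit(data)
        assert m.coef_["hiv_prevalence"] == pytest.approx(np.log(2), abs=1e-6)
        assert m.intercept_ == pytest.approx(np.log(0.02), abs=1e-6)

    def test_single_cluster_rejected(self):
        data = _frame(["a", "a"], [2, 4], [100, 100])
        with pytest.raises(ValueError, match=">= 2 region clusters"):
            OffsetPoissonGEE().fit(data)

    def test_non_integer_counts_rejected(self):
        data = _frame(["a", "b"], [2.5, 4], [100, 100])
        with pytest.raises(ValueError, match="integers"):
            OffsetPoissonGEE().fit(data)

    def test_rank_deficiency_rejected(self):
        data = _frame(
            ["a", "b"], [2, 4], [100, 100],
            hiv_prevalence=[1.0, 2.0], literacy=[2.0, 4.0],
        )
        with pytest.raises(ValueError):
            OffsetPoissonGEE(covariates=("hiv_prevalence", "literacy")).fit(data)


class TestInvariances:
    def test_independence_matches_plain_glm(self):
        rng = np.random.default_rng(7)
        data = _simulate(rng, n_regions=13, n_methods=1)
        m = OffsetPoissonGEE(covariates=("hiv_prevalence",), standardize=False).fit(data)
        X = sm.add_constant(data[["hiv_prevalence"]].to_numpy())
        glm = sm.GLM(
            data["count"].to_numpy(), X, family=sm.families.Poisson(),
            offset=np.log(data["denominator"].to_numpy()),
        ).fit()
        assert m.intercept_ == pytest.approx(glm.params[0], abs=1e-6)
        assert m.coef_["hiv_prevalence"] == pytest.approx(glm.params[1], abs=1e-6)

    def test_denominator_scaling_shifts_only_intercept(self):
        rng = np.random.default_rng(11)
        data = _simulate(rng)
        m1 = OffsetPoissonGEE(covariates=("hiv_prevalence",)).fit(data)
        scaled = data.assign(denominator=data["denominator"] * 10)
        m2 = OffsetPoissonGEE(covariates=("hiv_prevalence",)).fit(scaled)
        assert m2.coef_["hiv_prevalence"] == pytest.approx(
            m1.coef_["hiv_prevalence"], abs=1e-6
        )
        assert m2.intercept_ == pytest.approx(m1.intercept_ - np.log(10), abs=1e-6)

    def test_standardization_preserves_raw_scale_coefficients(self):
        rng = np.random.default_rng(3)
        data = _simulate(rng)
        raw = OffsetPoissonGEE(covariates=("hiv_prevalence",), standardize=False).fit(data)
        std = OffsetPoissonGEE(covariates=("hiv_prevalence",), standardize=True).fit(data)
        assert std.coef_["hiv_prevalence"] == pytest.approx(
            raw.coef_["hiv_prevalence"], rel=1e-5
        )
        assert std.intercept_ == pytest.approx(raw.intercept_, rel=1e-5)
        assert std.aic_ == pytest.approx(raw.aic_, rel=1e-8)


class TestModelSelection:
    def _tables(self, rng):
        data = _simulate(rng, beta=0.5)
        est = data.rename(columns={"count": "point"})[["region_id", "point"]]
        den = data.drop_duplicates("region_id").set_index("region_id")["denominator"].astype(float)
        cov = data.drop_duplicates("region_id").set_index("region_id")[["hiv_prevalence"]]
        cov["literacy"] = rng.uniform(60, 95, size=len(cov))  # pure noise
        return est, den, cov

    def test_aic_argmin_selected_and_ranking_sorted(self):
        rng = np.random.default_rng(5)
        est, den, cov = self._tables(rng)
        candidates = [
            PoissonModelSpec(()),
            PoissonModelSpec(("hiv_prevalence",)),
            PoissonModelSpec(("literacy",)),
        ]
        best, ranking = select_model(candidates, est, den, cov)
        assert ranking["aic"].is_monotonic_increasing
        assert best.spec.label == ranking.loc[0, "model"]
        assert best.spec.covariates == ("hiv_prevalence",)

    def test_true_covariate_selected_in_majority_of_replicates(self):
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            est, den, cov = self._tables(rng)
            best, _ = select_model(
                [PoissonModelSpec(("hiv_prevalence",)), PoissonModelSpec(("literacy",))],
                est, den, cov,
            )
            wins += best.spec.covariates == ("hiv_prevalence",)
        assert wins > n_rep / 2

    def test_all_failures_raise(self):
        est = pd.DataFrame({"region_id": ["a", "a"], "point": [2.0, 4.0]})
        den = pd.Series({"a": 100.0})
        cov = pd.DataFrame(index=pd.Index(["a"], name="region_id"))
        with pytest.raises(RuntimeError, match="all candidate models failed"):
            select_model([PoissonModelSpec(())], est, den, cov)


class TestPrediction:
    def test_intercept_only_prediction(self):
        data = _frame(["a", "b"], [3, 3], [100, 100])
        m = OffsetPoissonGEE().fit(data)  # rate 0.03
        cov = pd.DataFrame(index=pd.Index(["a", "b"], name="region_id"))
        proj = pd.Series({"a": 1000.0, "b": 2000.0})
        out = m.predict(cov, proj)
        assert out.set_index("region_id")["estimate"].to_dict() == {"a": 30, "b": 60}

    def test_prediction_capped_at_projection(self):
        data = _frame(["a", "b"], [150, 150], [100, 100])  # rate 1.5
        m = OffsetPoissonGEE().fit(data)
        cov = pd.DataFrame(index=pd.Index(["a"], name="region_id"))
        with pytest.warns(UserWarning, match="capping"):
            out = m.predict(cov, pd.Series({"a": 10.0}))
        assert out.loc[0, "estimate"] == 10

    def test_missing_covariate_rejected(self):
        data = _frame(["a", "b"], [2, 4], [100, 100], hiv_prevalence=[1.0, 2.0])
        m = OffsetPoissonGEE(covariates=("hiv_prevalence",)).fit(data)
        with pytest.raises(KeyError, match="hiv_prevalence"):
            m.predict_proportion(pd.DataFrame(index=["a"]))

    def test_fit_result_roundtrip(self):
        data = _frame(["a", "b"], [2, 4], [100, 100])
        fr = OffsetPoissonGEE().fit(data).to_fit_result()
        cov = pd.DataFrame(index=pd.Index(["a", "b"], name="region_id"))
        out = predict_regions(fr, cov, pd.Series({"a": 1000.0, "b": 1000.0}), "FSW")
        assert (out["population"] == "FSW").all()
        assert fr.n_obs == 2 and fr.n_clusters == 2


def test_parameter_recovery_over_replicates():
    """Coefficient estimates center on the generating value across seeds."""
    b_hat = []
    for seed in range(200):
        rng = np.random.default_rng(5000 + seed)
        data = _simulate(rng, n_regions=13, n_methods=7, beta=0.4)
        m = OffsetPoissonGEE(covariates=("hiv_prevalence",), standardize=False).fit(data)
        b_hat.append(m.coef_["hiv_prevalence"])
    b_hat = np.asarray(b_hat)
    truth = 0.4 / 5  # hiv_prevalence = 17 + 5 z, so per-unit slope is beta/5
    mc_se = b_hat.std(ddof=1) / np.sqrt(len(b_hat))
    assert abs(b_hat.mean() - truth) < 2 * mc_se + 1e-4
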