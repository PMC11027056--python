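"""Precision-weighted log-scale triangulation against a grid-posterior oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kpsae.consensus import (
    BayesianConsensus,
    ConfidenceScheme,
    Z_95,
    ci_to_log_sd,
    consensus_by_group,
    consensus_estimate,
    default_confidence_scheme,
    geometric_confidence_scheme,
    rank_sensitivity,
)
from kpsae.core_data import METHOD_RANKING
from kpsae.program_priors import LogNormalPrior

from conftest import make_estimates


def grid_posterior(points, sigmas, weights, prior=None, n_grid=100_000):
    """Brute-force discretized posterior over log size.

    Independent oracle: each input contributes a tempered Gaussian factor
    exp(-w (mu - ln x)^2 / (2 s^2)); the prior an untempered one.  Returns
    the posterior mean and SD of log size computed by numeric summation.
    """
    mus = np.log(points)
    span = [mus.min() - 8 * max(sigmas), mus.max() + 8 * max(sigmas)]
    if prior is not None:
        span[0] = min(span[0], prior.mu_log - 8 * prior.sigma_log)
        span[1] = max(span[1], prior.mu_log + 8 * prior.sigma_log)
    grid = np.linspace(span[0], span[1], n_grid)
    logp = np.zeros_like(grid)
    for m, s, w in zip(mus, sigmas, weights):
        logp -= w * (grid - m) ** 2 / (2 * s**2)
    if prior is not None:
        logp -= (grid - prior.mu_log) ** 2 / (2 * prior.sigma_log**2)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    mean = float((grid * p).sum())
    sd = float(np.sqrt(((grid - mean) ** 2 * p).sum()))
    return mean, sd


class TestConfidenceScheme:
    def test_default_weights(self):
        scheme = default_confidence_scheme()
        assert scheme["ss_pse"] == pytest.approx(1.0)
        assert scheme["wisdom_of_crowds"] == pytest.approx(1 / 7)
        ws = [scheme[m] for m in METHOD_RANKING]
        assert all(a > b for a, b in zip(ws, ws[1:]))
        assert scheme.is_order_preserving()

    def test_order_violating_detected(self):
        s = ConfidenceScheme({"ss_pse": 0.1, "wisdom_of_crowds": 1.0})
        assert not s.is_order_preserving()
        with pytest.raises(ValueError, match="non-increasing"):
            s.require_order_preserving()

    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            ConfidenceScheme({"ss_pse": 0.0})
        with pytest.raises(ValueError):
            ConfidenceScheme({"ss_pse": 1.5})


class TestCiToLogSd:
    def test_published_interval(self):
        assert ci_to_log_sd(1480, 1099, 1779) == pytest.approx(
            (math.log(1779) - math.log(1099)) / 3.92
        )
        assert ci_to_log_sd(1480, 1099, 1779) == pytest.approx(0.1229, abs=1e-4)

    def test_degenerate_interval(self):
        assert ci_to_log_sd(100, 100, 100) == 0.0

    def test_missing_bounds_fallback(self):
        sd = ci_to_log_sd(400, None, None, fallback_factor=4)
        assert sd == pytest.approx(math.log(4) / 1.96)
        assert sd == pytest.approx(0.7073, abs=1e-4)
        assert ci_to_log_sd(400, float("nan"), 1600.0) == sd

    def test_nonpositive_bound_rejected(self):
        with pytest.raises(ValueError):
            ci_to_log_sd(100, 0, 200)
        with pytest.raises(ValueError):
            ci_to_log_sd(-1, None, None)


class TestConsensusClosedForm:
    def test_single_input_identity(self):
        res = consensus_estimate(make_estimates([("ss_pse", 100, 0.2)]))
        assert res.point == pytest.approx(100.0)
        assert res.ci_lower == pytest.approx(100 * math.exp(-1.96 * 0.2))
        assert res.ci_upper == pytest.approx(100 * math.exp(1.96 * 0.2))
        assert res.n_inputs == 1 and not res.prior_used

    def test_equal_weight_geometric_mean(self):
        scheme = ConfidenceScheme({"ss_pse": 1.0, "mapping": 1.0})
        res = consensus_estimate(
            make_estimates([("ss_pse", 100, 0.3), ("mapping", 400, 0.3)]), scheme
        )
        assert res.point == pytest.approx(200.0)

    def test_conjugate_update_with_prior(self):
        est = make_estimates([("ss_pse", math.exp(4), 1.0)])
        res = consensus_estimate(est, prior=LogNormalPrior(6.0, 1.0))
        assert res.mu_post == pytest.approx(5.0)
        assert res.point == pytest.approx(math.exp(5), rel=1e-12)
        assert res.sigma_post == pytest.approx(1 / math.sqrt(2))
        assert res.ci_lower == pytest.approx(math.exp(5 - Z_95 / math.sqrt(2)))
        assert res.ci_upper == pytest.approx(math.exp(5 + Z_95 / math.sqrt(2)))
        assert res.prior_used

    def test_point_mass_prior_refused(self):
        with pytest.raises(ValueError, match="widen"):
            consensus_estimate(
                make_estimates([("ss_pse", 100, 0.2)]), prior=LogNormalPrior(5, 0.0)
            )

    def test_empty_input_refused(self):
        with pytest.raises(ValueError, match="at least one"):
            consensus_estimate(pd.DataFrame())

    def test_result_invariants(self):
        res = consensus_estimate(
            make_estimates([("ss_pse", 150, 0.2), ("key_informant", 800, 0.6)])
        )
        assert res.ci_lower <= res.point <= res.ci_upper
        assert res.point == pytest.approx(math.exp(res.mu_post))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
@pytest.mark.parametrize("with_prior", [False, True])
def test_grid_oracle_equivalence(seed, with_prior):
    """Closed-form posterior matches a brute-force grid posterior."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 6))
    methods = list(rng.choice(METHOD_RANKING, size=k, replace=False))
    points = rng.uniform(50, 5000, size=k)
    sigmas = rng.uniform(0.05, 0.9, size=k)
    est = make_estimates(list(zip(methods, points, sigmas)))
    scheme = default_confidence_scheme()
    prior = LogNormalPrior(float(rng.uniform(3, 8)), float(rng.uniform(0.2, 1.5))) \
        if with_prior else None
    model = BayesianConsensus(scheme=scheme, prior=prior).fit(est)
    weights = [scheme[m] for m in est["method"]]
    mean, sd = grid_posterior(
        est["point"].to_numpy(), np.array(sigmas), weights, prior
    )
    assert model.mu_post_ == pytest.approx(mean, abs=1e-4)
    assert model.sigma_post_ == pytest.approx(sd, rel=1e-3)
    assert math.log(model.ci_lower_) == pytest.approx(mean - Z_95 * sd, abs=1e-3)
    assert math.log(model.ci_upper_) == pytest.approx(mean + Z_95 * sd, abs=1e-3)


class TestPosteriorProperties:
    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_precision_conservation_and_convexity(self, data):
        k = data.draw(st.integers(1, 5))
        methods = METHOD_RANKING[:k]
        points = [data.draw(st.floats(10, 10_000)) for _ in range(k)]
        sigmas = [data.draw(st.floats(0.05, 1.5)) for _ in range(k)]
        use_prior = data.draw(st.booleans())
        prior = LogNormalPrior(data.draw(st.floats(2, 9)),
                               data.draw(st.floats(0.1, 2))) if use_prior else None
        scheme = default_confidence_scheme()
        model = BayesianConsensus(scheme=scheme, prior=prior).fit(
            make_estimates(list(zip(methods, points, sigmas)))
        )
        expected_prec = sum(
            scheme[m] / s**2 for m, s in zip(methods, sigmas)
        ) + (1 / prior.sigma_log**2 if prior else 0.0)
        assert 1 / model.sigma_post_**2 == pytest.approx(expected_prec, rel=1e-12)
        hull = [math.log(p) for p in points] + ([prior.mu_log] if prior else [])
        assert min(hull) - 1e-9 <= model.mu_post_ <= max(hull) + 1e-9

    def test_weight_scaling_noop_without_prior(self):
        est = make_estimates([("ss_pse", 100, 0.1), ("mapping", 300, 0.4)])
        s1 = ConfidenceScheme({"ss_pse": 1.0, "mapping": 0.5})
        s2 = ConfidenceScheme({"ss_pse": 0.5, "mapping": 0.25})
        r1 = consensus_estimate(est, s1)
        r2 = consensus_estimate(est, s2)
        assert r1.point == pytest.approx(r2.point, rel=1e-12)
        assert r2.sigma_post > r1.sigma_post  # interval does widen

    def test_weight_scale_moves_away_from_prior(self):
        est = make_estimates([("ss_pse", 100, 0.1), ("mapping", 300, 0.4)])
        prior = LogNormalPrior(math.log(1000), 0.5)
        data_only = consensus_estimate(est, ConfidenceScheme({"ss_pse": 1.0, "mapping": 0.5}))
        pts = []
        for c in (0.25, 0.5, 1.0):
            scheme = ConfidenceScheme({"ss_pse": c, "mapping": 0.5 * c})
            pts.append(consensus_estimate(est, scheme, prior).point)
        dists = [abs(math.log(p) - math.log(prior.median)) for p in pts]
        assert dists[0] < dists[1] < dists[2]
        assert all(p < prior.median and p > data_only.point for p in pts)

    def test_monotone_prior_influence(self):
        est = make_estimates([("ss_pse", 100, 0.2)])
        points = [
            consensus_estimate(est, prior=LogNormalPrior(mu, 0.5)).point
            for mu in (4.0, 5.0, 6.0)
        ]
        assert points[0] < points[1] < points[2]


class TestGrouping:
    def test_consensus_by_group_keys(self, tiny_dataset):
        out = consensus_by_group(tiny_dataset.direct_estimates)
        assert len(out) == 1
        assert out.loc[0, "region_id"] == "r01"
        assert out.loc[0, "n_inputs"] == 3

    def test_per_region_prior_mapping(self, tiny_dataset):
        prior = LogNormalPrior(math.log(500), 0.4)
        with_prior = consensus_by_group(
            tiny_dataset.direct_estimates, priors={("r01", "FSW"): prior}
        )
        without = consensus_by_group(tiny_dataset.direct_estimates)
        assert with_prior.loc[0, "prior_used"]
        assert with_prior.loc[0, "point"] > without.loc[0, "point"]


class TestRankSensitivity:
    def test_single_input_all_schemes_agree(self):
        est = make_estimates([("ss_pse", 100, 0.2)])
        table, _ = rank_sensitivity(
            est,
            schemes=[ConfidenceScheme({"ss_pse": 1.0}, label="a"),
                     ConfidenceScheme({"ss_pse": 0.3}, label="b")],
        )
        assert table["point"].nunique() == 1

    def test_order_preserving_schemes_and_spread_reported(self):
        est = make_estimates(
            [(m, p, s) for m, p, s in zip(
                METHOD_RANKING,
                [1000, 1100, 900, 1300, 700, 2500, 300],
                [0.1, 0.18, 0.26, 0.34, 0.45, 0.6, 0.8],
            )]
        )
        schemes = [default_confidence_scheme(), geometric_confidence_scheme(0.5)]
        perms = [tuple(reversed(METHOD_RANKING))]
        table, spreads = rank_sensitivity(est, schemes=schemes, permutations=perms)
        assert len(table) == 3
        assert spreads["spread_order_preserving"] >= 1
        assert spreads["spread_order_violating"] >= 1
        assert np.isfinite(table["point"]).all()

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError):
            rank_sensitivity(make_estimates([("ss_pse", 100, 0.2)]))
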