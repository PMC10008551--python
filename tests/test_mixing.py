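"""Bayesian dietary mixing: problem building, forward model, posterior sampling."""

import numpy as np
import pytest

from isomix import mixing as mx
from isomix.synth import default_problem_for_synthesis


def _simple_source(name, d13c, conc_protein=0.5, sd=0.1):
    return mx.FoodSource(
        name,
        {
            "protein": {"d13C_coll": (d13c, sd)},
            "energy": {"d13C_coll": (d13c - 1.0, sd)},
        },
        {"protein": (conc_protein, 0.0), "energy": (1.0 - conc_protein, 0.0)},
    )


class TestBuildProblem:
    def test_seven_source_problem_with_prior_is_valid(self):
        problem = mx.build_problem(
            mx.default_sources(),
            [mx.ProxyTarget("d13C_coll", -19.0, 0.7), mx.ProxyTarget("d15N", 10.0, 1.0)],
            mx.default_offsets(),
            mx.default_routing(),
            priors=[mx.Constraint.at_least("C3 plants", 0.3)],
        )
        assert len(problem.source_names) == 7
        assert problem.satisfies(np.array([0.4] + [0.1] * 6)).all()
        assert not problem.satisfies(np.full(7, 1 / 7)).any()

    def test_infeasible_constraints_rejected_by_name(self):
        with pytest.raises(ValueError, match="infeasible"):
            mx.build_problem(
                [_simple_source("A", -26.0), _simple_source("B", -12.0)],
                [mx.ProxyTarget("d13C_coll", -19.0, 0.5)],
                {},
                {"d13C_coll": {"protein": 0.5, "energy": 0.5}},
                priors=[mx.Constraint.at_least("A", 0.8), mx.Constraint.at_least("B", 0.8)],
            )

    def test_no_constraints_means_uniform_simplex_prior(self):
        problem = mx.build_problem(
            [_simple_source("A", -26.0), _simple_source("B", -12.0)],
            [mx.ProxyTarget("d13C_coll", -19.0, 0.5)],
            {},
            {"d13C_coll": {"protein": 0.5, "energy": 0.5}},
        )
        assert problem.satisfies(np.array([[1.0, 0.0], [0.0, 1.0]])).all()

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError, match="2 sources"):
            mx.build_problem(
                [_simple_source("A", -26.0)],
                [mx.ProxyTarget("d13C_coll", -19.0, 0.5)],
                {},
                {"d13C_coll": {"protein": 1.0}},
            )


class TestForwardModel:
    def test_single_source_with_zero_offset_returns_its_signal(self):
        s = mx.FoodSource("A", {"protein": {"d13C_coll": (-20.0, 0.1)}}, {"protein": (1.0, 0.0)})
        s2 = mx.FoodSource("B", {"protein": {"d13C_coll": (-20.0, 0.1)}}, {"protein": (1.0, 0.0)})
        problem = mx.build_problem(
            [s, s2], [mx.ProxyTarget("d13C_coll", -20.0, 0.5)], {}, {"d13C_coll": {"protein": 1.0}}
        )
        pred = mx.forward_model(np.array([1.0, 0.0]), problem)
        assert pred[0] == pytest.approx(-20.0)

    def test_equal_concentrations_give_arithmetic_mean(self):
        problem = mx.build_problem(
            [_simple_source("A", -26.0), _simple_source("B", -12.0)],
            [mx.ProxyTarget("d13C_coll", -19.0, 0.5)],
            {},
            {"d13C_coll": {"protein": 1.0}},
        )
        pred = mx.forward_model(np.array([0.5, 0.5]), problem)
        assert pred[0] == pytest.approx((-26.0 - 12.0) / 2)

    def test_concentration_weighted_mean_matches_hand_computation(self):
        a = _simple_source("A", -26.0, conc_protein=0.8)
        b = _simple_source("B", -12.0, conc_protein=0.2)
        problem = mx.build_problem(
            [a, b], [mx.ProxyTarget("d13C_coll", -19.0, 0.5)], {}, {"d13C_coll": {"protein": 1.0}}
        )
        alpha = np.array([0.5, 0.5])
        # hand evaluation: protein pool is 0.5*0.8 from A and 0.5*0.2 from B
        expected = (0.5 * 0.8 * -26.0 + 0.5 * 0.2 * -12.0) / (0.5 * 0.8 + 0.5 * 0.2)
        assert mx.forward_model(alpha, problem)[0] == pytest.approx(expected)

    def test_offset_added_to_prediction(self):
        problem = mx.build_problem(
            [_simple_source("A", -26.0), _simple_source("B", -12.0)],
            [mx.ProxyTarget("d13C_coll", -19.0, 0.5)],
            {"d13C_coll": (4.8, 0.5)},
            {"d13C_coll": {"protein": 1.0}},
        )
        assert mx.forward_model(np.array([1.0, 0.0]), problem)[0] == pytest.approx(-26.0 + 4.8)

    def test_whole_diet_routing_is_caloric_share_weighted(self):
        a = _simple_source("A", -26.0, conc_protein=0.8)
        b = _simple_source("B", -12.0, conc_protein=0.2)
        problem = mx.build_problem(
            [a, b], [mx.ProxyTarget("d13C_coll", -19.0, 0.5)], {}, {"d13C_coll": mx.WHOLE_DIET}
        )
        alpha = np.array([0.5, 0.5])
        # every (source, fraction) calorie stream contributes its own signal
        expected = 0.5 * (0.8 * -26.0 + 0.2 * -27.0) + 0.5 * (0.2 * -12.0 + 0.8 * -13.0)
        assert mx.forward_model(alpha, problem)[0] == pytest.approx(expected)


class TestSamplePosterior:
    def test_single_source_posterior_is_degenerate_at_one(self):
        s = mx.FoodSource("only", {"protein": {"d13C_coll": (-20.0, 0.1)}}, {"protein": (1.0, 0.0)})
        problem = mx.MixingProblem(
            sources=[s],
            proxies=[mx.ProxyTarget("d13C_coll", -20.0, 0.5)],
            offsets={},
            routing={"d13C_coll": {"protein": 1.0}},
        )
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=1, iterations=100, burn_in=10))
        assert np.all(post.draws == 1.0)

    def test_two_source_recovery_within_monte_carlo_error(self, two_source_problem):
        problem, true_alpha = two_source_problem
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=7))
        mean = post.draws[:, 0].mean()
        mcse = post.draws[:, 0].std(ddof=1) / np.sqrt(float(post.ess[0]))
        assert abs(mean - true_alpha) < 3 * max(mcse, 1e-4)

    def test_draws_on_simplex(self, two_source_problem):
        problem, _ = two_source_problem
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=2, iterations=500, burn_in=300))
        assert np.all(post.draws >= 0)
        np.testing.assert_allclose(post.draws.sum(axis=1), 1.0, atol=1e-9)

    def test_all_draws_satisfy_declared_constraints(self):
        problem = mx.build_problem(
            mx.default_sources(),
            [mx.ProxyTarget("d13C_coll", -19.0, 0.7), mx.ProxyTarget("d15N", 10.0, 1.0)],
            mx.default_offsets(),
            mx.default_routing(),
            priors=[
                mx.Constraint.at_least("C3 plants", 0.3),
                mx.Constraint.at_most("marine fish", 0.2),
            ],
        )
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=3, iterations=800, burn_in=800))
        assert problem.satisfies(post.draws).all()

    def test_seed_determinism(self, two_source_problem):
        problem, _ = two_source_problem
        settings = mx.McmcSettings(seed=11, iterations=400, burn_in=200)
        a = mx.sample_posterior(problem, settings)
        b = mx.sample_posterior(problem, settings)
        np.testing.assert_array_equal(a.chain_draws, b.chain_draws)

    def test_posterior_predictive_covers_targets(self):
        problem = default_problem_for_synthesis()
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=5))
        pred = mx.forward_model(post.draws[::50], problem).mean(axis=0)
        # combined uncertainty: target sd plus offset sd, generously 3x
        tol = 3.0 * np.sqrt(problem.target_sd**2 + problem.offset_sd**2)
        assert np.all(np.abs(pred - problem.target_mean) < tol)


class TestSummaries:
    def test_degenerate_posterior_has_zero_width_intervals(self):
        post = mx.DietPosterior(
            source_names=["a", "b"],
            chain_draws=np.tile([0.25, 0.75], (2, 10, 1)),
            rhat=np.ones(2),
            ess=np.full(2, 20.0),
            accept_rate=1.0,
            settings=mx.McmcSettings(seed=0),
        )
        summary = mx.summarize_posterior(post)
        assert summary.loc["a", "ci95_low"] == summary.loc["a", "ci95_high"] == 0.25

    def test_quantiles_match_sorted_order_oracle(self):
        draws = np.array([[v, 1 - v] for v in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)])
        post = mx.DietPosterior(
            source_names=["a", "b"],
            chain_draws=draws[None],
            rhat=np.ones(2),
            ess=np.full(2, 10.0),
            accept_rate=1.0,
            settings=mx.McmcSettings(seed=0),
        )
        summary = mx.summarize_posterior(post)
        vals = draws[:, 0]
        assert summary.loc["a", "median"] == pytest.approx(np.quantile(vals, 0.5))
        assert summary.loc["a", "ci68_low"] == pytest.approx(np.quantile(vals, 0.16))
        assert summary.loc["a", "ci95_high"] == pytest.approx(np.quantile(vals, 0.975))
        # 68% interval nested inside 95%
        assert summary.loc["a", "ci95_low"] <= summary.loc["a", "ci68_low"]
        assert summary.loc["a", "ci68_high"] <= summary.loc["a", "ci95_high"]

    def test_macronutrient_split_reported_with_problem(self, two_source_problem):
        problem, _ = two_source_problem
        post = mx.sample_posterior(problem, mx.McmcSettings(seed=4, iterations=300, burn_in=200))
        summary = mx.summarize_posterior(post, problem)
        assert "protein" in summary.index
        assert set(summary["kind"]) == {"source", "macronutrient"}
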