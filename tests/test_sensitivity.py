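"""Moment matching, tornado analysis, PSA, CEAC, and scatter fractions."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea.econ_eval import icer
from markovcea.markov_engine import evaluate_strategies
from markovcea.parameters import LIVING_STATES, ModelConfig, StrategyParams
from markovcea.sensitivity import (
    FeasibilityError,
    PsaSpec,
    acceptance_fraction,
    beta_params_from_moments,
    ceac,
    default_wtp_grid,
    gamma_params_from_moments,
    run_owsa,
    run_psa,
    scatter_frame,
)


def _degenerate(strategies):
    """Strategy copies with every utility SD zeroed (spike distributions)."""
    return [
        StrategyParams(
            s.name,
            s.annual_costs,
            {st_: (m, 0.0) for st_, (m, _) in s.state_utilities.items()},
            s.response_distribution,
        )
        for s in strategies
    ]


class TestMomentMatching:
    def test_uniform_beta(self):
        alpha, beta = beta_params_from_moments(0.5, np.sqrt(1 / 12))
        assert alpha == pytest.approx(1.0, rel=1e-9)
        assert beta == pytest.approx(1.0, rel=1e-9)

    def test_infliximab_remission_utility(self):
        # moment-matching closed form at the reported (0.836, 0.196)
        alpha, beta = beta_params_from_moments(0.836, 0.196)
        assert alpha == pytest.approx(2.148, abs=0.001)
        assert beta == pytest.approx(0.421, abs=0.001)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        mean=st.floats(0.05, 0.95),
        cv=st.floats(0.05, 0.5),
    )
    def test_beta_round_trip_recovers_moments(self, mean, cv):
        sd = cv * np.sqrt(mean * (1 - mean))  # always feasible
        alpha, beta = beta_params_from_moments(mean, sd)
        total = alpha + beta
        assert alpha / total == pytest.approx(mean, rel=1e-9)
        var = alpha * beta / (total**2 * (total + 1))
        assert np.sqrt(var) == pytest.approx(sd, rel=1e-9)

    def test_beta_infeasible_sd_instructs_shrinkage(self):
        with pytest.raises(FeasibilityError, match="shrink"):
            beta_params_from_moments(0.5, 0.6)

    def test_beta_degenerate_mean_rejected(self):
        with pytest.raises(FeasibilityError):
            beta_params_from_moments(1.0, 0.1)

    def test_gamma_closed_form(self):
        assert gamma_params_from_moments(100.0, 10.0) == (100.0, 1.0)

    def test_gamma_medication_cost_under_default_cv(self):
        mean = 7110.39
        shape, rate = gamma_params_from_moments(mean, 0.2 * mean)
        assert shape == pytest.approx(25.0, rel=1e-12)
        assert rate == pytest.approx(25.0 / mean, rel=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(mean=st.floats(0.1, 1e6), cv=st.floats(0.01, 2.0))
    def test_gamma_round_trip_is_algebraic_identity(self, mean, cv):
        sd = cv * mean
        shape, rate = gamma_params_from_moments(mean, sd)
        assert shape / rate == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(shape) / rate == pytest.approx(sd, rel=1e-12)

    def test_gamma_nonpositive_rejected(self):
        with pytest.raises(FeasibilityError):
            gamma_params_from_moments(0.0, 1.0)

    def test_sampled_moments_recover_inputs(self):
        # sampling oracle: empirical moments at large n within 3 MC standard
        # errors of the matched inputs
        rng = np.random.default_rng(2024)
        n = 200_000
        mean, sd = 0.73, 0.15
        alpha, beta = beta_params_from_moments(mean, sd)
        draws = rng.beta(alpha, beta, n)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(n)
        shape, rate = gamma_params_from_moments(5000.0, 1000.0)
        gdraws = rng.gamma(shape, 1 / rate, n)
        assert abs(gdraws.mean() - 5000.0) < 3 * 1000.0 / np.sqrt(n)


class TestOwsa:
    def test_entries_sorted_by_descending_width(self, study):
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_base_icer_identical_across_entries(self, study):
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        assert len({e.base_icer for e in entries}) == 1

    def test_inert_zero_cost_component_has_zero_width(self, study):
        # Adalimumab's injection cost is 0: scaling it by ±20% changes nothing
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        inert = next(
            e for e in entries if e.strategy == "Adalimumab" and e.target == "injection"
        )
        assert inert.width == 0.0
        assert inert.low_icer == inert.high_icer == inert.base_icer

    def test_comparator_remission_utility_among_top_entries(self, study):
        # rank property: the comparator's remission-state utility is one of
        # the more influential parameters of the Infliximab-vs-Adalimumab ICER
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        top_half = entries[: len(entries) // 2]
        assert any(
            e.strategy == "Adalimumab" and e.kind == "utility" and e.target == "Remission"
            for e in top_half
        )

    def test_width_matches_brute_force_reevaluation(self, study):
        # re-run oracle: perturb the parameter set directly and re-evaluate
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        entry = next(
            e for e in entries if e.strategy == "Infliximab" and e.target == "medication"
        )
        by_name = {s.name: s for s in strategies}
        expected = []
        for factor in (0.8, 1.2):
            ifx = by_name["Infliximab"]
            perturbed = StrategyParams(
                ifx.name,
                {**ifx.annual_costs, "medication": factor * ifx.annual_costs["medication"]},
                ifx.state_utilities,
                ifx.response_distribution,
            )
            results = {
                r.strategy: r
                for r in evaluate_strategies(tm, [perturbed, by_name["Adalimumab"]], cfg)
            }
            expected.append(
                icer(
                    results["Infliximab"].total_cost,
                    results["Adalimumab"].total_cost,
                    results["Infliximab"].total_qaly,
                    results["Adalimumab"].total_qaly,
                )
            )
        assert entry.low_icer == pytest.approx(expected[0], rel=1e-12)
        assert entry.high_icer == pytest.approx(expected[1], rel=1e-12)

    def test_linear_cost_endpoints_are_collinear_with_base(self, study):
        # a cost component enters the totals linearly, so the ±20% ICERs
        # are symmetric about the base value
        cfg, strategies, tm = study
        entries = run_owsa(tm, strategies, cfg, ("Infliximab", "Adalimumab"))
        entry = next(
            e for e in entries if e.kind == "cost" and e.strategy == "Infliximab"
            and e.target == "medication"
        )
        assert (entry.high_icer + entry.low_icer) / 2 == pytest.approx(
            entry.base_icer, rel=1e-9
        )

    def test_unknown_comparator_rejected(self, study):
        cfg, strategies, tm = study
        with pytest.raises(ValueError, match="Rituximab"):
            run_owsa(tm, strategies, cfg, ("Infliximab", "Rituximab"))


class TestPsa:
    def test_same_seed_is_bit_identical(self, study):
        cfg, strategies, tm = study
        spec = PsaSpec(n_draws=200, seed=11)
        a = run_psa(spec, tm, strategies, cfg)
        b = run_psa(spec, tm, strategies, cfg)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_different_seed_changes_draws(self, study):
        cfg, strategies, tm = study
        a = run_psa(PsaSpec(n_draws=50, seed=1), tm, strategies, cfg)
        b = run_psa(PsaSpec(n_draws=50, seed=2), tm, strategies, cfg)
        assert not np.array_equal(a.costs, b.costs)

    def test_degenerate_distributions_reproduce_deterministic_results_exactly(
        self, study
    ):
        cfg, strategies, tm = study
        degenerate = _degenerate(strategies)
        psa = run_psa(PsaSpec(n_draws=20, seed=3, cost_cv=0.0), tm, degenerate, cfg)
        deterministic = evaluate_strategies(tm, degenerate, cfg)
        for j, result in enumerate(deterministic):
            assert np.all(psa.costs[:, j] == result.total_cost)
            assert np.all(psa.qalys[:, j] == result.total_qaly)

    def test_mean_draw_cost_near_deterministic_base(self, study):
        # law of large numbers: the PSA cost mean approaches the
        # deterministic total within 3 standard errors
        cfg, strategies, tm = study
        psa = run_psa(PsaSpec(n_draws=4000, seed=5), tm, strategies, cfg)
        deterministic = evaluate_strategies(tm, strategies, cfg)
        for j, result in enumerate(deterministic):
            se = psa.costs[:, j].std(ddof=1) / np.sqrt(psa.n_draws)
            assert abs(psa.costs[:, j].mean() - result.total_cost) < 3 * se

    def test_all_draws_finite_and_nonnegative(self, study):
        cfg, strategies, tm = study
        psa = run_psa(PsaSpec(n_draws=500, seed=8), tm, strategies, cfg)
        assert np.all(np.isfinite(psa.costs)) and np.all(psa.costs >= 0)
        assert np.all(np.isfinite(psa.qalys)) and np.all(psa.qalys >= 0)

    def test_infeasible_utility_sd_is_shrunk_with_warning(self, study):
        cfg, strategies, tm = study
        s = strategies[0]
        utilities = dict(s.state_utilities)
        utilities["Remission"] = (0.9, 0.5)  # beyond sqrt(0.9 * 0.1)
        bad = StrategyParams(s.name, s.annual_costs, utilities, s.response_distribution)
        with pytest.warns(UserWarning, match="shrunk"):
            run_psa(PsaSpec(n_draws=10, seed=0), tm, [bad], cfg)


@pytest.fixture(scope="module")
def psa(study):
    cfg, strategies, tm = study
    return run_psa(PsaSpec(n_draws=1000, seed=17), tm, strategies, cfg)


class TestCeacAndScatter:
    def test_probabilities_sum_to_one(self, study, psa):
        cfg, _, _ = study
        curve = ceac(psa, default_wtp_grid(cfg))
        np.testing.assert_allclose(curve.prob_optimal.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(curve.prob_optimal >= 0) and np.all(curve.prob_optimal <= 1)

    def test_single_strategy_has_probability_one(self, study):
        cfg, strategies, tm = study
        solo = run_psa(PsaSpec(n_draws=100, seed=1), tm, strategies[:1], cfg)
        curve = ceac(solo, [0.0, 12547.0, 40000.0])
        np.testing.assert_array_equal(curve.prob_optimal, 1.0)

    def test_zero_wtp_rewards_the_cheapest_draw(self, psa):
        curve = ceac(psa, [0.0])
        recount = np.bincount(
            np.argmin(psa.costs, axis=1), minlength=len(psa.strategies)
        ) / psa.n_draws
        np.testing.assert_allclose(curve.prob_optimal[0], recount, atol=1e-12)

    def test_curve_matches_per_draw_argmax_recount(self, psa):
        wtp = 12547.0
        curve = ceac(psa, [wtp])
        nmb = psa.qalys * wtp - psa.costs
        recount = np.bincount(
            np.argmax(nmb, axis=1), minlength=len(psa.strategies)
        ) / psa.n_draws
        # ties are measure-zero here, so the strict recount agrees
        np.testing.assert_allclose(curve.prob_optimal[0], recount, atol=1e-12)

    def test_max_qaly_strategy_gains_at_large_wtp(self, psa):
        grid = np.array([0.0, 1e9])
        curve = ceac(psa, grid)
        j = int(np.argmax(psa.qalys.mean(axis=0)))
        assert curve.prob_optimal[1, j] >= curve.prob_optimal[0, j]

    def test_acceptance_fraction_matches_recount(self, psa):
        wtp = 12547.0
        a, b = psa.strategies[0], psa.strategies[1]
        frac = acceptance_fraction(psa, a, b, wtp)
        ja, jb = psa.column(a), psa.column(b)
        recount = np.mean(
            (psa.qalys[:, ja] - psa.qalys[:, jb]) * wtp
            - (psa.costs[:, ja] - psa.costs[:, jb])
            > 0
        )
        assert frac == recount
        assert scatter_frame(psa, a, b, wtp)["accepted"].mean() == recount

    def test_identical_strategies_never_accepted_under_strict_rule(self, study):
        cfg, strategies, tm = study
        s = strategies[0]
        twin = dataclasses.replace(s, name="Twin")
        psa = run_psa(PsaSpec(n_draws=100, seed=9, cost_cv=0.0), tm, [_degenerate([s])[0], _degenerate([twin])[0]], cfg)
        assert acceptance_fraction(psa, s.name, "Twin", 12547.0) == 0.0

    def test_strict_domination_in_every_draw_gives_one(self, study):
        cfg, strategies, tm = study
        s = _degenerate(strategies)[0]
        worse = StrategyParams(
            "Worse",
            {k: v * 2 for k, v in s.annual_costs.items()},
            {k: (m / 2, 0.0) for k, (m, _) in s.state_utilities.items()},
            s.response_distribution,
        )
        psa = run_psa(PsaSpec(n_draws=50, seed=4, cost_cv=0.0), tm, [s, worse], cfg)
        assert acceptance_fraction(psa, s.name, "Worse", 12547.0) == 1.0

    def test_unknown_strategy_rejected(self, psa):
        with pytest.raises(ValueError, match="unknown strategy"):
            acceptance_fraction(psa, "Nope", psa.strategies[0], 1000.0)

    def test_default_grid_contains_the_gdp_threshold(self, study):
        cfg, _, _ = study
        grid = default_wtp_grid(cfg)
        assert 12547.0 in grid
        assert grid[0] == 0.0 and grid[-1] == pytest.approx(3 * 12547.0)
        assert np.all(np.diff(grid) > 0)
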