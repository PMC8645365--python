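"""Sensitivity analyses: one-way (±20%) tornado and probabilistic (PSA).

One-way analysis re-evaluates the pairwise ICER with each cost component
and each state-utility mean set to 0.8x and 1.2x of its base value, all
other parameters held fixed, and orders the entries by tornado width.

The probabilistic analysis is a second-order Monte Carlo: each trial
draws one value for every utility parameter (beta distribution, moment-
matched to the reported mean/SD) and every cost parameter (gamma, with a
configurable coefficient of variation standing in for unreported cost
SDs), evaluates every strategy on the shared draw, and records discounted
(cost, QALY) pairs.  From these draws the cost-effectiveness
acceptability curve (probability of maximal net monetary benefit per
willingness-to-pay level) and pairwise scatter acceptance fractions are
computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .econ_eval import icer
from .markov_engine import cycle_cost_vector, run_cohort, state_weights
from .parameters import (
    COST_COMPONENTS,
    LIVING_STATES,
    ModelConfig,
    StrategyParams,
    TransitionMatrix,
)

__all__ = [
    "FeasibilityError",
    "OwsaEntry",
    "PsaSpec",
    "PsaResult",
    "CeacCurve",
    "beta_params_from_moments",
    "gamma_params_from_moments",
    "run_owsa",
    "owsa_frame",
    "run_psa",
    "ceac",
    "acceptance_fraction",
    "scatter_frame",
    "default_wtp_grid",
]


class FeasibilityError(ValueError):
    """Distribution moments are infeasible for the requested family."""


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters ``(alpha, beta)`` matching a mean and SD.

    Uses ``alpha = mean * nu``, ``beta = (1 - mean) * nu`` with
    ``nu = mean (1 - mean) / sd^2 - 1``; requires ``0 < mean < 1`` and
    ``0 < sd^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise FeasibilityError(f"beta mean must lie strictly in (0, 1), got {mean}")
    if sd <= 0.0:
        raise FeasibilityError(f"beta SD must be positive, got {sd}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise FeasibilityError(
            f"beta moments infeasible: sd^2 = {var:.6g} >= mean(1-mean) = {bound:.6g}; "
            f"shrink the SD below {np.sqrt(bound):.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma ``(shape, rate)`` matching a mean and SD: ``shape = mean^2/sd^2``,
    ``rate = mean/sd^2``."""
    if mean <= 0.0:
        raise FeasibilityError(f"gamma mean must be positive, got {mean}")
    if sd <= 0.0:
        raise FeasibilityError(f"gamma SD must be positive, got {sd}")
    var = sd * sd
    return mean * mean / var, mean / var


# ---------------------------------------------------------------------------
# Shared evaluation kernel


def _strategy_vectors(
    strategy: StrategyParams, cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(per-cycle state cost vector, state utility vector), each length 5."""
    costs = cycle_cost_vector(strategy, cfg)
    utils = np.array([strategy.state_utilities[s][0] for s in LIVING_STATES] + [0.0])
    return costs, utils


def _evaluate(
    costs: np.ndarray, utils: np.ndarray, w_cost: np.ndarray, w_qaly: np.ndarray
) -> tuple[float, float]:
    return float(np.dot(costs, w_cost)), float(np.dot(utils, w_qaly))


# ---------------------------------------------------------------------------
# One-way sensitivity analysis


@dataclass(frozen=True)
class OwsaEntry:
    """Tornado entry: the pairwise ICER at 0.8x and 1.2x of one parameter."""

    strategy: str
    kind: str  # "cost" | "utility"
    target: str  # cost component or living state
    low_icer: float
    high_icer: float
    base_icer: float

    @property
    def parameter(self) -> str:
        return f"{self.strategy}:{self.kind}:{self.target}"

    @property
    def width(self) -> float:
        return abs(self.high_icer - self.low_icer)


def run_owsa(
    tm: TransitionMatrix,
    strategies: Sequence[StrategyParams],
    cfg: ModelConfig,
    comparator: tuple[str, str],
    rel_change: float = 0.2,
) -> list[OwsaEntry]:
    """One-way sensitivity analysis of the ICER between a comparator pair.

    Every cost parameter and every state-utility mean of the two strategies
    is varied to ``1 - rel_change`` and ``1 + rel_change`` times its base
    value in turn; entries are returned sorted by descending tornado width
    (zero-influence parameters trail with zero width).  The ICER orientation
    is first-named vs. second-named strategy.
    """
    by_name = {s.name: s for s in strategies}
    for name in comparator:
        if name not in by_name:
            raise ValueError(f"unknown comparator strategy '{name}'")
    a_name, b_name = comparator

    trace = run_cohort(tm, cfg)
    w_cost, w_qaly = state_weights(trace, cfg)
    base = {name: _strategy_vectors(by_name[name], cfg) for name in comparator}

    def pair_icer(vectors: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> float:
        cost_a, qaly_a = _evaluate(*vectors[a_name], w_cost, w_qaly)
        cost_b, qaly_b = _evaluate(*vectors[b_name], w_cost, w_qaly)
        return icer(cost_a, cost_b, qaly_a, qaly_b)

    base_icer = pair_icer(base)

    entries: list[OwsaEntry] = []
    for name in comparator:
        strat = by_name[name]
        # cost parameters: the annual components under uniform allocation,
        # or the per-state cycle costs when that override is active
        if strat.state_cycle_costs is not None:
            cost_targets = [
                (state, i) for i, state in enumerate(LIVING_STATES)
            ]
            perturb_state_cost = True
        else:
            cost_targets = [(c, None) for c in COST_COMPONENTS if c in strat.annual_costs]
            perturb_state_cost = False

        for target, idx in cost_targets:
            endpoint_icers = []
            for factor in (1.0 - rel_change, 1.0 + rel_change):
                vectors = dict(base)
                costs, utils = base[name]
                if perturb_state_cost:
                    new_costs = costs.copy()
                    new_costs[idx] *= factor
                else:
                    base_value = strat.annual_costs[target]
                    new_total = strat.total_annual_cost + (factor - 1.0) * base_value
                    new_costs = np.zeros(5)
                    new_costs[:4] = new_total * cfg.cycle_length_years
                vectors[name] = (new_costs, utils)
                endpoint_icers.append(pair_icer(vectors))
            entries.append(
                OwsaEntry(name, "cost", target, endpoint_icers[0], endpoint_icers[1], base_icer)
            )

        for i, state in enumerate(LIVING_STATES):
            endpoint_icers = []
            for factor in (1.0 - rel_change, 1.0 + rel_change):
                vectors = dict(base)
                costs, utils = base[name]
                new_utils = utils.copy()
                new_utils[i] *= factor
                vectors[name] = (costs, new_utils)
                endpoint_icers.append(pair_icer(vectors))
            entries.append(
                OwsaEntry(name, "utility", state, endpoint_icers[0], endpoint_icers[1], base_icer)
            )

    entries.sort(key=lambda e: -e.width)
    return entries


def owsa_frame(entries: Sequence[OwsaEntry]) -> pd.DataFrame:
    """Tornado table as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "strategy": [e.strategy for e in entries],
            "kind": [e.kind for e in entries],
            "target": [e.target for e in entries],
            "low_icer": [e.low_icer for e in entries],
            "high_icer": [e.high_icer for e in entries],
            "base_icer": [e.base_icer for e in entries],
            "width": [e.width for e in entries],
        }
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PsaSpec:
    """Second-order Monte Carlo settings.

    ``cost_cv`` is the coefficient of variation assumed for gamma cost
    distributions (per-component SDs are not reported; 0.2 mirrors the
    one-way perturbation scale).  Utility SDs come from the strategy
    parameters; an SD at or beyond the beta feasibility bound is shrunk
    to 0.99x the bound with a warning.
    """

    n_draws: int = 5000
    seed: int = 0
    cost_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError(f"n_draws must be positive, got {self.n_draws}")
        if self.cost_cv < 0:
            raise ValueError(f"cost_cv must be nonnegative, got {self.cost_cv}")


@dataclass(frozen=True)
class PsaResult:
    """Per-draw discounted (cost, QALY) per strategy."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    seed: int
    spec: PsaSpec

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def column(self, strategy: str) -> int:
        try:
            return self.strategies.index(strategy)
        except ValueError:
            raise ValueError(
                f"unknown strategy '{strategy}'; have {list(self.strategies)}"
            ) from None

    def frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"draw": np.arange(self.n_draws)}
        for j, name in enumerate(self.strategies):
            data[f"cost_{name}"] = self.costs[:, j]
            data[f"qaly_{name}"] = self.qalys[:, j]
        return pd.DataFrame(data)


def _beta_or_degenerate(mean: float, sd: float, context: str) -> tuple[float, float] | None:
    """Feasible beta parameters, a shrunken-SD fallback, or None for sd == 0."""
    if sd == 0.0:
        return None
    if not 0.0 < mean < 1.0:
        raise FeasibilityError(
            f"{context}: utility mean {mean} with positive SD cannot be beta-distributed"
        )
    bound = np.sqrt(mean * (1.0 - mean))
    if sd >= bound:
        shrunk = 0.99 * bound
        warnings.warn(
            f"{context}: utility SD {sd:.4g} is beta-infeasible for mean {mean:.4g}; "
            f"shrunk to {shrunk:.4g}",
            UserWarning,
            stacklevel=3,
        )
        sd = shrunk
    return beta_params_from_moments(mean, sd)


def run_psa(
    spec: PsaSpec,
    tm: TransitionMatrix,
    strategies: Sequence[StrategyParams],
    cfg: ModelConfig,
) -> PsaResult:
    """Second-order Monte Carlo over utility (beta) and cost (gamma) parameters.

    All distributions are validated before any sampling.  One seeded
    generator drives the run; parameters are sampled in lexicographic
    (strategy, parameter) order so results are bit-reproducible from the
    seed.  Each draw is evaluated with the same accumulation kernel as the
    deterministic model, on the shared cohort trace.
    """
    strategies = list(strategies)
    by_name = {s.name: s for s in strategies}
    if len(by_name) != len(strategies):
        raise ValueError("duplicate strategy names")

    # fail fast: resolve every distribution before sampling
    plans: dict[str, dict] = {}
    for name in sorted(by_name):
        s = by_name[name]
        cost_plan: list[tuple[str, float, tuple[float, float] | None]] = []
        if s.state_cycle_costs is not None:
            cost_items = [(st, s.state_cycle_costs[st]) for st in sorted(s.state_cycle_costs)]
        else:
            cost_items = [(c, s.annual_costs[c]) for c in sorted(s.annual_costs)]
        for target, mean in cost_items:
            sd = spec.cost_cv * mean
            params = gamma_params_from_moments(mean, sd) if mean > 0 and sd > 0 else None
            cost_plan.append((target, mean, params))
        util_plan = []
        for state in sorted(LIVING_STATES):
            mean, sd = s.state_utilities[state]
            params = _beta_or_degenerate(mean, sd, f"strategy '{name}', state '{state}'")
            util_plan.append((state, mean, params))
        plans[name] = {"cost": cost_plan, "utility": util_plan}

    rng = np.random.default_rng(spec.seed)
    n = spec.n_draws
    samples: dict[str, dict] = {}
    for name in sorted(by_name):
        cost_draws: dict[str, np.ndarray] = {}
        for target, mean, params in plans[name]["cost"]:
            if params is None:
                cost_draws[target] = np.full(n, mean)
            else:
                shape, rate = params
                cost_draws[target] = rng.gamma(shape, 1.0 / rate, size=n)
        util_draws: dict[str, np.ndarray] = {}
        for state, mean, params in plans[name]["utility"]:
            if params is None:
                util_draws[state] = np.full(n, mean)
            else:
                alpha, beta = params
                util_draws[state] = rng.beta(alpha, beta, size=n)
        samples[name] = {"cost": cost_draws, "utility": util_draws}

    trace = run_cohort(tm, cfg)
    w_cost, w_qaly = state_weights(trace, cfg)

    costs_out = np.empty((n, len(strategies)))
    qalys_out = np.empty((n, len(strategies)))
    for j, s in enumerate(strategies):
        draw = samples[s.name]
        state_costs = np.zeros((n, 5))
        if s.state_cycle_costs is not None:
            for i, state in enumerate(LIVING_STATES):
                state_costs[:, i] = draw["cost"][state]
        else:
            # sum in annual_costs key order: bit-identical to the
            # deterministic total when every draw is degenerate
            annual_total = sum(draw["cost"][c] for c in s.annual_costs)
            per_cycle = annual_total * cfg.cycle_length_years
            state_costs[:, :4] = per_cycle[:, None]
        utils = np.zeros((n, 5))
        for i, state in enumerate(LIVING_STATES):
            utils[:, i] = draw["utility"][state]
        # same np.dot kernel as the deterministic evaluation, per draw
        for k in range(n):
            costs_out[k, j] = np.dot(state_costs[k], w_cost)
            qalys_out[k, j] = np.dot(utils[k], w_qaly)

    return PsaResult(
        strategies=tuple(s.name for s in strategies),
        costs=costs_out,
        qalys=qalys_out,
        seed=spec.seed,
        spec=spec,
    )


@dataclass(frozen=True)
class CeacCurve:
    """Cost-effectiveness acceptability curve.

    ``prob_optimal[i, j]``: fraction of draws in which strategy ``j`` has
    the maximal net monetary benefit at ``wtp_grid[i]`` (ties split equally).
    """

    wtp_grid: np.ndarray
    strategies: tuple[str, ...]
    prob_optimal: np.ndarray

    def frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"wtp": self.wtp_grid}
        for j, name in enumerate(self.strategies):
            data[name] = self.prob_optimal[:, j]
        return pd.DataFrame(data)

    def probability_at(self, strategy: str, wtp: float) -> float:
        j = list(self.strategies).index(strategy)
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.prob_optimal[i, j])


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> CeacCurve:
    """Probability each strategy is optimal (max NMB) across the WTP grid."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("wtp_grid must be ascending")
    prob = np.empty((grid.size, len(psa.strategies)))
    for i, wtp in enumerate(grid):
        nmb = psa.qalys * wtp - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        prob[i] = weights.mean(axis=0)
    return CeacCurve(grid, psa.strategies, prob)


def acceptance_fraction(
    psa: PsaResult, strategy_a: str, strategy_b: str, wtp: float
) -> float:
    """Fraction of draws in which ``a`` beats ``b`` at the threshold.

    A draw is accepted when the incremental net monetary benefit is strictly
    positive: ``(qaly_a - qaly_b) * wtp - (cost_a - cost_b) > 0``; exact ties
    are not accepted.
    """
    ja, jb = psa.column(strategy_a), psa.column(strategy_b)
    inc_nmb = (psa.qalys[:, ja] - psa.qalys[:, jb]) * wtp - (
        psa.costs[:, ja] - psa.costs[:, jb]
    )
    return float(np.mean(inc_nmb > 0.0))


def scatter_frame(
    psa: PsaResult, strategy_a: str, strategy_b: str, wtp: float
) -> pd.DataFrame:
    """Incremental scatter data of ``a`` vs ``b``: per-draw deltas and acceptance flag."""
    ja, jb = psa.column(strategy_a), psa.column(strategy_b)
    d_cost = psa.costs[:, ja] - psa.costs[:, jb]
    d_qaly = psa.qalys[:, ja] - psa.qalys[:, jb]
    return pd.DataFrame(
        {
            "draw": np.arange(psa.n_draws),
            "delta_cost": d_cost,
            "delta_qaly": d_qaly,
            "accepted": (d_qaly * wtp - d_cost > 0.0).astype(int),
        }
    )


def default_wtp_grid(cfg: ModelConfig, n_points: int = 100) -> np.ndarray:
    """WTP grid from 0 to 3x GDP, always containing the 1x GDP threshold."""
    high = max(cfg.wtp_multipliers) * cfg.gdp_per_capita
    grid = np.linspace(0.0, high, n_points)
    return np.unique(np.append(grid, cfg.gdp_per_capita))
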