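"""Markov cohort engine: occupancy traces and discounted cost/QALY totals.

The cohort is propagated as an expectation: the occupancy row at cycle
``t + 1`` is the row at ``t`` right-multiplied by the transition matrix.
Rewards are attributed to the occupancy at the *start* of each cycle
(optionally averaged with the next row when half-cycle correction is on),
and discounted continuously in elapsed years ``cycle * cycle_length``, so
annual rates are exact at year boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    LIVING_STATES,
    ROW_SUM_TOL,
    STATES,
    ModelConfig,
    StrategyParams,
    TransitionMatrix,
)

__all__ = [
    "EARLY_STOP_LIVING_MASS",
    "CohortTrace",
    "EvalResult",
    "run_cohort",
    "discount_factor",
    "state_weights",
    "cycle_cost_vector",
    "accumulate_outcomes",
    "evaluate_strategy",
    "evaluate_strategies",
]

#: Propagation stops early once the living mass falls below this value;
#: at that point further cycles contribute nothing measurable.
EARLY_STOP_LIVING_MASS = 1e-9


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy of the cohort.

    ``occupancy`` has one row per cycle boundary (row 0 is the initial
    distribution), columns in :data:`~markovcea.parameters.STATES` order.
    Rows are probability vectors and the Death column is non-decreasing.
    """

    occupancy: np.ndarray
    cycle_length_years: float = 0.25

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 5 or occ.shape[0] < 1:
            raise ValueError(f"occupancy must be (n_cycles+1, 5), got shape {occ.shape}")
        sums = occ.sum(axis=1)
        bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            t = int(bad[0, 0])
            raise ValueError(f"occupancy row {t} sums to {sums[t]:.12g}, expected 1")
        death = occ[:, 4]
        if np.any(np.diff(death) < -1e-12):
            raise ValueError("Death occupancy must be non-decreasing")
        occ = occ.copy()
        occ.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(self.occupancy.shape[0])

    @property
    def elapsed_years(self) -> np.ndarray:
        return self.cycles * self.cycle_length_years

    def to_frame(
        self,
        discount_rate_costs: float | None = None,
        discount_rate_outcomes: float | None = None,
    ) -> pd.DataFrame:
        """Trace as a table: cycle, elapsed years, occupancies, discount factors."""
        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "cycle", self.cycles)
        frame.insert(1, "elapsed_years", self.elapsed_years)
        if discount_rate_costs is not None:
            frame["cost_discount_factor"] = discount_factor(
                self.cycles, discount_rate_costs, self.cycle_length_years
            )
        if discount_rate_outcomes is not None:
            frame["outcome_discount_factor"] = discount_factor(
                self.cycles, discount_rate_outcomes, self.cycle_length_years
            )
        return frame


@dataclass(frozen=True)
class EvalResult:
    """Discounted totals for one strategy: the operands of the ICER."""

    strategy: str
    total_cost: float
    total_qaly: float


def run_cohort(tm: TransitionMatrix, cfg: ModelConfig) -> CohortTrace:
    """Propagate the cohort through the transition matrix.

    Stops at ``cfg.max_cycles`` or earlier once the living mass drops below
    :data:`EARLY_STOP_LIVING_MASS`.
    """
    x = np.asarray(cfg.initial_distribution, dtype=float)
    rows = [x]
    for _ in range(cfg.max_cycles):
        if x[:4].sum() < EARLY_STOP_LIVING_MASS:
            break
        x = x @ tm.probs
        rows.append(x)
    return CohortTrace(np.vstack(rows), cfg.cycle_length_years)


def discount_factor(cycle_index, annual_rate: float, cycle_length_years: float):
    """Discount factor ``(1 + r)^-(cycle * cycle_length_years)``.

    Accepts a scalar or array of cycle indices; indices must be >= 0.
    """
    idx = np.asarray(cycle_index)
    if np.any(idx < 0):
        raise ValueError("cycle_index must be nonnegative")
    out = (1.0 + annual_rate) ** (-(idx * cycle_length_years))
    return float(out) if np.isscalar(cycle_index) else out


def state_weights(trace: CohortTrace, cfg: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discounted per-state accumulation weights of a trace.

    Returns ``(w_cost, w_qaly)``, each of length 5.  For any per-cycle state
    cost vector ``c`` and utility vector ``u``, the discounted totals are the
    dot products ``c . w_cost`` and ``u . w_qaly`` — the single kernel shared
    by the deterministic evaluation and the sensitivity analyses, so that a
    degenerate probabilistic run reproduces the deterministic result exactly.

    ``w_cost[s] = sum_t occ[t, s] * df_cost(t)`` over reward rows
    ``t = 0..n_cycles-1`` (start-of-cycle attribution; adjacent-row averages
    when half-cycle correction is enabled), and
    ``w_qaly[s] = sum_t occ[t, s] * cycle_length * df_outcome(t)``.
    """
    occ = trace.occupancy
    n = trace.n_cycles
    if n == 0:
        return np.zeros(5), np.zeros(5)
    rows = occ[:-1]
    if cfg.half_cycle_correction:
        rows = 0.5 * (occ[:-1] + occ[1:])
    t = np.arange(n)
    df_cost = discount_factor(t, cfg.discount_rate_costs, cfg.cycle_length_years)
    df_out = discount_factor(t, cfg.discount_rate_outcomes, cfg.cycle_length_years)
    w_cost = rows.T @ df_cost
    w_qaly = (rows.T @ df_out) * cfg.cycle_length_years
    return w_cost, w_qaly


def cycle_cost_vector(strategy: StrategyParams, cfg: ModelConfig) -> np.ndarray:
    """Per-cycle cost by state (length 5; Death costs nothing).

    Default: the annual component total spread uniformly over living states,
    scaled to the cycle length.  A ``state_cycle_costs`` table on the
    strategy overrides the uniform allocation.
    """
    costs = np.zeros(5)
    if strategy.state_cycle_costs is not None:
        for i, state in enumerate(LIVING_STATES):
            if state not in strategy.state_cycle_costs:
                raise ValueError(
                    f"strategy '{strategy.name}': no cycle cost for living state '{state}'"
                )
            costs[i] = strategy.state_cycle_costs[state]
    else:
        costs[:4] = strategy.total_annual_cost * cfg.cycle_length_years
    return costs


def accumulate_outcomes(
    trace: CohortTrace, strategy: StrategyParams, cfg: ModelConfig
) -> EvalResult:
    """Discounted total cost and QALYs of a strategy over a trace."""
    for state in LIVING_STATES:
        if state not in strategy.state_utilities:
            raise ValueError(
                f"strategy '{strategy.name}': no utility for living state '{state}'"
            )
    w_cost, w_qaly = state_weights(trace, cfg)
    costs = cycle_cost_vector(strategy, cfg)
    utils = np.array(
        [strategy.state_utilities[s][0] for s in LIVING_STATES] + [0.0]
    )
    return EvalResult(
        strategy=strategy.name,
        total_cost=float(np.dot(costs, w_cost)),
        total_qaly=float(np.dot(utils, w_qaly)),
    )


def evaluate_strategy(
    tm: TransitionMatrix, strategy: StrategyParams, cfg: ModelConfig
) -> EvalResult:
    """Run the cohort and accumulate outcomes for a single strategy."""
    return accumulate_outcomes(run_cohort(tm, cfg), strategy, cfg)


def evaluate_strategies(
    tm: TransitionMatrix, strategies, cfg: ModelConfig
) -> list[EvalResult]:
    """Evaluate all strategies on the shared cohort trace.

    The trace depends only on the transition matrix and settings, so it is
    computed once.
    """
    trace = run_cohort(tm, cfg)
    return [accumulate_outcomes(trace, s, cfg) for s in strategies]
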