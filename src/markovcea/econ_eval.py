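"""Economic evaluation: ICERs, dominance ranking, WTP classification, NMB.

Strategies are ranked by ascending cost.  A strategy that costs more and
yields no more QALYs than another is *absolutely dominated* (weak
dominance — one tie plus one strict inequality — counts).  Among the
survivors, a strategy whose incremental cost-effectiveness ratio against
the previous survivor exceeds that of the next against itself is
*extendedly dominated* and removed; the rule is iterated until the ICER
sequence along the frontier is non-decreasing.  Verdicts against the
willingness-to-pay threshold follow the WHO convention: an ICER below
1x GDP per capita is highly cost-effective, below 3x cost-effective,
otherwise not cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .markov_engine import EvalResult
from .parameters import ModelConfig

__all__ = [
    "STATUS_REFERENCE",
    "STATUS_NONDOMINATED",
    "STATUS_ABS_DOMINATED",
    "STATUS_EXT_DOMINATED",
    "VERDICT_HIGHLY",
    "VERDICT_COST_EFFECTIVE",
    "VERDICT_NOT",
    "CeTableRow",
    "ThresholdDecision",
    "icer",
    "rank_strategies",
    "classify_icer",
    "net_monetary_benefit",
    "ce_table_frame",
]

STATUS_REFERENCE = "reference"
STATUS_NONDOMINATED = "nondominated"
STATUS_ABS_DOMINATED = "absolutely_dominated"
STATUS_EXT_DOMINATED = "extendedly_dominated"

VERDICT_HIGHLY = "highly_cost_effective"
VERDICT_COST_EFFECTIVE = "cost_effective"
VERDICT_NOT = "not_cost_effective"


def icer(cost_a: float, cost_b: float, outcome_a: float, outcome_b: float) -> float:
    """Incremental cost-effectiveness ratio ``(cost_a - cost_b) / (outcome_a - outcome_b)``.

    Equal outcomes leave the ratio undefined; ``nan`` is returned and the
    caller decides by cost alone.
    """
    d_outcome = outcome_a - outcome_b
    if d_outcome == 0.0:
        return math.nan
    return (cost_a - cost_b) / d_outcome


@dataclass(frozen=True)
class CeTableRow:
    """One strategy in the ranked cost-effectiveness table.

    Incrementals are taken against the previous frontier survivor for
    nondominated strategies, and against the reference for dominated ones.
    ``icer`` is ``None`` unless the row is nondominated and not the
    reference.  ``verdict`` is filled when a GDP threshold is supplied.
    """

    strategy: str
    cost: float
    qaly: float
    incr_cost: float
    incr_qaly: float
    icer: float | None
    status: str
    verdict: str | None = None


@dataclass(frozen=True)
class ThresholdDecision:
    """WTP classification of an ICER against GDP-multiple thresholds."""

    icer: float
    verdict: str


def _dominates(a: EvalResult, b: EvalResult) -> bool:
    """True iff ``a`` absolutely (weakly) dominates ``b``."""
    if a.total_cost < b.total_cost and a.total_qaly >= b.total_qaly:
        return True
    if a.total_cost == b.total_cost and a.total_qaly > b.total_qaly:
        return True
    # exact tie: the alphabetically first name survives (deterministic)
    if (
        a.total_cost == b.total_cost
        and a.total_qaly == b.total_qaly
        and a.strategy < b.strategy
    ):
        return True
    return False


def rank_strategies(
    results: Iterable[EvalResult], gdp: float | None = None
) -> list[CeTableRow]:
    """Rank strategies by cost and classify dominance.

    Returns one row per strategy in ascending-cost order: the cheapest
    nondominated strategy is the reference; each further frontier strategy
    carries a sequential ICER against the previous survivor; dominated
    strategies are labelled and carry incrementals against the reference.
    With ``gdp`` given, finite ICERs also receive a WTP verdict.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("rank_strategies needs at least 2 strategies")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate strategy names: {names}")

    ordered = sorted(results, key=lambda r: (r.total_cost, r.strategy))
    abs_dominated = {
        r.strategy
        for r in ordered
        if any(_dominates(other, r) for other in ordered if other is not r)
    }
    survivors = [r for r in ordered if r.strategy not in abs_dominated]

    # iterated extended-dominance pruning: remove any interior survivor whose
    # sequential ICER exceeds the next one, until the sequence is non-decreasing
    ext_dominated: set[str] = set()
    while len(survivors) >= 3:
        icers = [
            icer(
                survivors[i].total_cost,
                survivors[i - 1].total_cost,
                survivors[i].total_qaly,
                survivors[i - 1].total_qaly,
            )
            for i in range(1, len(survivors))
        ]
        removed = False
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                ext_dominated.add(survivors[i + 1].strategy)
                del survivors[i + 1]
                removed = True
                break
        if not removed:
            break

    reference = survivors[0]
    prev_on_frontier = {
        survivors[i].strategy: survivors[i - 1] for i in range(1, len(survivors))
    }

    rows: list[CeTableRow] = []
    for r in ordered:
        if r.strategy == reference.strategy:
            rows.append(
                CeTableRow(r.strategy, r.total_cost, r.total_qaly, 0.0, 0.0, None, STATUS_REFERENCE)
            )
            continue
        if r.strategy in abs_dominated or r.strategy in ext_dominated:
            status = STATUS_ABS_DOMINATED if r.strategy in abs_dominated else STATUS_EXT_DOMINATED
            rows.append(
                CeTableRow(
                    r.strategy,
                    r.total_cost,
                    r.total_qaly,
                    r.total_cost - reference.total_cost,
                    r.total_qaly - reference.total_qaly,
                    None,
                    status,
                )
            )
            continue
        prev = prev_on_frontier[r.strategy]
        ratio = icer(r.total_cost, prev.total_cost, r.total_qaly, prev.total_qaly)
        verdict = None
        if gdp is not None and math.isfinite(ratio):
            verdict = _classify(ratio, gdp, (1.0, 3.0))
        rows.append(
            CeTableRow(
                r.strategy,
                r.total_cost,
                r.total_qaly,
                r.total_cost - prev.total_cost,
                r.total_qaly - prev.total_qaly,
                ratio,
                STATUS_NONDOMINATED,
                verdict,
            )
        )
    return rows


def _classify(value: float, gdp: float, multipliers: Sequence[float]) -> str:
    low, high = sorted(multipliers)[0], sorted(multipliers)[-1]
    if value < low * gdp:
        return VERDICT_HIGHLY
    if value < high * gdp:
        return VERDICT_COST_EFFECTIVE
    return VERDICT_NOT


def classify_icer(value: float, cfg: ModelConfig) -> ThresholdDecision:
    """Classify a finite ICER against the configured GDP-multiple thresholds."""
    if not math.isfinite(value):
        raise ValueError(f"ICER must be finite for threshold classification, got {value}")
    return ThresholdDecision(
        icer=value,
        verdict=_classify(value, cfg.gdp_per_capita, cfg.wtp_multipliers),
    )


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit ``qaly * wtp - cost`` at a willingness-to-pay level."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be nonnegative, got {wtp}")
    return qaly * wtp - cost


def ce_table_frame(rows: Sequence[CeTableRow]) -> pd.DataFrame:
    """Ranked cost-effectiveness table as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "cost": [r.cost for r in rows],
            "qaly": [r.qaly for r in rows],
            "incr_cost": [r.incr_cost for r in rows],
            "incr_qaly": [r.incr_qaly for r in rows],
            "icer": [r.icer for r in rows],
            "status": [r.status for r in rows],
            "verdict": [r.verdict for r in rows],
        }
    )
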