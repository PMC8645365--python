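"""Synthetic patient-level data with the study's statistical structure.

The generator emulates what the underlying study collected per patient:
a treatment arm, a categorical DAS-28 outcome band, an EQ-5D-style
utility on [0, 1] drawn from the band's beta distribution, and annual
cost components drawn from gamma distributions.  Summaries aggregate an
arm back into table-style statistics (band counts/percentages, utility
mean/SD per band, cost category totals and shares), and
:func:`recover_parameters` closes the generate -> estimate loop so the
whole pipeline can be exercised on data whose generating truth is known.

Records live in a pandas DataFrame with columns ``arm``, ``das28_band``,
``utility`` and one ``cost_<component>`` column per cost component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    COST_CATEGORIES,
    COST_COMPONENTS,
    LIVING_STATES,
    StrategyParams,
)
from .sensitivity import (
    FeasibilityError,
    beta_params_from_moments,
    gamma_params_from_moments,
)

__all__ = [
    "ArmSummary",
    "ArmEstimate",
    "generate_cohort",
    "summarize_arm",
    "recover_parameters",
]

DEFAULT_COST_CV = 0.2


def _band_probabilities(strategy: StrategyParams) -> np.ndarray:
    counts = np.array(
        [strategy.response_distribution.get(b, 0) for b in LIVING_STATES], dtype=float
    )
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"strategy '{strategy.name}': empty response distribution")
    return counts / total

def _check_feasible(strategy: StrategyParams, cost_cv: float) -> None:
    for state, (mean, sd) in strategy.state_utilities.items():
        if sd > 0:
            beta_params_from_moments(mean, sd)  # raises FeasibilityError if infeasible
    for comp, mean in strategy.annual_costs.items():
        if mean > 0 and cost_cv > 0:
            gamma_params_from_moments(mean, cost_cv * mean)


def generate_cohort(
    arm_specs: Sequence[StrategyParams],
    seed: int,
    n_per_arm: int | Mapping[str, int] | None = None,
    cost_cv: float = DEFAULT_COST_CV,
) -> pd.DataFrame:
    """Draw a patient-level cohort from per-arm generating parameters.

    Per arm of size ``n`` (the arm's observed size unless overridden):
    bands come from the categorical response distribution, the utility from
    the band's beta (degenerate at the mean when the SD is 0), and each
    annual cost component from a gamma with SD ``cost_cv * mean``
    (degenerate at 0 or when ``cost_cv`` is 0).  All distribution moments
    are validated before any sampling; reproducible from the seed.
    """
    for s in arm_specs:
        _check_feasible(s, cost_cv)

    rng = np.random.default_rng(seed)
    frames = []
    for s in arm_specs:
        if n_per_arm is None:
            n = s.n
        elif isinstance(n_per_arm, Mapping):
            n = int(n_per_arm[s.name])
        else:
            n = int(n_per_arm)
        if n < 1:
            raise ValueError(f"arm '{s.name}': size must be positive, got {n}")

        p = _band_probabilities(s)
        band_idx = rng.choice(len(LIVING_STATES), size=n, p=p)
        bands = np.array(LIVING_STATES, dtype=object)[band_idx]

        utility = np.empty(n)
        for i, state in enumerate(LIVING_STATES):
            mask = band_idx == i
            if not mask.any():
                continue
            mean, sd = s.state_utilities[state]
            if sd == 0.0:
                utility[mask] = mean
            else:
                alpha, beta = beta_params_from_moments(mean, sd)
                utility[mask] = rng.beta(alpha, beta, size=int(mask.sum()))

        data: dict[str, object] = {"arm": s.name, "das28_band": bands, "utility": utility}
        for comp in COST_COMPONENTS:
            mean = float(s.annual_costs.get(comp, 0.0))
            sd = cost_cv * mean
            if mean == 0.0 or sd == 0.0:
                data[f"cost_{comp}"] = np.full(n, mean)
            else:
                shape, rate = gamma_params_from_moments(mean, sd)
                data[f"cost_{comp}"] = rng.gamma(shape, 1.0 / rate, size=n)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ArmSummary:
    """Table-style statistics of one arm.

    Percentages are rounded to 2 decimals (matching the study's reporting);
    ``utility_stats`` maps band -> (mean, sample SD with n-1 denominator);
    bands with a single record report SD 0 and appear in
    ``degenerate_bands``.  ``cost_totals`` satisfies
    DMC + DNMC + IC = total by construction; ``cost_shares`` gives each
    component's percentage of its category and each category's percentage
    of the total.
    """

    arm: str
    n: int
    band_counts: dict[str, int]
    band_percents: dict[str, float]
    utility_stats: dict[str, tuple[float, float]]
    cost_means: dict[str, float]
    cost_totals: dict[str, float]
    cost_shares: dict[str, float]
    category_shares: dict[str, float]
    degenerate_bands: tuple[str, ...]


def summarize_arm(records: pd.DataFrame, arm: str) -> ArmSummary:
    """Aggregate one arm's records into summary statistics."""
    sub = records[records["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no records for arm '{arm}'")
    n = len(sub)

    band_counts = {
        band: int((sub["das28_band"] == band).sum()) for band in LIVING_STATES
    }
    band_percents = {band: round(100.0 * c / n, 2) for band, c in band_counts.items()}

    utility_stats: dict[str, tuple[float, float]] = {}
    degenerate: list[str] = []
    for band, count in band_counts.items():
        if count == 0:
            continue
        values = sub.loc[sub["das28_band"] == band, "utility"]
        if count == 1:
            utility_stats[band] = (float(values.iloc[0]), 0.0)
            degenerate.append(band)
        else:
            utility_stats[band] = (float(values.mean()), float(values.std(ddof=1)))

    cost_means = {
        comp: float(sub[f"cost_{comp}"].mean()) for comp in COST_COMPONENTS
    }
    cost_totals = {
        cat: float(sum(cost_means[c] for c in comps))
        for cat, comps in COST_CATEGORIES.items()
    }
    cost_totals["total"] = sum(cost_totals.values())

    cost_shares: dict[str, float] = {}
    for cat, comps in COST_CATEGORIES.items():
        denom = cost_totals[cat]
        for comp in comps:
            cost_shares[comp] = round(100.0 * cost_means[comp] / denom, 2) if denom else 0.0
    category_shares = {
        cat: round(100.0 * cost_totals[cat] / cost_totals["total"], 2)
        for cat in COST_CATEGORIES
    }

    return ArmSummary(
        arm=arm,
        n=n,
        band_counts=band_counts,
        band_percents=band_percents,
        utility_stats=utility_stats,
        cost_means=cost_means,
        cost_totals=cost_totals,
        cost_shares=cost_shares,
        category_shares=category_shares,
        degenerate_bands=tuple(degenerate),
    )


@dataclass(frozen=True)
class ArmEstimate:
    """Parameters estimated from one arm's patient records.

    Bands with fewer than two records cannot support an SD estimate and are
    listed in ``flagged_bands`` rather than silently imputed;
    :meth:`as_strategy_params` refuses to build a parameter set while any
    band is flagged.
    """

    arm: str
    n: int
    band_counts: dict[str, int]
    utility_moments: dict[str, tuple[float, float]]
    cost_means: dict[str, float]
    flagged_bands: tuple[str, ...]

    def as_strategy_params(self) -> StrategyParams:
        """Estimated parameters, ready to feed back into the Markov/PSA pipeline."""
        if self.flagged_bands:
            raise ValueError(
                f"arm '{self.arm}': insufficient data to estimate band(s): "
                f"{', '.join(self.flagged_bands)}"
            )
        return StrategyParams(
            name=self.arm,
            annual_costs=dict(self.cost_means),
            state_utilities=dict(self.utility_moments),
            response_distribution=dict(self.band_counts),
        )


def recover_parameters(records: pd.DataFrame) -> dict[str, ArmEstimate]:
    """Estimate per-arm generating parameters from patient records.

    Band proportions come from the observed counts, utilities as (mean,
    sample SD), and cost components as means.  Clamp-free: estimates are
    reported as observed, so recovery of a zero-variance fixture is exact.
    """
    out: dict[str, ArmEstimate] = {}
    for arm in records["arm"].unique():
        sub = records[records["arm"] == arm]
        band_counts = {
            band: int((sub["das28_band"] == band).sum()) for band in LIVING_STATES
        }
        moments: dict[str, tuple[float, float]] = {}
        flagged: list[str] = []
        for band, count in band_counts.items():
            values = sub.loc[sub["das28_band"] == band, "utility"]
            if count < 2:
                flagged.append(band)
                if count == 1:
                    moments[band] = (float(values.iloc[0]), 0.0)
            else:
                sd = float(values.std(ddof=1))
                moments[band] = (float(values.mean()), sd)
        cost_means = {
            comp: float(sub[f"cost_{comp}"].mean()) for comp in COST_COMPONENTS
        }
        out[str(arm)] = ArmEstimate(
            arm=str(arm),
            n=len(sub),
            band_counts=band_counts,
            utility_moments=moments,
            cost_means=cost_means,
            flagged_bands=tuple(flagged),
        )
    return out
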