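"""Model parameters: domain types, validation, and configuration I/O.

The cost-utility model runs on five health states defined by DAS-28
disease-activity bands — Remission (DAS-28 < 2.6), Low (2.6–3.2),
Moderate (3.2–5.1), Severe (> 5.1) — plus an absorbing Death state.
Each treatment strategy carries an annual per-patient cost breakdown
(direct medical, direct non-medical, and indirect components in PPP $),
per-state utility moments on [0, 1], and the observed DAS-28 response
distribution of its trial arm.

Configuration is a single YAML (or JSON) document with ``model``,
``transition_matrix`` and ``strategies`` sections; the transition matrix
may alternatively be read from CSV.  The parameter set of the underlying
three-arm study (Infliximab, Adalimumab, Etanercept) ships as a bundled
fixture, see :func:`paper_params`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STATES",
    "LIVING_STATES",
    "DEATH_STATE",
    "DAS28_BANDS",
    "DIRECT_MEDICAL",
    "DIRECT_NONMEDICAL",
    "INDIRECT",
    "COST_COMPONENTS",
    "COST_CATEGORIES",
    "ConfigError",
    "HealthState",
    "TransitionMatrix",
    "StrategyParams",
    "ModelConfig",
    "validate_matrix",
    "load_config",
    "save_config",
    "config_to_dict",
    "load_transition_matrix_csv",
    "paper_params",
    "paper_reference_results",
]

#: Canonical state order used throughout the package.
STATES: tuple[str, ...] = ("Remission", "Low", "Moderate", "Severe", "Death")
LIVING_STATES: tuple[str, ...] = STATES[:-1]
DEATH_STATE = "Death"

#: DAS-28 band covered by each state ("n/a" for the absorbing state).
DAS28_BANDS: dict[str, str] = {
    "Remission": "DAS-28 < 2.6",
    "Low": "2.6 <= DAS-28 < 3.2",
    "Moderate": "3.2 <= DAS-28 <= 5.1",
    "Severe": "DAS-28 > 5.1",
    "Death": "n/a",
}

# Annual cost components, grouped by the societal-perspective category
# they belong to: direct medical (DMC), direct non-medical (DNMC) and
# indirect / productivity-loss (IC) costs.
DIRECT_MEDICAL: tuple[str, ...] = (
    "visits",
    "medication",
    "tests",
    "physiotherapy_other",
    "diagnostics",
    "injection",
)
DIRECT_NONMEDICAL: tuple[str, ...] = ("transportation", "accommodation", "meals")
INDIRECT: tuple[str, ...] = ("lost_revenue",)
COST_COMPONENTS: tuple[str, ...] = DIRECT_MEDICAL + DIRECT_NONMEDICAL + INDIRECT
COST_CATEGORIES: dict[str, tuple[str, ...]] = {
    "DMC": DIRECT_MEDICAL,
    "DNMC": DIRECT_NONMEDICAL,
    "IC": INDIRECT,
}

ROW_SUM_TOL = 1e-9
#: Printed category totals are allowed to differ from the component sum by
#: ordinary last-digit rounding; anything larger is flagged to the user.
PRINTED_TOTAL_TOL = 0.02

_PAPER_FIXTURE = "paper_params.yaml"


class ConfigError(ValueError):
    """A configuration document violates the schema or a type invariant."""


@dataclass(frozen=True)
class HealthState:
    """One model state: its label and the DAS-28 band it covers."""

    label: str
    das28_band: str

    def __post_init__(self) -> None:
        if self.label not in STATES:
            raise ConfigError(f"unknown health state {self.label!r}; expected one of {STATES}")

    @property
    def is_absorbing(self) -> bool:
        return self.label == DEATH_STATE


#: The five model states in canonical order.
HEALTH_STATES: tuple[HealthState, ...] = tuple(
    HealthState(label, DAS28_BANDS[label]) for label in STATES
)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 matrix of per-cycle transition probabilities.

    Rows are source states and columns destination states, in
    :data:`STATES` order.  The Death row must be exactly absorbing.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (5, 5):
            raise ConfigError(f"transition matrix must be 5x5, got shape {probs.shape}")
        if np.any(probs < 0.0) or np.any(probs > 1.0):
            bad = np.argwhere((probs < 0.0) | (probs > 1.0))[0]
            raise ConfigError(
                f"transition probability out of [0, 1] at row '{STATES[bad[0]]}', "
                f"column '{STATES[bad[1]]}': {probs[tuple(bad)]}"
            )
        sums = probs.sum(axis=1)
        for label, total in zip(STATES, sums):
            if abs(total - 1.0) > ROW_SUM_TOL:
                raise ConfigError(
                    f"transition row '{label}' sums to {total:.12g}, expected 1"
                )
        if not np.array_equal(probs[4], np.array([0.0, 0.0, 0.0, 0.0, 1.0])):
            raise ConfigError("Death row must be absorbing: (0, 0, 0, 0, 1)")
        probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def from_living_rows(cls, rows: Mapping[str, Sequence[float]]) -> "TransitionMatrix":
        """Build from the four living-state rows, appending the absorbing Death row."""
        probs = np.zeros((5, 5))
        for i, state in enumerate(LIVING_STATES):
            if state not in rows:
                raise ConfigError(f"transition matrix is missing row '{state}'")
            probs[i] = np.asarray(rows[state], dtype=float)
        probs[4, 4] = 1.0
        return cls(probs)

    @property
    def living_submatrix(self) -> np.ndarray:
        return self.probs[:4, :4]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(STATES), columns=list(STATES))


def validate_matrix(probs: Any) -> TransitionMatrix:
    """Validate a numeric 5x5 array as a transition matrix.

    Returns the :class:`TransitionMatrix` iff every entry is a probability,
    every row sums to 1 within ``1e-9`` and the Death row is absorbing;
    raises :class:`ConfigError` naming the offending row otherwise.
    """
    return TransitionMatrix(np.asarray(probs, dtype=float))


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of one treatment strategy (one trial arm).

    annual_costs
        PPP $ per patient-year for each cost component (see
        :data:`COST_COMPONENTS`).
    state_utilities
        ``(mean, sd)`` of the EQ-5D-style utility weight per living state,
        on [0, 1] per year of perfect health.
    response_distribution
        Observed patient count per DAS-28 band in the trial arm; the counts
        sum to the arm size :attr:`n`.
    state_cycle_costs
        Optional per-cycle cost per living state; when present it overrides
        the default uniform allocation of the annual total.
    printed_totals
        Optional externally reported category totals (DMC/DNMC/IC/total)
        kept for cross-checking against the component sums.
    """

    name: str
    annual_costs: Mapping[str, float]
    state_utilities: Mapping[str, tuple[float, float]]
    response_distribution: Mapping[str, int]
    state_cycle_costs: Mapping[str, float] | None = None
    printed_totals: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigError("strategy name must be non-empty")
        unknown = sorted(set(self.annual_costs) - set(COST_COMPONENTS))
        if unknown:
            raise ConfigError(
                f"strategy '{self.name}': unknown cost component(s): {', '.join(unknown)}"
            )
        for comp, value in self.annual_costs.items():
            if value < 0:
                raise ConfigError(
                    f"strategy '{self.name}': cost component '{comp}' is negative ({value})"
                )
        missing = [s for s in LIVING_STATES if s not in self.state_utilities]
        if missing:
            raise ConfigError(
                f"strategy '{self.name}': missing utility for state(s): {', '.join(missing)}"
            )
        unknown_u = sorted(set(self.state_utilities) - set(LIVING_STATES))
        if unknown_u:
            raise ConfigError(
                f"strategy '{self.name}': utility given for unknown state(s): {', '.join(unknown_u)}"
            )
        for state, (mean, sd) in self.state_utilities.items():
            if not 0.0 <= mean <= 1.0:
                raise ConfigError(
                    f"strategy '{self.name}': utility mean for '{state}' is {mean}, "
                    "must lie in [0, 1]"
                )
            if sd < 0:
                raise ConfigError(
                    f"strategy '{self.name}': utility SD for '{state}' is negative ({sd})"
                )
        unknown_b = sorted(set(self.response_distribution) - set(LIVING_STATES))
        if unknown_b:
            raise ConfigError(
                f"strategy '{self.name}': response count for unknown band(s): {', '.join(unknown_b)}"
            )
        for band, count in self.response_distribution.items():
            if count < 0 or int(count) != count:
                raise ConfigError(
                    f"strategy '{self.name}': response count for '{band}' must be a "
                    f"nonnegative integer, got {count}"
                )
        if self.state_cycle_costs is not None:
            for state, value in self.state_cycle_costs.items():
                if state not in LIVING_STATES:
                    raise ConfigError(
                        f"strategy '{self.name}': cycle cost for unknown state '{state}'"
                    )
                if value < 0:
                    raise ConfigError(
                        f"strategy '{self.name}': cycle cost for '{state}' is negative ({value})"
                    )

    @property
    def n(self) -> int:
        """Arm size: sum of the response-distribution counts."""
        return int(sum(self.response_distribution.values()))

    @property
    def total_annual_cost(self) -> float:
        return float(sum(self.annual_costs.values()))

    def category_totals(self) -> dict[str, float]:
        """Component sums per cost category plus the grand total."""
        out = {
            cat: float(sum(self.annual_costs.get(c, 0.0) for c in comps))
            for cat, comps in COST_CATEGORIES.items()
        }
        out["total"] = sum(out.values())
        return out

    def response_percents(self, decimals: int = 2) -> dict[str, float]:
        """Per-band response percentages of the arm, rounded as reported."""
        n = self.n
        if n == 0:
            raise ConfigError(f"strategy '{self.name}': empty response distribution")
        return {
            band: round(100.0 * count / n, decimals)
            for band, count in self.response_distribution.items()
        }

    def printed_total_mismatches(self, tol: float = PRINTED_TOTAL_TOL) -> dict[str, tuple[float, float]]:
        """Category totals whose component sum disagrees with the printed value.

        Returns ``{category: (component_sum, printed_value)}`` for every
        discrepancy larger than ``tol`` (PPP $).  An empty dict means the
        printed totals are consistent up to last-digit rounding.
        """
        if not self.printed_totals:
            return {}
        computed = self.category_totals()
        return {
            cat: (computed[cat], float(printed))
            for cat, printed in self.printed_totals.items()
            if cat in computed and abs(computed[cat] - float(printed)) > tol
        }


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings.

    Cycles are three months (0.25 years) by default; costs and outcomes
    are discounted at separate annual rates (5.8% and 3%).  The cohort
    starts in the Severe band — the DAS-28 > 5.1 threshold at which
    biologic therapy is initiated — and runs to ``max_cycles`` as a
    lifetime-horizon proxy.  ``gdp_per_capita`` with ``wtp_multipliers``
    (1x, 3x) defines the WHO-style willingness-to-pay bands.
    """

    cycle_length_years: float = 0.25
    discount_rate_costs: float = 0.058
    discount_rate_outcomes: float = 0.03
    max_cycles: int = 400
    initial_distribution: tuple[float, ...] = (0.0, 0.0, 0.0, 1.0, 0.0)
    half_cycle_correction: bool = False
    gdp_per_capita: float = 12547.0
    wtp_multipliers: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        if self.cycle_length_years <= 0:
            raise ConfigError(f"cycle_length_years must be positive, got {self.cycle_length_years}")
        for name in ("discount_rate_costs", "discount_rate_outcomes"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1), got {rate}")
        if self.max_cycles < 1:
            raise ConfigError(f"max_cycles must be a positive integer, got {self.max_cycles}")
        dist = tuple(float(x) for x in self.initial_distribution)
        if len(dist) != 5:
            raise ConfigError("initial_distribution must have 5 entries (one per state)")
        if any(x < 0 for x in dist):
            raise ConfigError("initial_distribution entries must be nonnegative")
        if abs(sum(dist) - 1.0) > ROW_SUM_TOL:
            raise ConfigError(f"initial_distribution sums to {sum(dist):.12g}, expected 1")
        if dist[4] != 0.0:
            raise ConfigError("initial_distribution must place no mass on Death")
        object.__setattr__(self, "initial_distribution", dist)
        object.__setattr__(self, "wtp_multipliers", tuple(float(m) for m in self.wtp_multipliers))

    @property
    def wtp_thresholds(self) -> tuple[float, ...]:
        """Willingness-to-pay thresholds in PPP $/QALY (GDP multiples)."""
        return tuple(m * self.gdp_per_capita for m in self.wtp_multipliers)


# ---------------------------------------------------------------------------
# Configuration parsing


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(unknown)}")


def _parse_model(section: Mapping[str, Any]) -> ModelConfig:
    if not isinstance(section, Mapping):
        raise ConfigError("'model' section must be a mapping")
    allowed = {
        "cycle_length_years",
        "discount_rate_costs",
        "discount_rate_outcomes",
        "max_cycles",
        "initial_distribution",
        "half_cycle_correction",
        "gdp_per_capita",
        "wtp_multipliers",
    }
    _check_keys(section, allowed, "'model' section")
    kwargs = dict(section)
    if "initial_distribution" in kwargs:
        dist = kwargs["initial_distribution"]
        if isinstance(dist, Mapping):
            _check_keys(dist, set(STATES), "'initial_distribution'")
            dist = tuple(float(dist.get(s, 0.0)) for s in STATES)
        kwargs["initial_distribution"] = tuple(float(x) for x in dist)
    if "wtp_multipliers" in kwargs:
        kwargs["wtp_multipliers"] = tuple(float(m) for m in kwargs["wtp_multipliers"])
    return ModelConfig(**kwargs)


def _parse_transition(section: Mapping[str, Any]) -> TransitionMatrix:
    if not isinstance(section, Mapping):
        raise ConfigError("'transition_matrix' section must be a mapping")
    _check_keys(section, {"states", "rows"}, "'transition_matrix' section")
    states = tuple(section.get("states", STATES))
    if states != STATES:
        raise ConfigError(
            f"'transition_matrix.states' must equal {list(STATES)}, got {list(states)}"
        )
    rows = section.get("rows")
    if not isinstance(rows, Mapping):
        raise ConfigError("'transition_matrix.rows' must map state labels to rows")
    _check_keys(rows, set(STATES), "'transition_matrix.rows'")
    for label, row in rows.items():
        if len(row) != 5:
            raise ConfigError(f"transition row '{label}' must have 5 entries, got {len(row)}")
    if DEATH_STATE in rows:
        probs = np.array([rows[s] for s in STATES], dtype=float)
        return TransitionMatrix(probs)
    return TransitionMatrix.from_living_rows(rows)


def _parse_utility(name: str, state: str, entry: Any) -> tuple[float, float]:
    if isinstance(entry, Mapping):
        _check_keys(entry, {"mean", "sd"}, f"utility of '{state}' in strategy '{name}'")
        return float(entry["mean"]), float(entry["sd"])
    mean, sd = entry
    return float(mean), float(sd)


def _parse_strategy(entry: Mapping[str, Any]) -> StrategyParams:
    if not isinstance(entry, Mapping):
        raise ConfigError("each strategy must be a mapping")
    allowed = {
        "name",
        "annual_costs",
        "state_utilities",
        "response_distribution",
        "state_cycle_costs",
        "printed_totals",
    }
    name = entry.get("name", "<unnamed>")
    _check_keys(entry, allowed, f"strategy '{name}'")
    for required in ("name", "annual_costs", "state_utilities", "response_distribution"):
        if required not in entry:
            raise ConfigError(f"strategy '{name}': missing required key '{required}'")
    utilities = {
        state: _parse_utility(name, state, u)
        for state, u in entry["state_utilities"].items()
    }
    return StrategyParams(
        name=str(entry["name"]),
        annual_costs={k: float(v) for k, v in entry["annual_costs"].items()},
        state_utilities=utilities,
        response_distribution={k: int(v) for k, v in entry["response_distribution"].items()},
        state_cycle_costs=(
            {k: float(v) for k, v in entry["state_cycle_costs"].items()}
            if entry.get("state_cycle_costs") is not None
            else None
        ),
        printed_totals=(
            {k: float(v) for k, v in entry["printed_totals"].items()}
            if entry.get("printed_totals") is not None
            else None
        ),
    )


def _config_from_mapping(
    data: Mapping[str, Any],
) -> tuple[ModelConfig, list[StrategyParams], TransitionMatrix]:
    if not isinstance(data, Mapping):
        raise ConfigError("configuration document must be a mapping")
    _check_keys(
        data, {"model", "transition_matrix", "strategies", "reference_results"}, "top level"
    )
    if "transition_matrix" not in data:
        raise ConfigError("missing required section 'transition_matrix'")
    if "strategies" not in data or not data["strategies"]:
        raise ConfigError("missing or empty 'strategies' section: at least one strategy required")
    cfg = _parse_model(data.get("model", {}))
    tm = _parse_transition(data["transition_matrix"])
    strategies = [_parse_strategy(s) for s in data["strategies"]]
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate strategy names: {names}")
    for s in strategies:
        for cat, (computed, printed) in s.printed_total_mismatches().items():
            warnings.warn(
                f"strategy '{s.name}': printed {cat} total {printed:.2f} differs from "
                f"component sum {computed:.2f} by {abs(computed - printed):.2f} PPP $; "
                "components are kept as given",
                UserWarning,
                stacklevel=3,
            )
    return cfg, strategies, tm


def load_config(path: str | Path) -> tuple[ModelConfig, list[StrategyParams], TransitionMatrix]:
    """Load a YAML/JSON configuration file.

    Returns ``(ModelConfig, strategies, TransitionMatrix)`` with all type
    invariants enforced; unknown keys anywhere in the document are rejected
    with their names listed.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return _config_from_mapping(data)


def config_to_dict(
    cfg: ModelConfig,
    strategies: Sequence[StrategyParams],
    tm: TransitionMatrix,
) -> dict[str, Any]:
    """Serialize a parameter set back to the configuration schema."""
    return {
        "model": {
            "cycle_length_years": cfg.cycle_length_years,
            "discount_rate_costs": cfg.discount_rate_costs,
            "discount_rate_outcomes": cfg.discount_rate_outcomes,
            "max_cycles": cfg.max_cycles,
            "initial_distribution": {
                s: x for s, x in zip(STATES, cfg.initial_distribution)
            },
            "half_cycle_correction": cfg.half_cycle_correction,
            "gdp_per_capita": cfg.gdp_per_capita,
            "wtp_multipliers": list(cfg.wtp_multipliers),
        },
        "transition_matrix": {
            "states": list(STATES),
            "rows": {s: [float(x) for x in tm.probs[i]] for i, s in enumerate(STATES)},
        },
        "strategies": [
            {
                "name": s.name,
                "annual_costs": dict(s.annual_costs),
                "state_utilities": {
                    st: {"mean": m, "sd": sd} for st, (m, sd) in s.state_utilities.items()
                },
                "response_distribution": dict(s.response_distribution),
                **(
                    {"state_cycle_costs": dict(s.state_cycle_costs)}
                    if s.state_cycle_costs is not None
                    else {}
                ),
                **(
                    {"printed_totals": dict(s.printed_totals)}
                    if s.printed_totals is not None
                    else {}
                ),
            }
            for s in strategies
        ],
    }


def save_config(
    path: str | Path,
    cfg: ModelConfig,
    strategies: Sequence[StrategyParams],
    tm: TransitionMatrix,
) -> None:
    """Write a configuration document that :func:`load_config` reads back identically."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg, strategies, tm), sort_keys=False)
    )


def load_transition_matrix_csv(path: str | Path) -> TransitionMatrix:
    """Read a transition matrix from CSV.

    Expected layout: a header row of destination-state labels, one row per
    source state (index column holds the source labels).  The Death row may
    be omitted; the absorbing row is then appended.
    """
    frame = pd.read_csv(path, index_col=0)
    if list(frame.columns) != list(STATES):
        raise ConfigError(
            f"transition CSV columns must be {list(STATES)}, got {list(frame.columns)}"
        )
    rows = {str(label): frame.loc[label].to_numpy(dtype=float) for label in frame.index}
    _check_keys(rows, set(STATES), "transition CSV rows")
    if DEATH_STATE in rows:
        return TransitionMatrix(np.array([rows[s] for s in STATES]))
    return TransitionMatrix.from_living_rows(rows)


# ---------------------------------------------------------------------------
# Bundled study fixture


def _fixture_mapping() -> dict[str, Any]:
    text = resources.files("markovcea").joinpath(f"data/{_PAPER_FIXTURE}").read_text()
    return yaml.safe_load(text)


def paper_params() -> tuple[ModelConfig, list[StrategyParams], TransitionMatrix]:
    """The bundled three-arm study parameter set (transition matrix, costs,
    utilities, response distributions, discounting and threshold settings)."""
    return _config_from_mapping(_fixture_mapping())


def paper_reference_results() -> dict[str, dict[str, float]]:
    """Reported deterministic cost-utility results per strategy.

    These are the published per-arm totals (cost in PPP $, QALYs) together
    with the reported incremental values; they are consumed as inputs to the
    ICER/dominance layer and serve as reference points — the Markov engine's
    own totals depend on settings the report does not pin down.
    """
    section = _fixture_mapping().get("reference_results", {})
    return {name: {k: float(v) for k, v in row.items()} for name, row in section.items()}
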