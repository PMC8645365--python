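"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from markovcea.markov_engine import EvalResult
from markovcea.parameters import paper_params, paper_reference_results


@pytest.fixture(scope="session")
def study():
    """The bundled study parameter set: (ModelConfig, strategies, TransitionMatrix).

    Loading warns about the known printed-total inconsistency in one arm;
    that warning is exercised explicitly elsewhere.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return paper_params()


@pytest.fixture(scope="session")
def reference_results():
    """Published per-arm (cost, QALY) totals and incrementals."""
    return paper_reference_results()


@pytest.fixture(scope="session")
def reference_eval_results(reference_results):
    """The published totals wrapped as engine results, for the ranking layer."""
    return [
        EvalResult(name, row["cost"], row["qaly"])
        for name, row in reference_results.items()
    ]


# ---------------------------------------------------------------------------
# Independent oracles


def frontier_oracle(points):
    """Brute-force dominance classification on the cost-QALY plane.

    ``points`` is a list of ``(name, cost, qaly)``.  Absolute (weak)
    dominance is decided by exhaustive pairwise comparison with the same
    cost-then-name tie-break as the implementation; extended dominance by
    exhaustive enumeration of two-strategy convex blends among the
    absolutely-nondominated set.  Independent of the iterative ICER pruning
    used by the implementation.
    """
    abs_dom = set()
    for name, cost, qaly in points:
        for other, ocost, oqaly in points:
            if other == name:
                continue
            if (
                (ocost < cost and oqaly >= qaly)
                or (ocost == cost and oqaly > qaly)
                or (ocost == cost and oqaly == qaly and other < name)
            ):
                abs_dom.add(name)
                break
    survivors = [p for p in points if p[0] not in abs_dom]
    ext_dom = set()
    for name, cost, qaly in survivors:
        for a_name, a_cost, a_qaly in survivors:
            for b_name, b_cost, b_qaly in survivors:
                if len({name, a_name, b_name}) != 3:
                    continue
                if not (a_qaly < qaly < b_qaly):
                    continue
                lam = (b_qaly - qaly) / (b_qaly - a_qaly)
                blend_cost = lam * a_cost + (1.0 - lam) * b_cost
                if blend_cost < cost:
                    ext_dom.add(name)
    return abs_dom, ext_dom


@pytest.fixture(scope="session")
def dominance_oracle():
    return frontier_oracle


def random_ce_instance(rng: np.random.Generator, max_n: int = 6):
    """A random set of strategies on the cost-QALY plane."""
    n = int(rng.integers(2, max_n + 1))
    costs = rng.uniform(1_000, 100_000, size=n)
    qalys = rng.uniform(1.0, 15.0, size=n)
    return [(f"S{i}", float(costs[i]), float(qalys[i])) for i in range(n)]


@pytest.fixture(scope="session")
def make_ce_instance():
    return random_ce_instance
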