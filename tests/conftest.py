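"""Shared fixtures and the independent root-finding oracle.

The oracle solves for limiting H2 activities by bisection on
log10(a_H2) over [-30, 2] using only the dG' evaluator, and is used to
cross-check the closed-form threshold and ceiling expressions.
"""

from __future__ import annotations

import math

import pytest

from syntherm import Basis, ConditionSet, Reaction, delta_g_prime
from syntherm.constants import R_KJ
from syntherm.scenarios import load_bundle


@pytest.fixture(scope="session")
def bundle():
    return load_bundle()


@pytest.fixture(scope="session")
def standard(bundle):
    return bundle.conditions["standard"]


@pytest.fixture(scope="session")
def table3_env(bundle):
    return bundle.conditions["table3_env"]


@pytest.fixture(scope="session")
def fig2_env(bundle):
    return bundle.conditions["fig2_env"]


def _basis_factor(reaction: Reaction, basis: Basis) -> float:
    if basis is Basis.H2:
        return abs(float(reaction.coefficient("H2")))
    if basis is Basis.REACTION:
        return 1.0
    if basis is Basis.ACCEPTOR:
        return abs(float(reaction.coefficient(reaction.electron_acceptor)))
    if basis is Basis.REFERENCE:
        return abs(float(reaction.reference_coefficient))
    raise ValueError(basis)


def bisect_h2(
    reaction: Reaction,
    conditions: ConditionSet,
    dg_min: float,
    basis: Basis = Basis.H2,
    lo: float = -30.0,
    hi: float = 2.0,
    iterations: int = 200,
) -> float:
    """H2 activity (atm) at which dG' equals the target, by bisection.

    Works for both H2 consumers (dG' decreasing in a_H2) and producers
    (increasing); raises if the root is not bracketed.
    """
    target = dg_min * _basis_factor(reaction, basis)

    def f(x: float) -> float:
        res = delta_g_prime(reaction, conditions.with_activity("H2", 10.0**x))
        return res.dg_prime_reaction - target

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return 10.0**lo
    if f_hi == 0.0:
        return 10.0**hi
    if f_lo * f_hi > 0:
        raise ValueError("threshold not bracketed in [1e-30, 1e2] atm")
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if f_lo * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 10.0 ** (0.5 * (lo + hi))


def analytic_h2_threshold_standard(dg0_per_h2: float, dg_min: float,
                                   temperature: float = 298.15) -> float:
    """Threshold (atm) for a consumer with all other activities at 1."""
    return math.exp((dg0_per_h2 - dg_min) / (R_KJ * temperature))


@pytest.fixture(scope="session")
def h2_bisection():
    return bisect_h2
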