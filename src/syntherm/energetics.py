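"""Free-energy evaluation, thresholds, syntrophy windows and ladders.

The central quantity is the in-situ Gibbs free-energy change of a redox
reaction,

    dG' = dG0' + R T ln Q,

with ``dG0'`` the standard free energy at pH 7 and ``Q`` the reaction
quotient over effective activities (see :mod:`syntherm.reaction_model`
for the pH-7 proton convention).  For an H2-consuming reaction

    a EA + b H2 -> c C + d D,

setting dG' to a target minimum yield and solving for the hydrogen
activity gives the closed-form H2 consumption threshold

    a_H2 = [ (a_C^c a_D^d / a_EA^a) * exp((dG0' - dG'_target)/RT) ]^(1/b),

and for methane oxidation written as an H2-producing half-process
(CH4 + 3 H2O -> HCO3- + 4 H2 + H+, dG0' = +135.4 kJ/mol CH4) the same
algebra yields the maximum H2 activity (ceiling) at which the producer
still meets its yield:

    a_H2 = [ (a_CH4 / a_HCO3-) * exp((dG'_target - dG0')/RT) ]^(1/4).

A hydrogenotrophic consumer and the methane-oxidising producer are
syntrophically feasible when the consumer's threshold (floor) lies at or
below the producer's ceiling.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .constants import (
    ATM_PA,
    DG_MIN_DEFAULT,
    FARADAY_KJ_PER_V,
    HENRY_H2,
    R_KJ,
)
from .reaction_model import (
    ConditionSet,
    Reaction,
    Species,
    log_reaction_quotient,
)

__all__ = [
    "Basis",
    "EnergyResult",
    "ThresholdResult",
    "SyntrophyWindow",
    "delta_g_prime",
    "redox_potential",
    "henry_convert",
    "h2_threshold",
    "aom_h2_ceiling",
    "syntrophy_window",
    "energy_ladder",
    "profile_curve",
]


class Basis(str, enum.Enum):
    """Normalisation basis for free-energy values."""

    REACTION = "reaction"      #: per occurrence of the reaction as written
    REFERENCE = "reference"    #: per mole of the reaction's reference species
    ACCEPTOR = "acceptor"      #: per mole of electron acceptor consumed
    ELECTRON = "electron"      #: per mole of electrons transferred
    H2 = "h2"                  #: per mole of H2 converted


def _basis_divisor(reaction: Reaction, basis: Basis) -> float:
    """Moles of the basis quantity per occurrence of the reaction."""
    if basis is Basis.REACTION:
        return 1.0
    if basis is Basis.REFERENCE:
        return abs(float(reaction.reference_coefficient))
    if basis is Basis.ACCEPTOR:
        if reaction.electron_acceptor is None:
            raise ValueError(f"reaction {reaction.id!r} has no electron acceptor")
        return abs(float(reaction.coefficient(reaction.electron_acceptor)))
    if basis is Basis.ELECTRON:
        if not reaction.n_electrons:
            raise ValueError(f"reaction {reaction.id!r} has no electron count")
        return float(reaction.n_electrons)
    if basis is Basis.H2:
        coef = reaction.coefficient("H2")
        if coef == 0:
            raise ValueError(f"reaction {reaction.id!r} does not involve H2")
        return abs(float(coef))
    raise ValueError(f"unknown basis {basis!r}")


@dataclass(frozen=True)
class EnergyResult:
    """dG' and dG0' of one reaction on all normalisation bases."""

    reaction_id: str
    dg_prime_reaction: float
    dg0_prime_reaction: float
    dg_prime_per_reference: float
    dg0_prime_per_reference: float
    dg_prime_per_acceptor: Optional[float]
    dg0_prime_per_acceptor: Optional[float]
    dg_prime_per_electron: Optional[float]
    dg0_prime_per_electron: Optional[float]
    e0_prime: Optional[float]
    temperature: float

    def value(self, basis: Basis) -> float:
        """dG' on the requested basis."""
        v = {
            Basis.REACTION: self.dg_prime_reaction,
            Basis.REFERENCE: self.dg_prime_per_reference,
            Basis.ACCEPTOR: self.dg_prime_per_acceptor,
            Basis.ELECTRON: self.dg_prime_per_electron,
        }.get(basis)
        if v is None:
            raise ValueError(f"basis {basis!r} unavailable for this result")
        return v


@dataclass(frozen=True)
class ThresholdResult:
    """Limiting H2 activity for a fixed minimum free-energy yield."""

    h2_atm: float
    h2_molar: float
    dg_min: float
    basis: Basis


@dataclass(frozen=True)
class SyntrophyWindow:
    """H2 interval within which producer and consumer both conserve energy."""

    floor_h2: float    #: consumer threshold, M
    ceiling_h2: float  #: producer ceiling, M
    dg_min: float

    @property
    def feasible(self) -> bool:
        return self.floor_h2 <= self.ceiling_h2


def delta_g_prime(
    reaction: Reaction,
    conditions: ConditionSet,
    basis: Basis = Basis.REFERENCE,
) -> EnergyResult:
    """Evaluate dG' = dG0' + RT ln Q under the given conditions.

    All normalisation bases that the reaction supports are populated;
    ``basis`` only controls which value :meth:`EnergyResult.value`
    callers typically read first and is accepted for interface symmetry.
    """
    del basis  # all bases are computed regardless
    rt = R_KJ * conditions.temperature
    log_q = log_reaction_quotient(reaction, conditions)
    dg0_rxn = reaction.dg0_prime_reaction
    dg_rxn = dg0_rxn + rt * log_q

    def per(div: Optional[float]) -> tuple[Optional[float], Optional[float]]:
        if div is None:
            return None, None
        return dg_rxn / div, dg0_rxn / div

    ref_div = _basis_divisor(reaction, Basis.REFERENCE)
    acc_div = (
        _basis_divisor(reaction, Basis.ACCEPTOR)
        if reaction.electron_acceptor is not None
        else None
    )
    ele_div = (
        _basis_divisor(reaction, Basis.ELECTRON) if reaction.n_electrons else None
    )
    dg_ref, dg0_ref = per(ref_div)
    dg_acc, dg0_acc = per(acc_div)
    dg_ele, dg0_ele = per(ele_div)
    return EnergyResult(
        reaction_id=reaction.id,
        dg_prime_reaction=dg_rxn,
        dg0_prime_reaction=dg0_rxn,
        dg_prime_per_reference=dg_ref,
        dg0_prime_per_reference=dg0_ref,
        dg_prime_per_acceptor=dg_acc,
        dg0_prime_per_acceptor=dg0_acc,
        dg_prime_per_electron=dg_ele,
        dg0_prime_per_electron=dg0_ele,
        e0_prime=None if ele_div is None else -dg0_ele / FARADAY_KJ_PER_V,
        temperature=conditions.temperature,
    )


def redox_potential(reaction: Reaction) -> float:
    """Standard redox potential E0' (V) from dG0' = -n F dE0'."""
    if not reaction.n_electrons:
        raise ValueError(
            f"reaction {reaction.id!r}: n_electrons required for E0'"
        )
    return -reaction.dg0_prime_reaction / (
        float(reaction.n_electrons) * FARADAY_KJ_PER_V
    )


def henry_convert(species: Species, value: float, direction: str) -> float:
    """Convert a gas between partial pressure (atm) and aqueous M.

    Uses ``M = atm * 101325 Pa/atm * K_H / 1000``, with the Henry
    solubility ``K_H`` in mol m^-3 Pa^-1 taken from the species.
    ``direction`` is ``"atm_to_M"`` or ``"M_to_atm"``.
    """
    if species.henry_constant is None:
        raise ValueError(f"species {species.name!r} has no Henry constant")
    factor = ATM_PA * species.henry_constant / 1000.0
    if direction == "atm_to_M":
        return value * factor
    if direction == "M_to_atm":
        return value / factor
    raise ValueError(f"direction must be 'atm_to_M' or 'M_to_atm', got {direction!r}")


def _h2_henry(reaction: Optional[Reaction]) -> float:
    if reaction is not None:
        sp = reaction.species("H2")
        if sp is not None and sp.henry_constant is not None:
            return sp.henry_constant
    return HENRY_H2


def h2_threshold(
    reaction: Reaction,
    conditions: ConditionSet,
    dg_min: float = DG_MIN_DEFAULT,
    basis: Basis = Basis.H2,
) -> ThresholdResult:
    """Closed-form H2 consumption threshold of an H2-consuming reaction.

    Solves dG'(a_H2) = target for a_H2, where the target is ``dg_min``
    scaled from the requested basis to the per-reaction value.  All
    activities other than H2 come from ``conditions``.
    """
    b = -reaction.coefficient("H2")
    if b == 0:
        raise ValueError(f"reaction {reaction.id!r} does not contain H2")
    if b < 0:
        raise ValueError(
            f"reaction {reaction.id!r} produces H2; thresholds apply to consumers"
        )
    target_rxn = dg_min * _basis_divisor(reaction, basis)
    rt = R_KJ * conditions.temperature
    # Q with the H2 term removed: evaluate at a_H2 = 1
    log_q_rest = log_reaction_quotient(
        reaction, conditions.with_activity("H2", 1.0)
    )
    log_a_h2 = (
        log_q_rest + (reaction.dg0_prime_reaction - target_rxn) / rt
    ) / float(b)
    h2_atm = math.exp(log_a_h2)
    k_h = _h2_henry(reaction)
    return ThresholdResult(
        h2_atm=h2_atm,
        h2_molar=h2_atm * ATM_PA * k_h / 1000.0,
        dg_min=dg_min,
        basis=basis,
    )


def aom_h2_ceiling(
    conditions: ConditionSet,
    dg_min: float = DG_MIN_DEFAULT,
    basis: Basis = Basis.REFERENCE,
    dg0_prime: float = 135.4,
    h2_per_ch4: float = 4.0,
    henry_h2: float = HENRY_H2,
) -> ThresholdResult:
    """Maximum H2 activity at which methane oxidation meets its yield.

    Methane oxidation to bicarbonate releases ``h2_per_ch4`` (= 4) moles
    of H2 per mole of CH4 and has ``dg0_prime`` = +135.4 kJ/mol CH4;
    water and the proton (at pH 7) drop out of the quotient, leaving
    only the CH4 and HCO3- activities.  ``basis`` scales ``dg_min``:
    per mole CH4 (reference, = per reaction as written) or per mole H2.
    """
    try:
        a_ch4 = float(conditions.activities["CH4"])
        a_hco3 = float(conditions.activities["HCO3-"])
    except KeyError as exc:
        raise ValueError(f"missing activity for {exc.args[0]!r}") from None
    if basis in (Basis.REFERENCE, Basis.REACTION):
        target = dg_min
    elif basis is Basis.H2:
        target = dg_min * h2_per_ch4
    else:
        raise ValueError(f"unsupported basis {basis!r} for the AOM ceiling")
    rt = R_KJ * conditions.temperature
    h2_atm = (
        (a_ch4 / a_hco3) * math.exp((target - dg0_prime) / rt)
    ) ** (1.0 / h2_per_ch4)
    return ThresholdResult(
        h2_atm=h2_atm,
        h2_molar=h2_atm * ATM_PA * henry_h2 / 1000.0,
        dg_min=dg_min,
        basis=basis,
    )


def syntrophy_window(
    consumer: Reaction,
    conditions: ConditionSet,
    dg_min: float = DG_MIN_DEFAULT,
    consumer_basis: Basis = Basis.H2,
    producer_basis: Basis = Basis.REFERENCE,
    producer_dg0_prime: float = 135.4,
) -> SyntrophyWindow:
    """Feasible H2 interval for methane oxidation feeding a H2 consumer.

    The floor is the consumer's H2 threshold, the ceiling the producer's
    maximum H2 (both in M); the window is feasible when floor <= ceiling.
    """
    floor = h2_threshold(consumer, conditions, dg_min, consumer_basis)
    ceiling = aom_h2_ceiling(
        conditions, dg_min, producer_basis, dg0_prime=producer_dg0_prime
    )
    return SyntrophyWindow(
        floor_h2=floor.h2_molar, ceiling_h2=ceiling.h2_molar, dg_min=dg_min
    )


def energy_ladder(
    reactions: Iterable[Reaction],
    conditions: ConditionSet,
    basis: Basis = Basis.ELECTRON,
) -> list[tuple[str, float]]:
    """Rank reactions by free-energy yield, most favourable first.

    Empty (fully cancelled) reactions are excluded; ties are broken by
    reaction id.
    """
    rungs = [
        (r.id, delta_g_prime(r, conditions).value(basis))
        for r in reactions
        if not r.is_empty
    ]
    return sorted(rungs, key=lambda t: (t[1], t[0]))


def profile_curve(
    reaction: Reaction,
    conditions: ConditionSet,
    h2_grid: Sequence[float],
    basis: Basis = Basis.ACCEPTOR,
) -> pd.DataFrame:
    """dG' as a function of aqueous H2 concentration.

    Each grid value (M, strictly positive and increasing) is converted
    to a partial pressure via Henry's law and substituted as the H2
    activity; returns a frame with columns ``h2_molar``, ``h2_atm`` and
    ``dg_prime``.
    """
    grid = list(h2_grid)
    if any(h <= 0 for h in grid):
        raise ValueError("H2 grid values must be strictly positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("H2 grid must be strictly increasing")
    factor = ATM_PA * _h2_henry(reaction) / 1000.0
    rows = []
    for h2_m in grid:
        h2_atm = h2_m / factor
        res = delta_g_prime(reaction, conditions.with_activity("H2", h2_atm))
        rows.append((h2_m, h2_atm, res.value(basis)))
    return pd.DataFrame(rows, columns=["h2_molar", "h2_atm", "dg_prime"])
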