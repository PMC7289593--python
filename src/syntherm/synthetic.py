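"""Seeded generation of random-but-valid reactions and condition sets.

The generator emulates the shape of a generic hydrogenotrophic redox
process, ``a EA + b H2 (+ h H+) -> c C + d D``: one designated electron
acceptor, one to four moles of H2, integer product stoichiometry, small
random charges balanced exactly by a proton term, and a standard free
energy drawn uniformly from a configurable per-H2 range.  Every output
passes :func:`syntherm.reaction_model.validate_reaction`, so property
suites can exercise thresholds, normalisations and coupling on
thousands of cases without any external input.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; generation order is fixed, so a seed fully
determines the output on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Optional

import numpy as np

from .constants import HENRY_H2
from .reaction_model import (
    AQUEOUS,
    GAS,
    ConditionSet,
    Reaction,
    Species,
    SpeciesRegistry,
)

__all__ = [
    "GeneratorConfig",
    "random_consumer_reaction",
    "random_conditions",
    "random_scenarios",
]

_H2 = Species(name="H2", phase=GAS, charge=0, henry_constant=HENRY_H2)
_H_PLUS = Species(name="H+", phase=AQUEOUS, charge=1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-scenario generator.

    ``dg0_range`` is kJ per mole of H2 (defaults span the observed range
    of anaerobic H2-consuming respirations, roughly acetogenesis down to
    organohalide respiration); ``activity_log10_range`` is the log10 of
    activities in M (defaults cover trace contaminants up to molar
    solutes).
    """

    seed: int = 0
    n_species: int = 3
    dg0_range: tuple[float, float] = (-180.0, -20.0)
    activity_log10_range: tuple[float, float] = (-9.0, 0.0)
    max_stoich: int = 4
    fraction_gas: float = 0.2

    def __post_init__(self) -> None:
        if self.dg0_range[0] > self.dg0_range[1]:
            raise ValueError("dg0_range must be a non-empty interval")
        if self.activity_log10_range[0] > self.activity_log10_range[1]:
            raise ValueError("activity_log10_range must be a non-empty interval")
        if self.max_stoich < 1:
            raise ValueError("max_stoich must be at least 1")
        if not 0.0 <= self.fraction_gas <= 1.0:
            raise ValueError("fraction_gas must lie in [0, 1]")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    # independent, platform-stable streams per operation
    return np.random.default_rng([config.seed, stream])


def _random_phase(rng: np.random.Generator, fraction_gas: float) -> str:
    return GAS if rng.random() < fraction_gas else AQUEOUS


def random_consumer_reaction(
    config: GeneratorConfig, tag: int = 0
) -> tuple[Reaction, SpeciesRegistry]:
    """One random charge-balanced H2-consuming reaction.

    ``tag`` distinguishes (and names the species of) successive draws
    under the same seed; the pair (seed, tag) fully determines the
    result.  Returns the reaction together with a registry holding its
    species.
    """
    rng = _rng(config, stream=2 * tag + 1)
    b = int(rng.integers(1, 5))                    # moles of H2
    a = int(rng.integers(1, config.max_stoich + 1))
    c = int(rng.integers(1, config.max_stoich + 1))
    d = int(rng.integers(1, config.max_stoich + 1))
    z_ea, z_c, z_d = (int(z) for z in rng.integers(-2, 3, size=3))

    def charged_name(base: str, charge: int) -> str:
        if charge == 0:
            return base
        return f"{base}{'+' if charge > 0 else '-'}{abs(charge)}"

    ea = Species(
        name=charged_name(f"EA{tag}", z_ea),
        phase=_random_phase(rng, config.fraction_gas),
        charge=z_ea,
    )
    prod_c = Species(
        name=charged_name(f"C{tag}", z_c),
        phase=_random_phase(rng, config.fraction_gas),
        charge=z_c,
    )
    prod_d = Species(
        name=charged_name(f"D{tag}", z_d),
        phase=_random_phase(rng, config.fraction_gas),
        charge=z_d,
    )
    stoich: dict[Species, Fraction] = {
        ea: Fraction(-a),
        _H2: Fraction(-b),
        prod_c: Fraction(c),
        prod_d: Fraction(d),
    }
    # protons close the charge balance so that sum(nu_i * z_i) = 0
    h = a * z_ea - c * z_c - d * z_d
    if h != 0:
        stoich[_H_PLUS] = Fraction(h)

    dg0_per_h2 = float(rng.uniform(*config.dg0_range))
    reaction = Reaction(
        id=f"synthetic_{config.seed}_{tag}",
        stoichiometry=stoich,
        dg0_prime=dg0_per_h2,
        reference_species="H2",
        electron_donor="H2",
        electron_acceptor=ea.name,
        n_electrons=2 * b,
    )
    registry = SpeciesRegistry(stoich.keys())
    return reaction, registry


def random_conditions(
    config: GeneratorConfig,
    registry: SpeciesRegistry,
    tag: int = 0,
    pH: float = 7.0,
    temperature: float = 298.15,
) -> ConditionSet:
    """Log-uniform activities for every free species in the registry.

    Water and solids are pinned to unit activity by the condition-set
    semantics and protons are controlled by pH, so neither receives an
    entry; species are assigned in sorted-name order for stability.
    """
    rng = _rng(config, stream=2 * tag + 2)
    lo, hi = config.activity_log10_range
    activities = {
        name: float(10.0 ** rng.uniform(lo, hi))
        for name in sorted(registry)
        if not registry[name].fixed_unit_activity and name != "H+"
    }
    return ConditionSet(activities=activities, temperature=temperature, pH=pH)


def random_scenarios(
    config: GeneratorConfig, n: int
) -> Iterator[tuple[Reaction, ConditionSet]]:
    """Stream of *n* independent (reaction, conditions) pairs."""
    for tag in range(n):
        reaction, registry = random_consumer_reaction(config, tag=tag)
        yield reaction, random_conditions(config, registry, tag=tag)
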