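"""Chemical species, reactions and condition sets for redox energetics.

Stoichiometric coefficients are stored as exact :class:`fractions.Fraction`
values (reactants negative, products positive), so scaling and linear
combination of reactions never accumulate floating-point drift.  Free
energies are the only floating-point quantities on a reaction.

Conventions
-----------
* ``dg0_prime`` is the standard free-energy change at pH 7 (solutes 1 M,
  gases 1 atm, water and solids at unit activity) expressed per mole of
  the declared ``reference_species``; the per-reaction value is obtained
  by multiplying with the magnitude of the reference coefficient.
* Protons are referenced to the pH-7 standard state: in any reaction
  quotient H+ contributes ``(a_H+ / 1e-7) ** nu``, so a condition set at
  pH 7 contributes a factor of one regardless of proton stoichiometry.
* Water and solid-phase species have unit activity always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Mapping, Optional, Union

from .constants import PH_STANDARD, T_STANDARD

__all__ = [
    "GAS",
    "AQUEOUS",
    "SOLID",
    "WATER",
    "PHASES",
    "Species",
    "SpeciesRegistry",
    "Reaction",
    "ConditionSet",
    "UnknownSpeciesError",
    "MissingActivityError",
    "validate_reaction",
    "scale_reaction",
    "couple_reactions",
    "reaction_quotient",
]

GAS = "g"
AQUEOUS = "aq"
SOLID = "s"
WATER = "w"
PHASES = frozenset({GAS, AQUEOUS, SOLID, WATER})

#: species whose activity is pinned to exactly 1 in every condition set
_UNIT_ACTIVITY_PHASES = frozenset({SOLID, WATER})

Coefficient = Union[int, Fraction]


class UnknownSpeciesError(KeyError):
    """A reaction refers to a species absent from the registry."""


class MissingActivityError(KeyError):
    """A condition set lacks an activity required to evaluate a quotient."""


@dataclass(frozen=True)
class Species:
    """A named chemical entity with a phase and optional charge.

    Parameters
    ----------
    name
        Unique identifier, e.g. ``"SO4-2"`` or ``"CH4"``.  A trailing
        ``+n``/``-n`` (or bare sign) conventionally encodes the charge.
    phase
        One of ``"g"`` (gas), ``"aq"`` (aqueous), ``"s"`` (solid),
        ``"w"`` (water).
    charge
        Signed elementary charge; ``None`` when unknown.
    henry_constant
        Henry solubility in mol m^-3 Pa^-1; gases only.
    """

    name: str
    phase: str
    charge: Optional[int] = None
    henry_constant: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"species {self.name!r}: phase must be one of "
                f"{sorted(PHASES)}, got {self.phase!r}"
            )
        if self.henry_constant is not None and self.phase != GAS:
            raise ValueError(
                f"species {self.name!r}: a Henry constant is only "
                f"meaningful for gas-phase species (phase={self.phase!r})"
            )

    @property
    def fixed_unit_activity(self) -> bool:
        """True for water and solids, whose activity is always 1."""
        return self.phase in _UNIT_ACTIVITY_PHASES


class SpeciesRegistry(Mapping[str, Species]):
    """Name-indexed collection of species with uniqueness enforcement."""

    def __init__(self, species: Iterable[Species] = ()) -> None:
        self._species: dict[str, Species] = {}
        for sp in species:
            self.add(sp)

    def add(self, species: Species) -> None:
        existing = self._species.get(species.name)
        if existing is not None and existing != species:
            raise ValueError(
                f"species name {species.name!r} already registered with "
                f"different attributes"
            )
        self._species[species.name] = species

    def __getitem__(self, name: str) -> Species:
        try:
            return self._species[name]
        except KeyError:
            raise UnknownSpeciesError(name) from None

    def __iter__(self):
        return iter(self._species)

    def __len__(self) -> int:
        return len(self._species)


def _as_fraction(value: Union[Coefficient, float, str]) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, (int, str, Rational)):
        return Fraction(value)
    if isinstance(value, float):
        # exact binary value; callers wanting decimals pass strings
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as a rational coefficient")


@dataclass(frozen=True)
class Reaction:
    """A signed-stoichiometry redox reaction.

    ``stoichiometry`` maps :class:`Species` to signed rational
    coefficients (reactants negative, products positive).  ``dg0_prime``
    is kJ per mole of ``reference_species``.
    """

    id: str
    stoichiometry: Mapping[Species, Fraction]
    dg0_prime: Optional[float] = None
    reference_species: Optional[str] = None
    electron_donor: Optional[str] = None
    electron_acceptor: Optional[str] = None
    n_electrons: Optional[Fraction] = None

    def __post_init__(self) -> None:
        stoich = {
            sp: _as_fraction(c)
            for sp, c in self.stoichiometry.items()
            if _as_fraction(c) != 0
        }
        object.__setattr__(self, "stoichiometry", stoich)
        if self.n_electrons is not None:
            object.__setattr__(self, "n_electrons", _as_fraction(self.n_electrons))

    # -- lookups -----------------------------------------------------------

    def species(self, name: str) -> Optional[Species]:
        for sp in self.stoichiometry:
            if sp.name == name:
                return sp
        return None

    def coefficient(self, name: str) -> Fraction:
        sp = self.species(name)
        return self.stoichiometry[sp] if sp is not None else Fraction(0)

    @property
    def reactants(self) -> dict[Species, Fraction]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[Species, Fraction]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    @property
    def is_empty(self) -> bool:
        return not self.stoichiometry

    # -- derived free energies --------------------------------------------

    @property
    def reference_coefficient(self) -> Fraction:
        if self.reference_species is None:
            raise ValueError(f"reaction {self.id!r} has no reference species")
        coef = self.coefficient(self.reference_species)
        if coef == 0:
            raise ValueError(
                f"reaction {self.id!r}: reference species "
                f"{self.reference_species!r} not in stoichiometry"
            )
        return coef

    @property
    def dg0_prime_reaction(self) -> float:
        """dG0' per occurrence of the reaction as written (kJ).

        A fully cancelled (empty) reaction has zero free energy.
        """
        if self.is_empty:
            return 0.0 if self.dg0_prime is None else self.dg0_prime
        if self.dg0_prime is None:
            raise ValueError(f"reaction {self.id!r} has no dg0_prime")
        return self.dg0_prime * abs(self.reference_coefficient)

    # -- algebra -----------------------------------------------------------

    def reverse(self) -> "Reaction":
        """The reaction written backwards; free energies change sign."""
        return replace(
            self,
            id=f"{self.id}_reversed",
            stoichiometry={s: -c for s, c in self.stoichiometry.items()},
            dg0_prime=None if self.dg0_prime is None else -self.dg0_prime,
            electron_donor=self.electron_acceptor,
            electron_acceptor=self.electron_donor,
        )


@dataclass(frozen=True)
class ConditionSet:
    """Activities (effective concentrations), temperature and pH.

    Activities are M for aqueous solutes and atm for gases; water and
    solids are pinned to 1 regardless of any supplied value.  Proton
    activity is controlled exclusively through ``pH`` and is reported
    relative to the pH-7 standard state.
    """

    activities: Mapping[str, float] = field(default_factory=dict)
    temperature: float = T_STANDARD
    pH: float = PH_STANDARD

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        for name, a in self.activities.items():
            if not a > 0:
                raise ValueError(f"activity of {name!r} must be positive, got {a}")

    def activity(self, species: Species) -> float:
        """Effective activity of *species* under these conditions.

        Water and solids return 1; H+ returns ``10**(7 - pH)`` (the
        activity relative to the pH-7 reference); everything else is
        looked up by name.
        """
        if species.fixed_unit_activity:
            return 1.0
        if species.name == "H+":
            return 10.0 ** (PH_STANDARD - self.pH)
        try:
            return float(self.activities[species.name])
        except KeyError:
            raise MissingActivityError(species.name) from None

    def with_activity(self, name: str, value: float) -> "ConditionSet":
        updated = dict(self.activities)
        updated[name] = value
        return replace(self, activities=updated)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: electrons released per mole of donor oxidised, for donors the
#: validator knows how to check
_DONOR_ELECTRONS = {"H2": 2, "CH4": 8}


def validate_reaction(reaction: Reaction, registry: SpeciesRegistry) -> list[str]:
    """Check a reaction against its structural invariants.

    Returns a list of human-readable violation descriptions; an empty
    list means the reaction is valid.  Unknown species raise
    :class:`UnknownSpeciesError` rather than being reported as
    violations, since nothing else can be checked without the registry
    entry.
    """
    for sp in reaction.stoichiometry:
        registry[sp.name]  # raises UnknownSpeciesError

    violations: list[str] = []

    for role in ("reference_species", "electron_donor", "electron_acceptor"):
        name = getattr(reaction, role)
        if name is not None and reaction.coefficient(name) == 0:
            violations.append(
                f"{role} {name!r} has zero coefficient in reaction {reaction.id!r}"
            )

    charges = {sp: registry[sp.name].charge for sp in reaction.stoichiometry}
    if all(q is not None for q in charges.values()):
        net = sum(c * charges[sp] for sp, c in reaction.stoichiometry.items())
        if net != 0:
            sign = "+" if net > 0 else ""
            violations.append(
                f"charge imbalance of {sign}{net} in reaction {reaction.id!r} "
                f"(include H+ to balance)"
            )

    donor = reaction.electron_donor
    if donor in _DONOR_ELECTRONS and reaction.n_electrons is not None:
        if donor == "CH4" and reaction.coefficient("HCO3-") == 0:
            pass  # only CH4 -> HCO3- (8 e-) oxidation is checkable
        else:
            expected = _DONOR_ELECTRONS[donor] * abs(reaction.coefficient(donor))
            if reaction.n_electrons != expected:
                violations.append(
                    f"n_electrons = {reaction.n_electrons} but donor {donor!r} "
                    f"with |coefficient| {abs(reaction.coefficient(donor))} "
                    f"implies {expected}"
                )

    return violations


def scale_reaction(reaction: Reaction, factor: Union[Coefficient, float, str]) -> Reaction:
    """Multiply all coefficients (and n_electrons) by a positive factor.

    ``dg0_prime`` is per mole of reference species and therefore
    unchanged; the per-reaction free energy scales through the reference
    coefficient.
    """
    f = _as_fraction(factor)
    if f <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return replace(
        reaction,
        stoichiometry={s: c * f for s, c in reaction.stoichiometry.items()},
        n_electrons=None if reaction.n_electrons is None else reaction.n_electrons * f,
    )


def _recount_electrons(
    reaction_stub: Mapping[Species, Fraction],
    donor: Optional[str],
    fallback: Optional[Fraction],
) -> Optional[Fraction]:
    if donor in _DONOR_ELECTRONS:
        coef = next(
            (c for s, c in reaction_stub.items() if s.name == donor), Fraction(0)
        )
        if coef != 0:
            return _DONOR_ELECTRONS[donor] * abs(coef)
    return fallback


def couple_reactions(
    a: Reaction,
    weight_a: Union[Coefficient, float, str],
    b: Reaction,
    weight_b: Union[Coefficient, float, str],
    id: Optional[str] = None,
) -> Reaction:
    """Weighted linear combination of two reactions.

    Shared species cancel exactly for rational weights; after combination
    any residual coefficient of magnitude below 1e-12 (possible only with
    non-rational float weights) is dropped.  The combined standard free
    energy is the weighted sum of the per-reaction values.  Electrons are
    recounted from whichever declared donor survives in the combined
    stoichiometry (H2: 2 e- per mole; CH4: 8 e- per mole).
    """
    wa, wb = _as_fraction(weight_a), _as_fraction(weight_b)
    if wa == 0 and wb == 0:
        raise ValueError("coupling with both weights zero yields an empty reaction")

    combined: dict[Species, Fraction] = {}
    for rxn, w in ((a, wa), (b, wb)):
        for sp, coef in rxn.stoichiometry.items():
            combined[sp] = combined.get(sp, Fraction(0)) + w * coef
    combined = {
        sp: c for sp, c in combined.items() if c != 0 and abs(c) >= Fraction(1, 10**12)
    }

    dg0_rxn: Optional[float] = None
    if a.dg0_prime is not None and b.dg0_prime is not None:
        dg0_rxn = float(wa) * a.dg0_prime_reaction + float(wb) * b.dg0_prime_reaction

    donor = next(
        (
            d
            for d in (a.electron_donor, b.electron_donor)
            if d is not None and any(sp.name == d for sp in combined)
        ),
        None,
    )
    acceptor = next(
        (
            acc
            for acc in (a.electron_acceptor, b.electron_acceptor)
            if acc is not None and any(sp.name == acc for sp in combined)
        ),
        None,
    )
    fallback_n = None
    if a.n_electrons is not None and b.n_electrons is not None:
        fallback_n = wa * a.n_electrons + wb * b.n_electrons
    n_electrons = _recount_electrons(combined, donor, fallback_n)

    reference = next(
        (
            r
            for r in (a.reference_species, b.reference_species, donor)
            if r is not None and any(sp.name == r for sp in combined)
        ),
        None,
    )
    if reference is None and combined:
        reference = sorted(sp.name for sp in combined)[0]

    dg0_per_ref: Optional[float] = None
    if dg0_rxn is not None and reference is not None:
        ref_coef = next(c for s, c in combined.items() if s.name == reference)
        dg0_per_ref = dg0_rxn / abs(float(ref_coef))
    elif dg0_rxn is not None:
        dg0_per_ref = dg0_rxn  # empty reaction: dG0' = 0

    return Reaction(
        id=id or f"{a.id}+{b.id}",
        stoichiometry=combined,
        dg0_prime=dg0_per_ref,
        reference_species=reference,
        electron_donor=donor,
        electron_acceptor=acceptor,
        n_electrons=n_electrons,
    )


def log_reaction_quotient(reaction: Reaction, conditions: ConditionSet) -> float:
    """Natural log of the reaction quotient; safe for extreme activities."""
    log_q = 0.0
    for sp, coef in reaction.stoichiometry.items():
        a = conditions.activity(sp)
        if a != 1.0:
            log_q += float(coef) * math.log(a)
    return log_q


def reaction_quotient(reaction: Reaction, conditions: ConditionSet) -> float:
    """Reaction quotient Q relative to the pH-7 standard state.

    Q = prod(products a^nu) / prod(reactants a^|nu|), with water and
    solids contributing 1 and H+ contributing (a_H+/1e-7)^nu.  Computed
    in log space for numerical range.
    """
    return math.exp(log_reaction_quotient(reaction, conditions))
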