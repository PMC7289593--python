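"""CSV readers and writers for species, reactions and condition sets.

Formats (UTF-8, comma-separated, LF endings, header row):

* species:    ``name, phase, charge, henry_mol_m3_Pa``
* reactions:  ``id, equation, dg0_prime_kj, ref_species, donor, acceptor,
  n_electrons`` — the equation column uses the mini-grammar of
  :mod:`syntherm.equations`
* conditions: ``species, activity, unit`` with unit in {M, atm, unitless}

Blank cells mean "not set".  Parse problems are reported with the file
and line they occurred on.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

from .equations import EquationParseError, format_equation, parse_equation
from .reaction_model import (
    ConditionSet,
    Reaction,
    Species,
    SpeciesRegistry,
)

__all__ = [
    "FileFormatError",
    "read_species_csv",
    "write_species_csv",
    "read_reactions_csv",
    "write_reactions_csv",
    "read_conditions_csv",
    "write_conditions_csv",
]

PathLike = Union[str, Path]

_CONDITION_UNITS = {"M", "atm", "unitless"}


class FileFormatError(ValueError):
    """A fixture file violates its documented format."""

    def __init__(self, path: PathLike, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def _opt_int(cell: str) -> Optional[int]:
    return int(cell) if cell.strip() else None


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell.strip() else None


def _opt_str(cell: str) -> Optional[str]:
    return cell.strip() or None


def read_species_csv(path: PathLike) -> SpeciesRegistry:
    registry = SpeciesRegistry()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                registry.add(
                    Species(
                        name=row["name"].strip(),
                        phase=row["phase"].strip(),
                        charge=_opt_int(row.get("charge", "")),
                        henry_constant=_opt_float(row.get("henry_mol_m3_Pa", "")),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    return registry


def write_species_csv(path: PathLike, registry: SpeciesRegistry) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["name", "phase", "charge", "henry_mol_m3_Pa"])
        for name in sorted(registry):
            sp = registry[name]
            writer.writerow([
                sp.name,
                sp.phase,
                "" if sp.charge is None else sp.charge,
                "" if sp.henry_constant is None else repr(sp.henry_constant),
            ])


def read_reactions_csv(
    path: PathLike, registry: Optional[SpeciesRegistry] = None
) -> dict[str, Reaction]:
    """Read a reaction table; returns reactions keyed by id, in file order.

    Species named in equations are resolved against (and added to) the
    registry when one is given.
    """
    reactions: dict[str, Reaction] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            rid = row["id"].strip()
            if rid in reactions:
                raise FileFormatError(path, lineno, f"duplicate reaction id {rid!r}")
            try:
                stoich = parse_equation(row["equation"], registry)
                n_cell = row.get("n_electrons", "").strip()
                reactions[rid] = Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    dg0_prime=_opt_float(row.get("dg0_prime_kj", "")),
                    reference_species=_opt_str(row.get("ref_species", "")),
                    electron_donor=_opt_str(row.get("donor", "")),
                    electron_acceptor=_opt_str(row.get("acceptor", "")),
                    n_electrons=Fraction(n_cell) if n_cell else None,
                )
            except (EquationParseError, ValueError, KeyError) as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    return reactions


def write_reactions_csv(path: PathLike, reactions: dict[str, Reaction]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([
            "id", "equation", "dg0_prime_kj", "ref_species",
            "donor", "acceptor", "n_electrons",
        ])
        for rid, rxn in reactions.items():
            n = rxn.n_electrons
            writer.writerow([
                rid,
                format_equation(rxn),
                "" if rxn.dg0_prime is None else repr(rxn.dg0_prime),
                rxn.reference_species or "",
                rxn.electron_donor or "",
                rxn.electron_acceptor or "",
                "" if n is None else (str(n.numerator) if n.denominator == 1 else str(n)),
            ])


def read_conditions_csv(
    path: PathLike,
    temperature: float = 298.15,
    pH: float = 7.0,
) -> ConditionSet:
    """Read an activity table into a condition set.

    The file carries activities only; temperature and pH are supplied by
    the caller (defaults: 298.15 K, pH 7).
    """
    activities: dict[str, float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            name = row["species"].strip()
            unit = row.get("unit", "").strip() or "M"
            if unit not in _CONDITION_UNITS:
                raise FileFormatError(
                    path, lineno,
                    f"unit must be one of {sorted(_CONDITION_UNITS)}, got {unit!r}",
                )
            if name in activities:
                raise FileFormatError(path, lineno, f"duplicate species {name!r}")
            try:
                activities[name] = float(row["activity"])
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
    return ConditionSet(activities=activities, temperature=temperature, pH=pH)


def write_conditions_csv(
    path: PathLike,
    conditions: ConditionSet,
    registry: Optional[SpeciesRegistry] = None,
) -> None:
    def unit_for(name: str) -> str:
        if registry is not None and name in registry:
            return "atm" if registry[name].phase == "g" else "M"
        return "M"

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["species", "activity", "unit"])
        for name in sorted(conditions.activities):
            writer.writerow([name, repr(conditions.activities[name]), unit_for(name)])
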