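"""Plain-text reaction equations.

Grammar (one reaction per line)::

    equation := side "->" side
    side     := term { "+" term }
    term     := [coefficient] name "(" phase ")"

Coefficients are positive integers, decimals or rationals (``1/2``) and
default to 1; ``phase`` is one of ``g``/``aq``/``s``/``w``.  An optional
trailing ``+n``/``-n`` (or bare sign) on a species name encodes its
charge, e.g. ``SO4-2`` or ``HCO3-``.  Names may themselves contain
parentheses (``Fe(OH)3``); the final parenthesised token is always the
phase tag.
"""

from __future__ import annotations

import re
from fractions import Fraction
from typing import Optional

from .reaction_model import PHASES, Reaction, Species, SpeciesRegistry

__all__ = ["EquationParseError", "parse_equation", "format_equation", "charge_from_name"]

_TERM_RE = re.compile(
    r"^\s*(?:(?P<coef>\d+/\d+|\d*\.\d+|\d+)\s+)?"
    r"(?P<name>.+?)\((?P<phase>[a-z]+)\)\s*$"
)
_CHARGE_RE = re.compile(r"([+-])(\d*)$")
_ARROW = "->"


class EquationParseError(ValueError):
    """Malformed reaction equation; carries the offending position."""

    def __init__(self, message: str, text: str, position: int) -> None:
        super().__init__(f"{message} at position {position}: {text!r}")
        self.text = text
        self.position = position


def charge_from_name(name: str) -> Optional[int]:
    """Charge encoded by a trailing ``+n``/``-n`` suffix, else None.

    ``"SO4-2"`` -> -2, ``"H+"`` -> +1, ``"HCO3-"`` -> -1, ``"CH4"`` -> None.
    """
    m = _CHARGE_RE.search(name)
    if m is None:
        return None
    sign = 1 if m.group(1) == "+" else -1
    magnitude = int(m.group(2)) if m.group(2) else 1
    return sign * magnitude


def _parse_term(term: str, text: str, offset: int) -> tuple[Fraction, str, str]:
    m = _TERM_RE.match(term)
    if m is None:
        raise EquationParseError("malformed term (expected '[coef] name(phase)')",
                                 text, offset)
    phase = m.group("phase")
    if phase not in PHASES:
        raise EquationParseError(f"unknown phase tag {phase!r}", text,
                                 offset + m.start("phase"))
    coef = Fraction(m.group("coef")) if m.group("coef") else Fraction(1)
    if coef <= 0:
        raise EquationParseError("coefficient must be positive", text, offset)
    return coef, m.group("name"), phase


def parse_equation(
    text: str, registry: Optional[SpeciesRegistry] = None
) -> dict[Species, Fraction]:
    """Parse an equation string into a signed stoichiometry map.

    Without a registry, species are constructed from the term itself
    (phase from the tag, charge from the name suffix) and added to no
    collection.  With a registry, names are resolved against it — new
    species are registered, and a phase tag conflicting with an existing
    entry is an error.
    """
    if text.count(_ARROW) != 1:
        raise EquationParseError("equation must contain exactly one '->'",
                                 text, text.find(_ARROW) if _ARROW in text else 0)
    lhs, rhs = text.split(_ARROW)
    stoich: dict[Species, Fraction] = {}

    for side_text, sign, offset0 in (
        (lhs, -1, 0),
        (rhs, +1, len(lhs) + len(_ARROW)),
    ):
        seen: set[str] = set()
        offset = offset0
        for term in side_text.split(" + "):
            coef, name, phase = _parse_term(term, text, offset)
            if name in seen:
                raise EquationParseError(
                    f"species {name!r} appears twice on one side", text, offset)
            seen.add(name)
            if registry is not None:
                existing = registry.get(name)
                if existing is not None:
                    if existing.phase != phase:
                        raise EquationParseError(
                            f"species {name!r} registered with phase "
                            f"{existing.phase!r}, not {phase!r}", text, offset)
                    sp = existing
                else:
                    sp = Species(name=name, phase=phase,
                                 charge=charge_from_name(name))
                    registry.add(sp)
            else:
                sp = Species(name=name, phase=phase, charge=charge_from_name(name))
            stoich[sp] = stoich.get(sp, Fraction(0)) + sign * coef
            offset += len(term) + len(" + ")

    stoich = {sp: c for sp, c in stoich.items() if c != 0}
    if not stoich:
        raise EquationParseError("equation cancels to nothing", text, 0)
    return stoich


def _format_coef(coef: Fraction) -> str:
    if coef == 1:
        return ""
    if coef.denominator == 1:
        return f"{coef.numerator} "
    return f"{coef.numerator}/{coef.denominator} "


def format_equation(reaction: Reaction) -> str:
    """Canonical text form: species sorted by name within each side."""
    lhs = sorted(((sp, -c) for sp, c in reaction.stoichiometry.items() if c < 0),
                 key=lambda t: t[0].name)
    rhs = sorted(((sp, c) for sp, c in reaction.stoichiometry.items() if c > 0),
                 key=lambda t: t[0].name)
    def side(terms):
        return " + ".join(f"{_format_coef(c)}{sp.name}({sp.phase})"
                          for sp, c in terms)
    return f"{side(lhs)} -> {side(rhs)}"
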