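"""Molecular formulas: parsing, formatting, masses and atom counts.

A formula here is pure composition — an element→count map in Hill-style flat
notation (``C9H13N3O``).  Parenthesised groups, hydrates, charges and isotope
labels are out of scope: catalogue molecular-formula fields are flat and the
downstream statistics use composition only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .elements import DEFAULT_ALLOWED, DEFAULT_MASS_TABLE, HALOGENS, MassTable

__all__ = [
    "MolecularFormula",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "atom_counts",
    "AtomCounts",
    "degree_of_unsaturation",
]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or disallowed molecular formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """An immutable element→count map.

    Counts must be non-negative with at least one positive entry, and every
    symbol must belong to ``allowed`` (zero-count entries are dropped).
    """

    counts: Mapping[str, int]
    allowed: tuple[str, ...] = field(default=DEFAULT_ALLOWED, compare=False)

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in self.allowed:
                raise FormulaError(f"element symbol {el!r} is not in the allowed set")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise FormulaError(f"count for {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise FormulaError(f"count for {el!r} must be non-negative, got {n}")
            if n > 0:
                cleaned[el] = n
        if not cleaned:
            raise FormulaError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    def get(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterable[str]:
        return iter(self.counts)

    def __str__(self) -> str:
        return format_formula(self)

    @property
    def hill(self) -> str:
        return format_formula(self)


def parse_formula(text: str, allowed: tuple[str, ...] = DEFAULT_ALLOWED) -> MolecularFormula:
    """Parse a Hill-style flat formula string such as ``"C6H6"``.

    Repeated element tokens sum.  Unknown symbols, explicit zero counts and
    empty strings are rejected with a message naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        if symbol not in allowed:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(f"multiplier for {symbol!r} must be positive in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return MolecularFormula(counts, allowed=allowed)


def format_formula(formula: MolecularFormula) -> str:
    """Hill notation: C first, then H, then the rest alphabetically."""
    counts = formula.counts
    order = [el for el in ("C", "H") if el in counts]
    order += sorted(el for el in counts if el not in ("C", "H"))
    return "".join(f"{el}{counts[el]}" if counts[el] != 1 else el for el in order)


def molecular_weight(
    formula: MolecularFormula,
    table: MassTable = DEFAULT_MASS_TABLE,
    mode: str = "average",
) -> float:
    """Molecular weight in Da: exact weighted sum over the mass table.

    ``mode="average"`` uses standard atomic weights (g/mol, the scale used for
    molar-price conversion); ``mode="nominal"`` uses integer most-abundant
    isotope masses (the scale of the nitrogen rule) and yields an integer.
    """
    if mode not in ("average", "nominal"):
        raise ValueError(f"mode must be 'average' or 'nominal', got {mode!r}")
    masses: Mapping[str, float] = table.average_mass if mode == "average" else table.nominal_mass
    total = 0
    for el, n in formula.counts.items():
        if el not in masses:
            raise FormulaError(f"element {el!r} missing from the mass table")
        total += n * masses[el]
    return total


class AtomCounts(NamedTuple):
    ac_total: int
    ac_c: int
    ac_h: int
    ac_hetero: int
    per_element: dict[str, int]


def atom_counts(formula: MolecularFormula) -> AtomCounts:
    """Total, carbon, hydrogen and heteroatom counts of a formula."""
    per = dict(formula.counts)
    ac_c = per.get("C", 0)
    ac_h = per.get("H", 0)
    total = sum(per.values())
    return AtomCounts(total, ac_c, ac_h, total - ac_c - ac_h, per)


def degree_of_unsaturation(formula: MolecularFormula) -> float:
    """DBE = (2·C + 2 + N − H − halogens) / 2.

    A valence-feasible neutral organic formula has a non-negative integer DBE.
    Divalent elements (O, S, Se) do not enter; trivalent P counts like N.
    """
    c = formula.get("C")
    n = formula.get("N") + formula.get("P")
    h = formula.get("H")
    x = sum(formula.get(el) for el in HALOGENS)
    return (2 * c + 2 + n - h - x) / 2.0
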