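"""Element data: allowed symbols, atomic masses, and the organic valence model.

Masses are frozen constants so that every result is reproducible without any
external resource.  ``AVERAGE_MASS`` holds the IUPAC conventional (abridged)
standard atomic weights; ``NOMINAL_MASS`` holds the integer mass number of the
most abundant isotope, which is the mass scale on which the nitrogen rule
(parity of nominal molecular mass equals parity of the nitrogen count for
C/H/N/O compounds) is stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Data version for the embedded mass tables (IUPAC 2021 abridged weights).
MASS_TABLE_VERSION = "iupac-2021-abridged"

#: Elements accepted by default: the common organic set of a building-block
#: catalogue.  Anything outside this set is rejected, never silently ignored.
DEFAULT_ALLOWED: tuple[str, ...] = (
    "C", "H", "N", "O", "S", "F", "Cl", "Br", "I", "Se", "P",
)

#: IUPAC conventional standard atomic weights, Da.
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.904,
}

#: Mass number of the most abundant isotope, Da (integer).
NOMINAL_MASS: dict[str, int] = {
    "H": 1,
    "C": 12,
    "N": 14,
    "O": 16,
    "F": 19,
    "P": 31,
    "S": 32,
    "Cl": 35,
    "Se": 80,
    "Br": 79,
    "I": 127,
}

#: Halogens (monovalent heteroatoms) — enter the degree-of-unsaturation rule
#: with the same sign as hydrogen.
HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I"})

#: Feasible valences per element, lowest first.  Multivalent elements (S, Se,
#: P) use the lowest valence that accommodates the explicit bond order sum.
VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "S": (2, 4, 6),
    "Se": (2, 4, 6),
    "P": (3, 5),
}


@dataclass(frozen=True)
class MassTable:
    """Average and nominal atomic masses over a fixed allowed element set."""

    average_mass: dict[str, float] = field(default_factory=lambda: dict(AVERAGE_MASS))
    nominal_mass: dict[str, int] = field(default_factory=lambda: dict(NOMINAL_MASS))
    version: str = MASS_TABLE_VERSION

    def __post_init__(self) -> None:
        if set(self.average_mass) != set(self.nominal_mass):
            raise ValueError("average and nominal mass tables must cover the same elements")
        for el, nominal in self.nominal_mass.items():
            avg = self.average_mass[el]
            if not (isinstance(nominal, int) and nominal > 0):
                raise ValueError(f"nominal mass of {el} must be a positive integer")
            # 1.5 Da bound: selenium's standard atomic weight (78.971) sits
            # 1.03 Da below its most abundant isotope mass (80)
            if avg <= 0 or abs(avg - nominal) > 1.5:
                raise ValueError(f"average mass of {el} must be positive and within 1.5 Da of nominal")

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self.average_mass)


#: The default mass table used throughout the package.
DEFAULT_MASS_TABLE = MassTable()
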