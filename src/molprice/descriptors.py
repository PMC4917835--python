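"""Per-record molecular descriptors and the nitrogen-rule parity check.

The descriptor set is deliberately small — average and nominal molecular
weight, atom counts (total / C / H / heteroatom / per element) and the two
parities entering the nitrogen rule — because these are the quantities the
structure–price statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elements import DEFAULT_ALLOWED, DEFAULT_MASS_TABLE, MassTable
from .formula import MolecularFormula, atom_counts, molecular_weight, parse_formula

__all__ = ["DescriptorRow", "describe_formula", "nitrogen_parity", "descriptor_table"]


@dataclass(frozen=True)
class DescriptorRow:
    """Computed descriptors for one record."""

    mw_avg: float
    mw_nominal: int
    ac_total: int
    ac_c: int
    ac_h: int
    ac_hetero: int
    per_element: dict[str, int]
    n_parity: str          # parity of the nitrogen count: "even" | "odd"
    mw_parity: str         # parity of the nominal MW: "even" | "odd"
    chno_only: bool        # composition restricted to C, H, N, O

    def __post_init__(self) -> None:
        if self.ac_total != sum(self.per_element.values()):
            raise ValueError("ac_total must equal the sum of per-element counts")
        if self.ac_hetero != self.ac_total - self.ac_c - self.ac_h or self.ac_hetero < 0:
            raise ValueError("ac_hetero must equal ac_total - ac_c - ac_h and be non-negative")


def describe_formula(
    formula: MolecularFormula | str,
    table: MassTable = DEFAULT_MASS_TABLE,
) -> DescriptorRow:
    """Compute the full descriptor row for a formula (or formula string)."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mw_nom = int(molecular_weight(formula, table, mode="nominal"))
    mw_avg = molecular_weight(formula, table, mode="average")
    ac = atom_counts(formula)
    n_n = formula.get("N")
    return DescriptorRow(
        mw_avg=mw_avg,
        mw_nominal=mw_nom,
        ac_total=ac.ac_total,
        ac_c=ac.ac_c,
        ac_h=ac.ac_h,
        ac_hetero=ac.ac_hetero,
        per_element=ac.per_element,
        n_parity="even" if n_n % 2 == 0 else "odd",
        mw_parity="even" if mw_nom % 2 == 0 else "odd",
        chno_only=set(formula.counts) <= {"C", "H", "N", "O"},
    )


def nitrogen_parity(row: DescriptorRow) -> str:
    """Nitrogen-rule check for one descriptor row.

    For C/H/N/O-only compositions the parity of the nominal molecular mass
    must equal the parity of the nitrogen count; a mismatch flags a corrupt
    record (the pipeline treats it as a curation error, not a discovery).
    Returns ``"consistent"``, ``"inconsistent"`` or ``"not_applicable"``.
    """
    if not row.chno_only:
        return "not_applicable"
    return "consistent" if row.mw_parity == row.n_parity else "inconsistent"


def descriptor_table(
    formulas: Iterable[MolecularFormula | str],
    table: MassTable = DEFAULT_MASS_TABLE,
    elements: Sequence[str] = DEFAULT_ALLOWED,
) -> pd.DataFrame:
    """Descriptor DataFrame for a sequence of formulas.

    Columns: ``mw_avg``, ``mw_nominal``, ``ac_total``, ``ac_c``, ``ac_h``,
    ``ac_hetero``, one ``n_<El>`` count per element in ``elements``,
    ``chno_only`` and the two parity columns (0 = even, 1 = odd).
    """
    rows = [describe_formula(f, table) for f in formulas]
    if not rows:
        raise ValueError("no formulas given")
    data: dict[str, np.ndarray] = {
        "mw_avg": np.array([r.mw_avg for r in rows]),
        "mw_nominal": np.array([r.mw_nominal for r in rows], dtype=np.int64),
        "ac_total": np.array([r.ac_total for r in rows], dtype=np.int64),
        "ac_c": np.array([r.ac_c for r in rows], dtype=np.int64),
        "ac_h": np.array([r.ac_h for r in rows], dtype=np.int64),
        "ac_hetero": np.array([r.ac_hetero for r in rows], dtype=np.int64),
    }
    for el in elements:
        data[f"n_{el}"] = np.array([r.per_element.get(el, 0) for r in rows], dtype=np.int64)
    data["chno_only"] = np.array([r.chno_only for r in rows])
    data["mw_parity"] = data["mw_nominal"] % 2
    data["n_parity"] = data["n_N"] % 2 if "n_N" in data else np.zeros(len(rows), dtype=np.int64)
    return pd.DataFrame(data)
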