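"""Minimal SDF (V2000) reading: connection tables → molecular formulas.

Only what a catalogue reader needs is implemented: the atom and bond blocks,
charge entries (atom-block column and ``M  CHG`` lines), and the ``> <tag>``
data items.  Implicit hydrogens are assigned from the standard organic
valence model — per atom, ``max(0, valence − bond-order sum − |charge|)``
with the lowest feasible valence for multivalent S/Se/P.  Aromatic bonds
(type 4) count 1.5 toward the order sum, which is rounded per atom, so a
benzene ring drawn with six aromatic bonds and a Kekulé ring both give each
carbon an order sum of 3 and hence one implicit hydrogen.

V3000 files are rejected explicitly; 2014-era vendor catalogues are V2000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, TextIO

from .elements import DEFAULT_ALLOWED, VALENCES
from .formula import FormulaError, MolecularFormula

__all__ = ["SdfError", "formula_from_ctab", "iter_sdf", "SdfRecord"]

_BOND_ORDER = {1: 1.0, 2: 2.0, 3: 3.0, 4: 1.5}


class SdfError(ValueError):
    """Raised for malformed or unsupported connection tables."""


@dataclass
class SdfRecord:
    """One raw SDF entry: title, molfile text and data items."""

    title: str
    molblock: str
    data: dict[str, str]
    index: int  # 0-based position in the file


def formula_from_ctab(
    molblock: str,
    allowed: tuple[str, ...] = DEFAULT_ALLOWED,
) -> MolecularFormula:
    """Molecular formula of a V2000 molfile, with implicit hydrogens.

    Explicit atoms come from the atom block; each non-hydrogen atom then
    receives ``max(0, valence − order_sum − |charge|)`` implicit hydrogens.
    Fully explicit-H tables therefore round-trip exactly: saturated degrees
    leave nothing to add.
    """
    lines = molblock.splitlines()
    if len(lines) < 4:
        raise SdfError("molfile too short: missing counts line (line 4)")
    counts_line = lines[3]
    if "V3000" in counts_line:
        raise SdfError("V3000 connection tables are not supported (V2000 only)")
    try:
        n_atoms = int(counts_line[0:3])
        n_bonds = int(counts_line[3:6])
    except ValueError as exc:
        raise SdfError(f"malformed counts line (line 4): {counts_line!r}") from exc
    if n_atoms < 1:
        raise SdfError("connection table has no atoms")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise SdfError(f"truncated ctab: expected {n_atoms} atoms and {n_bonds} bonds")

    symbols: list[str] = []
    charges = [0] * n_atoms
    for i in range(n_atoms):
        line = lines[4 + i]
        if len(line) < 34:
            raise SdfError(f"malformed atom line {4 + i + 1}: {line!r}")
        sym = line[31:34].strip()
        if sym not in allowed:
            raise SdfError(f"unsupported element {sym!r} on atom line {4 + i + 1}")
        symbols.append(sym)
        # old-style charge column (4 = no charge in V2000 coding: 1..7 map to +3..-3)
        col = line[36:39].strip() if len(line) >= 39 else ""
        if col and col != "0":
            code = int(col)
            if code in (1, 2, 3, 5, 6, 7):
                charges[i] = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}[code]

    order_sum = [0.0] * n_atoms
    for j in range(n_bonds):
        line = lines[4 + n_atoms + j]
        try:
            a = int(line[0:3]) - 1
            b = int(line[3:6]) - 1
            btype = int(line[6:9])
        except ValueError as exc:
            raise SdfError(f"malformed bond line {4 + n_atoms + j + 1}: {line!r}") from exc
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise SdfError(f"bond line {4 + n_atoms + j + 1} references a missing atom")
        order = _BOND_ORDER.get(btype)
        if order is None:
            raise SdfError(f"unsupported bond type {btype} on line {4 + n_atoms + j + 1}")
        order_sum[a] += order
        order_sum[b] += order

    # M  CHG lines supersede the atom-block charge column
    for line in lines[4 + n_atoms + n_bonds:]:
        if line.startswith("M  CHG"):
            fields = line.split()
            try:
                k = int(fields[2])
                pairs = fields[3:3 + 2 * k]
                for idx, chg in zip(pairs[0::2], pairs[1::2]):
                    charges[int(idx) - 1] = int(chg)
            except (IndexError, ValueError) as exc:
                raise SdfError(f"malformed M  CHG line: {line!r}") from exc
        if line.startswith("M  END"):
            break

    counts: dict[str, int] = {}
    implicit_h = 0
    for sym, osum, chg in zip(symbols, order_sum, charges):
        counts[sym] = counts.get(sym, 0) + 1
        deg = round(osum)
        if sym == "H":
            continue
        valence = next((v for v in VALENCES[sym] if v >= deg), VALENCES[sym][-1])
        implicit_h += max(0, valence - deg - abs(chg))
    if implicit_h:
        counts["H"] = counts.get("H", 0) + implicit_h
    try:
        return MolecularFormula(counts, allowed=allowed)
    except FormulaError as exc:  # pragma: no cover - n_atoms >= 1 guarantees atoms
        raise SdfError(str(exc)) from exc


def iter_sdf(handle: TextIO) -> Iterator[SdfRecord]:
    """Iterate over the records of an SDF stream (``$$$$``-delimited)."""
    block_lines: list[str] = []
    index = 0
    for raw in handle:
        line = raw.rstrip("\n")
        if line.strip() == "$$$$":
            if any(s.strip() for s in block_lines):
                yield _parse_record(block_lines, index)
            index += 1
            block_lines = []
        else:
            block_lines.append(line)
    if any(s.strip() for s in block_lines):
        yield _parse_record(block_lines, index)


def _parse_record(lines: list[str], index: int) -> SdfRecord:
    # molfile runs to "M  END"; data items follow as "> <tag>" then value lines
    end = next((i for i, s in enumerate(lines) if s.startswith("M  END")), None)
    if end is None:
        # no ctab terminator: treat everything before the first data header as molblock
        end = next((i for i, s in enumerate(lines) if s.startswith(">")), len(lines)) - 1
    molblock = "\n".join(lines[: end + 1])
    data: dict[str, str] = {}
    tag: str | None = None
    buf: list[str] = []
    for line in lines[end + 1:]:
        if line.startswith(">"):
            if tag is not None:
                data[tag] = "\n".join(buf).strip()
            lo, hi = line.find("<"), line.rfind(">")
            tag = line[lo + 1:hi] if 0 <= lo < hi else line.lstrip("> ").strip()
            buf = []
        elif tag is not None:
            if line.strip() == "":
                data[tag] = "\n".join(buf).strip()
                tag = None
            else:
                buf.append(line)
    if tag is not None:
        data[tag] = "\n".join(buf).strip()
    title = lines[0].strip() if lines else ""
    return SdfRecord(title=title, molblock=molblock, data=data, index=index)
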