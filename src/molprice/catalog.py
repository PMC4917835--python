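"""Catalogue input, curation and deduplication.

Readers accept either a delimited table (CSV/TSV with a header and an
explicit column map) or an SDF file, and produce validated
:class:`CatalogRecord` collections plus a :class:`CurationReport` whose
category counts always reconcile with the input size.  Records are dropped
— never imputed — when the structure cannot be interpreted or the price is
missing/non-positive; drops are counted and their ids retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .descriptors import descriptor_table
from .formula import FormulaError, MolecularFormula, format_formula, parse_formula
from .sdf import SdfError, formula_from_ctab, iter_sdf

__all__ = [
    "CatalogRecord",
    "CurationReport",
    "read_catalog_table",
    "read_catalog_sdf",
    "deduplicate",
    "records_to_frame",
    "catalog_frame",
    "write_catalog_table",
]

logger = logging.getLogger(__name__)

_CURRENCY = re.compile(r"^[\s$€£]+|[\s$€£]+$")


@dataclass(frozen=True)
class CatalogRecord:
    """One marketed compound: id, composition, weight-based price, optional SAS."""

    record_id: str
    formula: MolecularFormula
    price_wbm: float
    sas: float | None = None
    source_line: int | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not (self.price_wbm > 0):
            raise ValueError(f"price_wbm must be positive, got {self.price_wbm}")
        if self.sas is not None and not pd.notna(self.sas):
            raise ValueError("sas, when present, must be finite")


@dataclass
class CurationReport:
    """Counts of kept and dropped records; categories sum to the input size."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_duplicates: int = 0
    n_dropped_invalid_structure: int = 0
    n_dropped_missing_price: int = 0
    n_sas_missing: int = 0
    dropped_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        total = (
            self.n_kept
            + self.n_dropped_duplicates
            + self.n_dropped_invalid_structure
            + self.n_dropped_missing_price
        )
        if total != self.n_input:
            raise AssertionError(
                f"curation counts do not reconcile: kept+dropped={total} != input={self.n_input}"
            )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_dropped_duplicates": self.n_dropped_duplicates,
            "n_dropped_invalid_structure": self.n_dropped_invalid_structure,
            "n_dropped_missing_price": self.n_dropped_missing_price,
            "n_sas_missing": self.n_sas_missing,
            "dropped_ids": list(self.dropped_ids),
        }


def parse_price(text: object) -> float | None:
    """Parse a price cell: decimal point only, leading/trailing currency symbols
    stripped, thousands separators rejected.  Returns None when unparseable or
    non-positive."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return None
    s = _CURRENCY.sub("", str(text).strip())
    if not s or "," in s:
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    return value if value > 0 else None


def parse_sas(text: object) -> float | None:
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return None
    s = str(text).strip()
    if not s:
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    return value if pd.notna(value) and abs(value) != float("inf") else None


def read_catalog_table(
    path: str | Path,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
    dedup_key: str = "id_or_formula_price",
) -> tuple[list[CatalogRecord], CurationReport]:
    """Read a delimited catalogue table.

    ``columns`` maps the roles ``record_id``, ``formula``, ``price`` and
    (optionally) ``sas`` to header names; defaults use those names verbatim.
    Missing mapped columns are an error naming the column; bad rows are
    dropped and counted, never a crash.
    """
    columns = {"record_id": "record_id", "formula": "formula", "price": "price_wbm",
               "sas": "sas", **(columns or {})}
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    for role in ("record_id", "formula", "price"):
        if columns[role] not in df.columns:
            raise ValueError(f"missing mapped column {columns[role]!r} (role {role!r})")
    has_sas = columns.get("sas") in df.columns

    ids = df[columns["record_id"]].tolist()
    formulas = df[columns["formula"]].tolist()
    prices = df[columns["price"]].tolist()
    sas_col = df[columns["sas"]].tolist() if has_sas else [None] * len(df)

    report = CurationReport(n_input=len(df))
    records: list[CatalogRecord] = []
    for i, (rid, ftext, ptext, stext) in enumerate(zip(ids, formulas, prices, sas_col)):
        rid = str(rid)
        price = parse_price(ptext)
        if price is None:
            report.n_dropped_missing_price += 1
            report.dropped_ids.append(rid)
            logger.debug("row %d (%s): missing or non-positive price", i, rid)
            continue
        try:
            f = parse_formula(str(ftext))
        except FormulaError as exc:
            report.n_dropped_invalid_structure += 1
            report.dropped_ids.append(rid)
            logger.debug("row %d (%s): invalid formula: %s", i, rid, exc)
            continue
        sas = parse_sas(stext) if has_sas else None
        if sas is None:
            report.n_sas_missing += 1
        records.append(CatalogRecord(rid, f, price, sas, source_line=i + 2))

    records, n_dup = deduplicate(records, key=dedup_key)
    report.n_dropped_duplicates = n_dup
    report.n_kept = len(records)
    report.validate()
    logger.info(
        "read %d rows from %s: kept %d, dropped %d invalid, %d priceless, %d duplicates",
        report.n_input, path, report.n_kept, report.n_dropped_invalid_structure,
        report.n_dropped_missing_price, report.n_dropped_duplicates,
    )
    return records, report


def read_catalog_sdf(
    path: str | Path,
    price_field: str,
    mf_field: str | None = None,
    sas_field: str | None = None,
    id_field: str | None = None,
    dedup_key: str = "id_or_formula_price",
) -> tuple[list[CatalogRecord], CurationReport]:
    """Read an SDF (V2000) catalogue.

    The formula comes from ``mf_field`` when present (the vendor MF field wins
    over the connection table — it reflects salts/hydrates the ctab may omit;
    a mismatch is logged), otherwise from the ctab with implicit hydrogens.
    Records with neither an interpretable ctab nor an MF field are dropped and
    counted.
    """
    report = CurationReport()
    records: list[CatalogRecord] = []
    with open(path) as handle:
        for rec in iter_sdf(handle):
            report.n_input += 1
            rid = (rec.data.get(id_field) if id_field else None) or rec.title or f"sdf-{rec.index}"
            price = parse_price(rec.data.get(price_field))
            if price is None:
                report.n_dropped_missing_price += 1
                report.dropped_ids.append(rid)
                continue
            formula = None
            ctab_formula = None
            try:
                ctab_formula = formula_from_ctab(rec.molblock)
            except SdfError as exc:
                logger.debug("record %s: ctab not interpretable: %s", rid, exc)
            if mf_field and rec.data.get(mf_field):
                try:
                    formula = parse_formula(rec.data[mf_field])
                except FormulaError as exc:
                    logger.debug("record %s: bad MF field: %s", rid, exc)
                if formula is not None and ctab_formula is not None and formula != ctab_formula:
                    logger.warning(
                        "record %s: MF field %s disagrees with ctab %s; MF field wins",
                        rid, format_formula(formula), format_formula(ctab_formula),
                    )
            if formula is None:
                formula = ctab_formula
            if formula is None:
                report.n_dropped_invalid_structure += 1
                report.dropped_ids.append(rid)
                continue
            sas = parse_sas(rec.data.get(sas_field)) if sas_field else None
            if sas is None:
                report.n_sas_missing += 1
            records.append(CatalogRecord(rid, formula, price, sas, source_line=rec.index))

    records, n_dup = deduplicate(records, key=dedup_key)
    report.n_dropped_duplicates = n_dup
    report.n_kept = len(records)
    report.validate()
    return records, report


def deduplicate(
    records: Sequence[CatalogRecord],
    key: str = "id_or_formula_price",
) -> tuple[list[CatalogRecord], int]:
    """Drop duplicate records, keeping the first occurrence, order stable.

    ``key`` is ``"id"`` (same record_id), ``"formula_price"`` (identical
    composition and WBM price) or the default ``"id_or_formula_price"``
    (either criterion marks a duplicate).
    """
    if key not in ("id", "formula_price", "id_or_formula_price"):
        raise ValueError(f"unknown duplicate key {key!r}")
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, float]] = set()
    kept: list[CatalogRecord] = []
    removed = 0
    for rec in records:
        pair = (format_formula(rec.formula), rec.price_wbm)
        dup_id = rec.record_id in seen_ids
        dup_pair = pair in seen_pairs
        is_dup = {
            "id": dup_id,
            "formula_price": dup_pair,
            "id_or_formula_price": dup_id or dup_pair,
        }[key]
        if is_dup:
            removed += 1
            continue
        seen_ids.add(rec.record_id)
        seen_pairs.add(pair)
        kept.append(rec)
    return kept, removed


def records_to_frame(records: Iterable[CatalogRecord]) -> pd.DataFrame:
    """Plain catalogue DataFrame: record_id, formula, price_wbm, sas."""
    recs = list(records)
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in recs],
            "formula": [format_formula(r.formula) for r in recs],
            "price_wbm": [r.price_wbm for r in recs],
            "sas": [r.sas if r.sas is not None else float("nan") for r in recs],
        }
    )


def catalog_frame(records: Iterable[CatalogRecord]) -> pd.DataFrame:
    """Catalogue DataFrame joined with all computed descriptors and the molar
    price column ``price_mbm`` ($/mol = price_wbm × average MW)."""
    base = records_to_frame(records)
    if base.empty:
        raise ValueError("no records")
    desc = descriptor_table(base["formula"])
    out = pd.concat([base.reset_index(drop=True), desc.reset_index(drop=True)], axis=1)
    out["price_mbm"] = out["price_wbm"] * out["mw_avg"]
    return out


def write_catalog_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a catalogue (or any tabular output) as TSV, stable and re-readable."""
    frame.to_csv(path, sep="\t", index=False)
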