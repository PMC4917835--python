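"""Data binning: fixed-width bins over a descriptor with per-bin means.

Binning replaces the raw values falling in a small interval by a value
representative of that interval; here each occupied molecular-weight (or
SAS) bin is summarised by its occupancy and the mean of every tracked
variable.  Bins are half-open ``[origin + i·res, origin + (i+1)·res)``
anchored at the origin, so tables at different resolutions compose (two
1-Da bins tile one 2-Da bin exactly).  Empty interior bins are reported
with count 0 and NaN means — flagged, never zero-filled — and excluded
from downstream correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinSpec",
    "BinTable",
    "assign_bin",
    "build_bin_table",
    "frequency_histogram",
    "cumulative_fraction_below",
    "sas_bin_table",
    "write_bin_table",
    "rebin",
]

#: Variables summarised per bin when present in the input frame.
DEFAULT_TRACKED = (
    "price_wbm", "price_mbm", "ac_total", "ac_c", "ac_h", "ac_hetero", "sas",
)


@dataclass(frozen=True)
class BinSpec:
    """Binning rule: variable, width, origin and the occupancy threshold used
    when a caller asks for 'stable' bins only."""

    variable: str = "mw_avg"
    resolution: float = 1.0
    origin: float = 0.0
    min_occupancy: int = 1
    representative: str = "center"  # bin label for correlations: "center" | "mean"

    def __post_init__(self) -> None:
        if not (self.resolution > 0):
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.min_occupancy < 1:
            raise ValueError(f"min_occupancy must be >= 1, got {self.min_occupancy}")
        if self.representative not in ("center", "mean"):
            raise ValueError(f"representative must be 'center' or 'mean'")


def assign_bin(values, spec: BinSpec):
    """Bin index by the floor rule: ``floor((value − origin)/resolution)``.

    Vectorised; non-finite values are rejected.
    """
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot bin non-finite values")
    idx = np.floor((arr - spec.origin) / spec.resolution).astype(np.int64)
    return int(idx) if np.isscalar(values) else idx


@dataclass(frozen=True)
class BinTable:
    """Per-bin occupancy and means at a stated resolution.

    ``table`` has one row per bin index from the lowest to the highest
    occupied bin (empty interior bins included with count 0), columns
    ``bin_index, lower, upper, count`` and one ``mean_<var>`` per tracked
    variable.
    """

    spec: BinSpec
    table: pd.DataFrame
    n_records: int
    tracked: tuple[str, ...] = field(default=())

    def occupied(self, min_occupancy: int | None = None) -> pd.DataFrame:
        """Rows of bins meeting the occupancy threshold (spec default)."""
        thr = self.spec.min_occupancy if min_occupancy is None else min_occupancy
        return self.table[self.table["count"] >= thr]

    def representatives(self, rows: pd.DataFrame | None = None) -> np.ndarray:
        """Bin representative values (x-axis of binned correlations)."""
        rows = self.table if rows is None else rows
        if self.spec.representative == "center":
            return (rows["lower"] + 0.5 * self.spec.resolution).to_numpy()
        return rows[f"mean_{self.spec.variable}"].to_numpy()


def build_bin_table(
    frame: pd.DataFrame,
    spec: BinSpec,
    tracked: Sequence[str] | None = None,
) -> BinTable:
    """Bin a descriptor frame on ``spec.variable`` and average tracked columns.

    Conserves mass exactly: counts sum to ``len(frame)`` and, for every
    tracked variable, ``Σ count·mean`` equals the raw column sum (over
    non-missing values).
    """
    if frame is None or len(frame) == 0:
        raise ValueError("cannot bin an empty record set")
    if spec.variable not in frame.columns:
        raise ValueError(f"binning variable {spec.variable!r} not in frame")
    if tracked is None:
        tracked = [c for c in DEFAULT_TRACKED if c in frame.columns and c != spec.variable]
    else:
        missing = [c for c in tracked if c not in frame.columns]
        if missing:
            raise ValueError(f"tracked columns not in frame: {missing}")
    # track the binning variable's own within-bin mean too (used when
    # representative="mean")
    tracked = list(dict.fromkeys([spec.variable, *tracked]))

    idx = assign_bin(frame[spec.variable].to_numpy(), spec)
    lo, hi = int(idx.min()), int(idx.max())
    full = pd.RangeIndex(lo, hi + 1)

    counts = pd.Series(idx).value_counts().reindex(full, fill_value=0)
    out = pd.DataFrame(
        {
            "bin_index": full.to_numpy(),
            "lower": spec.origin + full.to_numpy() * spec.resolution,
            "upper": spec.origin + (full.to_numpy() + 1) * spec.resolution,
            "count": counts.to_numpy(),
        }
    )
    grouped = frame[tracked].groupby(idx)
    means = grouped.mean().reindex(full)
    for var in tracked:
        out[f"mean_{var}"] = means[var].to_numpy()
    return BinTable(spec=spec, table=out, n_records=len(frame), tracked=tuple(tracked))


def frequency_histogram(bin_table: BinTable) -> pd.DataFrame:
    """Ordered (bin_index, lower, upper, count, cumulative_fraction) table."""
    t = bin_table.table[["bin_index", "lower", "upper", "count"]].copy()
    t["cumulative_fraction"] = t["count"].cumsum() / bin_table.n_records
    return t


def cumulative_fraction_below(bin_table: BinTable, cut: float) -> float:
    """Fraction of records with binning-variable value strictly below ``cut``.

    ``cut`` must lie on a bin boundary (multiple of the resolution from the
    origin) so that the answer is exact rather than interpolated.
    """
    spec = bin_table.spec
    edge = (cut - spec.origin) / spec.resolution
    if abs(edge - round(edge)) > 1e-9:
        raise ValueError(f"cut {cut} is not a bin boundary at resolution {spec.resolution}")
    below = bin_table.table["bin_index"] < round(edge)
    return float(bin_table.table.loc[below, "count"].sum() / bin_table.n_records)


def sas_bin_table(
    frame: pd.DataFrame,
    spec: BinSpec | None = None,
    tracked: Sequence[str] | None = None,
) -> tuple[BinTable, int]:
    """Bin on the synthetic-accessibility score, excluding records without one.

    Returns the bin table and the count of excluded (SAS-missing) records,
    mirroring how records that fail scoring are dropped and counted rather
    than imputed.
    """
    spec = spec or BinSpec(variable="sas", resolution=0.1)
    if spec.variable != "sas":
        raise ValueError("sas_bin_table bins on the 'sas' column")
    if "sas" not in frame.columns:
        raise ValueError("frame has no 'sas' column")
    present = frame[np.isfinite(frame["sas"].to_numpy(dtype=float))]
    n_excluded = len(frame) - len(present)
    if len(present) == 0:
        raise ValueError("all records are missing a SAS value")
    if tracked is None:
        tracked = [c for c in ("price_wbm", "price_mbm", "ac_total") if c in frame.columns]
    return build_bin_table(present, spec, tracked), n_excluded


def write_bin_table(bin_table: BinTable, path: str | Path) -> None:
    """Serialise as TSV with the binning rule recorded in header comments."""
    spec = bin_table.spec
    with open(path, "w") as fh:
        fh.write(f"# variable={spec.variable} resolution={spec.resolution} "
                 f"origin={spec.origin} representative={spec.representative} "
                 f"n_records={bin_table.n_records}\n")
        bin_table.table.to_csv(fh, sep="\t", index=False)


def rebin(bin_table: BinTable, factor: int) -> BinTable:
    """Aggregate a bin table to a coarser resolution (an integer multiple).

    Count-weighted means; used to compare rendering resolutions (a 1-Da
    table aggregated by 2 must match a directly built 2-Da table exactly).
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    spec = bin_table.spec
    t = bin_table.table
    coarse_idx = np.floor_divide(t["bin_index"].to_numpy(), factor)
    lo, hi = int(coarse_idx.min()), int(coarse_idx.max())
    full = pd.RangeIndex(lo, hi + 1)
    counts = pd.Series(t["count"].to_numpy(), index=coarse_idx).groupby(level=0).sum().reindex(full, fill_value=0)
    out = pd.DataFrame(
        {
            "bin_index": full.to_numpy(),
            "lower": spec.origin + full.to_numpy() * spec.resolution * factor,
            "upper": spec.origin + (full.to_numpy() + 1) * spec.resolution * factor,
            "count": counts.to_numpy(),
        }
    )
    for var in bin_table.tracked:
        col = f"mean_{var}"
        weighted = (t[col] * t["count"]).groupby(coarse_idx).sum().reindex(full)
        with np.errstate(invalid="ignore"):
            out[col] = weighted.to_numpy() / np.where(counts.to_numpy() > 0, counts.to_numpy(), np.nan)
    new_spec = replace(spec, resolution=spec.resolution * factor)
    return BinTable(spec=new_spec, table=out, n_records=bin_table.n_records,
                    tracked=bin_table.tracked)
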