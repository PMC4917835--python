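"""Heteroatom sub-libraries and the nitrogen-rule parity price comparison.

For C/H/N/O-only compounds the nitrogen rule splits every nominal-mass bin
into two structurally meaningful classes: even nominal MW ↔ even nitrogen
count and odd ↔ odd.  Comparing mean prices between the two classes inside
the same MW bin (iso-MW bins) isolates the effect of composition at fixed
mass; the per-element price profiles do the same thing one heteroatom
count at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinSpec, assign_bin
from .elements import DEFAULT_ALLOWED

__all__ = [
    "SubLibrarySpec",
    "extract_sublibrary",
    "parity_split_bins",
    "heteroatom_price_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubLibrarySpec:
    """Membership rule: at least ``min_count`` atoms of ``element``; with
    ``chno_only`` the composition must also be within {C, H, N, O} (required
    for nitrogen-rule validity)."""

    element: str = "N"
    min_count: int = 1
    chno_only: bool = False

    def __post_init__(self) -> None:
        if self.element not in DEFAULT_ALLOWED:
            raise ValueError(f"element {self.element!r} is not in the allowed set")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


def extract_sublibrary(frame: pd.DataFrame, spec: SubLibrarySpec) -> pd.DataFrame:
    """Filter a descriptor frame to the sub-library; original order preserved.

    An empty result is returned with a warning, not an error.
    """
    col = f"n_{spec.element}"
    if col not in frame.columns:
        raise ValueError(f"frame has no per-element column {col!r}")
    mask = frame[col].to_numpy() >= spec.min_count
    if spec.chno_only:
        if "chno_only" not in frame.columns:
            raise ValueError("frame has no 'chno_only' column")
        mask &= frame["chno_only"].to_numpy().astype(bool)
    out = frame[mask]
    if out.empty:
        logger.warning("sub-library %s>=%d%s is empty", spec.element, spec.min_count,
                       " (CHNO only)" if spec.chno_only else "")
    return out


def parity_split_bins(
    frame: pd.DataFrame,
    bin_spec: BinSpec | None = None,
    price_col: str = "price_wbm",
) -> pd.DataFrame:
    """Per-MW-bin mean price and mean N count, split by nominal-MW parity.

    Parity is always taken on the nominal (integer) molecular mass — the
    scale on which the nitrogen rule holds; under a CHNO-only sub-library
    this split coincides exactly with the parity of the nitrogen count.
    Only doubly-occupied bins (both classes present) are emitted.  Columns
    include which class carries the larger mean N count and whether that
    class is the cheaper one in the bin.

    The default bin width is 2 Da: a 1-Da bin of *average* MW contains
    essentially a single nominal mass (the mass defect of C/H/N/O
    compositions stays well below 1 Da in this MW range), hence a single
    parity class, so no bin would ever be doubly occupied.
    """
    bin_spec = bin_spec or BinSpec(variable="mw_avg", resolution=2.0)
    for col in (bin_spec.variable, "mw_nominal", "n_N", price_col):
        if col not in frame.columns:
            raise ValueError(f"frame has no column {col!r}")
    if frame.empty:
        return pd.DataFrame(
            columns=["bin_index", "lower", "upper", "count_even", "count_odd",
                     "mean_price_even", "mean_price_odd", "mean_n_even", "mean_n_odd",
                     "higher_n_class", "higher_n_is_cheaper"]
        )
    idx = assign_bin(frame[bin_spec.variable].to_numpy(), bin_spec)
    parity = frame["mw_nominal"].to_numpy() % 2
    g = pd.DataFrame(
        {
            "bin": idx,
            "parity": parity,
            "price": frame[price_col].to_numpy(dtype=float),
            "n_N": frame["n_N"].to_numpy(dtype=float),
        }
    ).groupby(["bin", "parity"]).agg(count=("price", "size"),
                                     mean_price=("price", "mean"),
                                     mean_n=("n_N", "mean"))
    wide = g.unstack("parity")
    # doubly-occupied bins only
    both = wide[("count", 0)].notna() & wide[("count", 1)].notna()
    wide = wide[both]
    out = pd.DataFrame(
        {
            "bin_index": wide.index.to_numpy(),
            "lower": bin_spec.origin + wide.index.to_numpy() * bin_spec.resolution,
            "upper": bin_spec.origin + (wide.index.to_numpy() + 1) * bin_spec.resolution,
            "count_even": wide[("count", 0)].to_numpy(dtype=int),
            "count_odd": wide[("count", 1)].to_numpy(dtype=int),
            "mean_price_even": wide[("mean_price", 0)].to_numpy(),
            "mean_price_odd": wide[("mean_price", 1)].to_numpy(),
            "mean_n_even": wide[("mean_n", 0)].to_numpy(),
            "mean_n_odd": wide[("mean_n", 1)].to_numpy(),
        }
    )
    higher_even = out["mean_n_even"] > out["mean_n_odd"]
    out["higher_n_class"] = np.where(higher_even, "even", "odd")
    out["higher_n_is_cheaper"] = np.where(
        higher_even,
        out["mean_price_even"] < out["mean_price_odd"],
        out["mean_price_odd"] < out["mean_price_even"],
    )
    return out.reset_index(drop=True)


def heteroatom_price_profile(
    frame: pd.DataFrame,
    element: str,
    min_occupancy: int = 30,
) -> pd.DataFrame:
    """Mean prices as a function of the per-molecule count of one element.

    One row per count value k = 0, 1, 2, … with occupancy, mean WBM and
    (when available) mean MBM price; rows with fewer than ``min_occupancy``
    records are kept but flagged unstable, since sparse-count means are
    noise.
    """
    col = f"n_{element}"
    if col not in frame.columns:
        raise ValueError(f"frame has no per-element column {col!r}")
    if "price_wbm" not in frame.columns:
        raise ValueError("frame has no 'price_wbm' column")
    agg = {"n": ("price_wbm", "size"), "mean_price_wbm": ("price_wbm", "mean")}
    if "price_mbm" in frame.columns:
        agg["mean_price_mbm"] = ("price_mbm", "mean")
    prof = frame.groupby(frame[col].to_numpy()).agg(**agg)
    prof.index.name = "count"
    prof = prof.reset_index().sort_values("count").reset_index(drop=True)
    prof.insert(0, "element", element)
    prof["stable"] = prof["n"] >= min_occupancy
    return prof
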