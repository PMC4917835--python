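"""Correlation matrices, binned correlations, and Monte-Carlo credibility nulls.

Two nulls calibrate how much correlation binning can manufacture by chance:

* the *random-variate* null correlates the fixed descriptor vector with
  i.i.d. Uniform(0,1) draws, and
* the *shuffled-price* null correlates it with random permutations of the
  real price column, which preserves the price distribution exactly.

For an n-record library the unbinned mean |R| of either null is the
half-normal expectation √(2/(πn)); after binning, one point per occupied
bin, the effective sample size drops to the number of bins and the null
|R| inflates accordingly — the reason binned trends need this calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import BinSpec, BinTable, assign_bin

__all__ = [
    "pearson_r",
    "CorrelationMatrix",
    "correlation_matrix",
    "binned_r",
    "NullResult",
    "random_variate_null",
    "shuffled_price_null",
    "expected_null_abs_r",
]

#: Default variable order of the library-wide correlation matrix.
DEFAULT_MATRIX_VARIABLES = ("price_wbm", "price_mbm", "mw_avg", "ac_total", "sas")


def _validated_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for a constant vector")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Rejects constant vectors (undefined R) and length < 3.
    """
    x, y = _validated_xy(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson matrix over the listwise-complete record subset."""

    variables: tuple[str, ...]
    r: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.variables), columns=list(self.variables))


def correlation_matrix(
    frame: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_MATRIX_VARIABLES,
) -> CorrelationMatrix:
    """Pairwise Pearson matrix over records complete in every variable.

    Records missing any variable (e.g. no SAS) are excluded listwise; the
    count actually used is reported in ``n``.
    """
    variables = tuple(v for v in variables if v in frame.columns)
    if len(variables) < 2:
        raise ValueError("need at least two variables present in the frame")
    sub = frame[list(variables)].astype(float).dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 complete records, got {len(sub)}")
    data = sub.to_numpy().T
    if np.any(np.ptp(data, axis=1) == 0):
        bad = [v for v, row in zip(variables, data) if np.ptp(row) == 0]
        raise ValueError(f"constant variable(s) {bad} make the correlation undefined")
    r = np.corrcoef(data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(variables=variables, r=r, n=len(sub))


def binned_r(
    bin_table: BinTable,
    variable: str,
    min_occupancy: int | None = None,
    x_max: float | None = None,
) -> float:
    """Correlation across bins: bin representative values vs bin means.

    One point per occupied bin, unweighted — the large fluctuations of
    sparse bins are part of the signal being assessed, not averaged away.
    ``x_max`` restricts to bins whose upper edge does not exceed it (the
    usual "below 400 Da" stability filter).
    """
    col = f"mean_{variable}"
    if col not in bin_table.table.columns:
        raise ValueError(f"variable {variable!r} is not tracked in this bin table")
    rows = bin_table.occupied(min_occupancy)
    if x_max is not None:
        rows = rows[rows["upper"] <= x_max]
    if len(rows) < 3:
        raise ValueError(f"need at least 3 occupied bins, got {len(rows)}")
    return pearson_r(bin_table.representatives(rows), rows[col].to_numpy())


@dataclass(frozen=True)
class NullResult:
    """Summary of one Monte-Carlo credibility simulation."""

    mode: str            # "random_variate" | "shuffled_price"
    binned: bool
    runs: int
    n: int
    seed: int
    mean_abs_r: float
    sd_abs_r: float

    @property
    def stderr(self) -> float:
        """Monte-Carlo standard error of ``mean_abs_r``."""
        return self.sd_abs_r / np.sqrt(self.runs)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode, "binned": self.binned, "runs": self.runs,
            "n": self.n, "seed": self.seed,
            "mean_abs_r": self.mean_abs_r, "sd_abs_r": self.sd_abs_r,
            "stderr": self.stderr,
        }


def expected_null_abs_r(n: int) -> float:
    """Analytic large-n mean |R| of an independent null: √(2/(πn))."""
    return float(np.sqrt(2.0 / (np.pi * n)))


class _FastNullEngine:
    """Precomputed pieces for repeated |R| evaluation against a fixed x.

    Unbinned: |r| via centered dot products (x centered once).  Binned: y is
    averaged within x's bins (occupied, occupancy-filtered) and correlated
    against the bin representatives.
    """

    def __init__(self, x: np.ndarray, bin_spec: BinSpec | None, min_occupancy: int = 1):
        self.x = np.asarray(x, dtype=float)
        if self.x.ndim != 1 or self.x.size < 3:
            raise ValueError("x must be a 1-D vector of length >= 3")
        if not np.isfinite(self.x).all() or np.ptp(self.x) == 0:
            raise ValueError("x must be finite and non-constant")
        self.binned = bin_spec is not None
        if not self.binned:
            xc = self.x - self.x.mean()
            self._xc = xc
            self._sxx = float(np.sqrt(xc @ xc))
        else:
            idx = assign_bin(self.x, bin_spec)
            offset = int(idx.min())
            idx = idx - offset
            counts = np.bincount(idx)
            keep = counts >= max(min_occupancy, 1)
            if keep.sum() < 3:
                raise ValueError("fewer than 3 occupied bins under the binning spec")
            centers = bin_spec.origin + (np.arange(counts.size) + offset + 0.5) * bin_spec.resolution
            # representative of each kept bin: center by default, mean-x optional
            if bin_spec.representative == "mean":
                sums = np.bincount(idx, weights=self.x)
                reps = sums[keep] / counts[keep]
            else:
                reps = centers[keep]
            self._idx = idx
            self._counts = counts
            self._keep = keep
            rc = reps - reps.mean()
            self._rc = rc
            self._srr = float(np.sqrt(rc @ rc))

    def abs_r(self, y: np.ndarray) -> float:
        if not self.binned:
            ym = y.mean()
            syy = np.sqrt(y @ y - y.size * ym * ym)
            return abs(float(self._xc @ y) / (self._sxx * syy))
        means = np.bincount(self._idx, weights=y)[self._keep] / self._counts[self._keep]
        mc = means - means.mean()
        denom = self._srr * np.sqrt(mc @ mc)
        if denom == 0:
            raise ValueError("constant bin means: correlation undefined")
        return abs(float(self._rc @ mc) / denom)


def random_variate_null(
    x,
    runs: int = 10_000,
    seed: int = 0,
    bin_spec: BinSpec | None = None,
    min_occupancy: int = 1,
) -> NullResult:
    """Mean |R| between x and i.i.d. Uniform(0,1) vectors over seeded runs.

    With ``bin_spec`` given, each run's uniform draw is averaged within x's
    bins first (the binned variant of the credibility simulation).
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    engine = _FastNullEngine(np.asarray(x, dtype=float), bin_spec, min_occupancy)
    rng = np.random.default_rng(seed)
    vals = np.empty(runs)
    for k in range(runs):
        vals[k] = engine.abs_r(rng.random(engine.x.size))
    return NullResult("random_variate", engine.binned, runs, engine.x.size, seed,
                      float(vals.mean()), float(vals.std(ddof=1)) if runs > 1 else 0.0)


def shuffled_price_null(
    x,
    prices,
    runs: int = 10_000,
    seed: int = 0,
    bin_spec: BinSpec | None = None,
    min_occupancy: int = 1,
) -> NullResult:
    """Mean |R| between x and uniformly random permutations of the price vector.

    Each run applies a fresh Fisher–Yates permutation, so every order
    statistic of the price column is conserved exactly; only the pairing
    with x is destroyed.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    x = np.asarray(x, dtype=float)
    p = np.asarray(prices, dtype=float)
    if p.shape != x.shape:
        raise ValueError("prices must have the same length as x")
    if not np.isfinite(p).all() or np.ptp(p) == 0:
        raise ValueError("prices must be finite and non-constant")
    engine = _FastNullEngine(x, bin_spec, min_occupancy)
    rng = np.random.default_rng(seed)
    vals = np.empty(runs)
    for k in range(runs):
        vals[k] = engine.abs_r(rng.permutation(p))
    return NullResult("shuffled_price", engine.binned, runs, x.size, seed,
                      float(vals.mean()), float(vals.std(ddof=1)) if runs > 1 else 0.0)
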