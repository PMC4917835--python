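"""Weight-based vs molar-based price metrics.

The market quotes prices per weight unit ($/g, the weight-based metric,
WBM).  Chemistry counts molecules, so the molar-based metric (MBM) is the
price of one mole: P2 = P1 × MW, with MW the average molecular weight in
g/mol.  A gram of benzene (MW 78) holds three times as many molecules as a
gram of [18]annulene (MW 3×78 = 234) — at equal WBM price the larger
molecule is three times as expensive per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PricePair", "wbm_to_mbm", "mbm_to_wbm", "molecules_per_gram_ratio"]


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")


def wbm_to_mbm(p1_wbm, mw_avg):
    """Convert a $/g price to $/mol: P2 = P1 × MW.  Accepts scalars or arrays."""
    _require_positive(p1_wbm=p1_wbm, mw_avg=mw_avg)
    return np.multiply(p1_wbm, mw_avg)[()] if np.isscalar(p1_wbm) and np.isscalar(mw_avg) \
        else np.multiply(p1_wbm, mw_avg)


def mbm_to_wbm(p2_mbm, mw_avg):
    """Convert a $/mol price back to $/g: P1 = P2 / MW."""
    _require_positive(p2_mbm=p2_mbm, mw_avg=mw_avg)
    return np.divide(p2_mbm, mw_avg)[()] if np.isscalar(p2_mbm) and np.isscalar(mw_avg) \
        else np.divide(p2_mbm, mw_avg)


def molecules_per_gram_ratio(mw_a: float, mw_b: float) -> float:
    """How many molecules of A fit in the weight of one molecule of B: MW_b / MW_a.

    benzene (78) vs [18]annulene (234) → 3.0: an equal weight unit holds
    three benzene molecules per annulene molecule.
    """
    _require_positive(mw_a=mw_a, mw_b=mw_b)
    return float(mw_b) / float(mw_a)


@dataclass(frozen=True)
class PricePair:
    """A consistent (WBM, MBM, MW) triple; MBM is derived, never free."""

    p1_wbm: float
    mw_avg: float

    def __post_init__(self) -> None:
        _require_positive(p1_wbm=self.p1_wbm, mw_avg=self.mw_avg)

    @property
    def p2_mbm(self) -> float:
        return self.p1_wbm * self.mw_avg
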