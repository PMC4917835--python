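"""Synthetic commercial-catalogue generator.

The real building-block catalogue behind the analysis is not
redistributable, so this module generates catalogues with the same
statistical skeleton: a truncated-Gaussian-mixture molecular-weight
distribution on [218.26, 738.74] Da calibrated so that 96% of records fall
below 350 Da and 99% below 400 Da with the global mode near 250 Da;
valence-feasible molecular formulas matching each sampled MW to within
0.5 Da; a piecewise-linear structural price model (positive MW slope below
a 250-Da breakpoint, flat above, per-element premiums/discounts, Gaussian
noise, positive floor) whose intercept is calibrated so the library mean
WBM price lands on 537.83 $/g; and a synthetic-accessibility stand-in —
an affine function of the total atom count plus noise, scaled to hit a
target corr(SAS, AC) of 0.380.  The SAS column is a declared stand-in for
a commercial scoring program, with no claim of fidelity to it.

Everything is driven by one integer seed and is bit-reproducible; the
planted parameters are returned alongside the catalogue so recovery tests
can compare against ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .elements import AVERAGE_MASS, NOMINAL_MASS
from .formula import MolecularFormula

__all__ = [
    "MwMixture",
    "PriceModel",
    "SasModel",
    "GeneratorConfig",
    "sample_mw",
    "formula_for_mw",
    "price_for_record",
    "generate_catalog",
    "write_minimal_sdf",
]

#: Heteroatom palette in Hill order after C, H.
_HETERO_ORDER = ("Br", "Cl", "F", "I", "N", "O", "S", "Se")
_HALOGEN_SET = ("F", "Cl", "Br", "I")


@dataclass(frozen=True)
class MwMixture:
    """Truncated-normal mixture for the MW distribution.

    Default weights were solved (closed-form truncated-normal CDFs) so the
    mixture hits P(MW<350)=0.96 and P(MW<400)=0.99 exactly on the support
    [218.26, 738.74] Da, with a narrow component putting the global mode at
    ~250 Da, a broad mid-mass body, and a small heavy tail.
    """

    weights: tuple[float, ...] = (0.7364702268875327, 0.25234554844466023, 0.011184224667807064)
    means: tuple[float, ...] = (250.0, 305.0, 470.0)
    sds: tuple[float, ...] = (16.0, 38.0, 105.0)

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("weights, means and sds must have equal length")
        if any(s <= 0 for s in self.sds) or any(w < 0 for w in self.weights):
            raise ValueError("sds must be positive and weights non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class PriceModel:
    """Structural WBM price model, $/g.

    price = max(floor, base + slope·min(MW, breakpoint) + Σ_e n_e·premium_e + ε),
    ε ~ N(0, noise_sd²).  ``base`` is calibrated per catalogue (intercept =
    target mean − mean structural part), so the library mean hits
    ``target_mean_price``.  N carries a positive premium; O/S/F are priced
    like carbon-backbone mass; Cl/Br/I/Se are planted as discounts.
    """

    mw_slope_low: float = 3.0
    breakpoint: float = 250.0
    premiums: dict[str, float] = field(default_factory=lambda: {
        "N": 15.0, "O": 6.0, "S": 4.0, "F": 4.0,
        "Cl": -18.0, "Br": -22.0, "I": -28.0, "Se": -24.0,
    })
    noise_sd: float = 150.0
    floor_price: float = 1.0
    target_mean_price: float = 537.83


@dataclass(frozen=True)
class SasModel:
    """Synthetic-accessibility stand-in: affine in the total atom count.

    The noise standard deviation is chosen from the attenuation identity
    corr = 1/√(1 + σ²_noise/σ²_signal) so that corr(SAS, AC) over the
    library matches ``target_corr_ac``; scores are clipped to [1, 10].
    """

    ac_weight: float = 0.06
    target_mean: float = 4.0
    target_corr_ac: float = 0.380
    clip: tuple[float, float] = (1.0, 10.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study-condition configuration of the synthetic catalogue."""

    n: int = 100_000
    seed: int = 0
    mw_range: tuple[float, float] = (218.26, 738.74)
    mixture: MwMixture = field(default_factory=MwMixture)
    price_model: PriceModel = field(default_factory=PriceModel)
    sas_model: SasModel = field(default_factory=SasModel)
    #: Poisson rate per heteroatom (counts per molecule); rates keep every
    #: sub-library populated (>=1000 members at n=1e5) while CHNO-only
    #: compositions remain the majority.
    element_rates: dict[str, float] = field(default_factory=lambda: {
        "N": 1.1, "O": 1.0, "S": 0.15, "F": 0.12,
        "Cl": 0.12, "Br": 0.05, "I": 0.02, "Se": 0.012,
    })
    #: H:C ratio range of the carbon/hydrogen skeleton (uniform draw).
    hc_ratio_range: tuple[float, float] = (1.0, 1.9)
    max_retries: int = 80

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.seed < 2**63):
            raise ValueError("seed must be a non-negative integer")
        unknown = set(self.element_rates) - set(_HETERO_ORDER)
        if unknown:
            raise ValueError(f"unsupported palette elements: {sorted(unknown)}")


def sample_mw(config: GeneratorConfig, count: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw molecular weights from the truncated mixture; fully seeded."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mix = config.mixture
    a, b = config.mw_range
    comp = rng.choice(len(mix.weights), size=count, p=np.asarray(mix.weights) / sum(mix.weights))
    out = np.empty(count)
    for k, (mu, sd) in enumerate(zip(mix.means, mix.sds)):
        mask = comp == k
        if mask.any():
            za, zb = (a - mu) / sd, (b - mu) / sd
            out[mask] = truncnorm.rvs(za, zb, loc=mu, scale=sd, size=int(mask.sum()),
                                      random_state=rng)
    return out


def _sample_compositions(
    targets: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Valence-feasible formulas matching each target MW to within 0.5 Da.

    Heteroatom counts are Poisson draws; the C/H skeleton is solved from the
    residual mass at a sampled H:C ratio, with H rounded to the parity that
    makes the degree of unsaturation DBE = (2C + 2 + N − H − X)/2 a
    non-negative integer (X = halogen count).  Records failing the mass
    tolerance or feasibility are redrawn; a record that cannot be realised
    within ``max_retries`` attempts is an error.
    """
    n = targets.size
    c_out = np.zeros(n, dtype=np.int64)
    h_out = np.zeros(n, dtype=np.int64)
    het_out = {el: np.zeros(n, dtype=np.int64) for el in _HETERO_ORDER}
    rates = config.element_rates
    lo_u, hi_u = config.hc_ratio_range
    m_c, m_h = AVERAGE_MASS["C"], AVERAGE_MASS["H"]

    pending = np.arange(n)
    for _ in range(config.max_retries):
        m = pending.size
        het = {el: (rng.poisson(rates[el], m) if rates.get(el, 0) > 0
                    else np.zeros(m, dtype=np.int64)) for el in _HETERO_ORDER}
        het_mass = sum(het[el] * AVERAGE_MASS[el] for el in _HETERO_ORDER)
        u = rng.uniform(lo_u, hi_u, m)
        rem = targets[pending] - het_mass
        c = np.rint(rem / (m_c + m_h * u)).astype(np.int64)
        c = np.maximum(c, 1)
        n_n = het["N"]
        x = sum(het[el] for el in _HALOGEN_SET)
        req_parity = (n_n + x) % 2
        h_real = (rem - m_c * c) / m_h
        h = np.rint(h_real).astype(np.int64)
        wrong = (h % 2) != req_parity
        h = np.where(wrong, h + np.where(h_real >= h, 1, -1), h)
        mw = m_c * c + m_h * h + het_mass
        dbe2 = 2 * c + 2 + n_n - h - x
        ok = (
            (np.abs(mw - targets[pending]) <= 0.5)
            & (h >= 0) & (c >= 1) & (dbe2 >= 0) & (rem > m_c + m_h)
        )
        sel = pending[ok]
        c_out[sel] = c[ok]
        h_out[sel] = h[ok]
        for el in _HETERO_ORDER:
            het_out[el][sel] = het[el][ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise RuntimeError(
            f"could not realise formulas for {pending.size} targets within "
            f"{config.max_retries} attempts (palette too restrictive?)"
        )
    return {"C": c_out, "H": h_out, **het_out}


def _formula_strings(counts: dict[str, np.ndarray]) -> np.ndarray:
    """Hill-notation strings, vectorised (C, H, then alphabetical)."""
    n = counts["C"].size
    parts = np.full(n, "", dtype=object)
    order = ["C", "H"] + sorted(_HETERO_ORDER)
    for el in order:
        cnt = counts[el]
        digits = cnt.astype(str).astype(object)
        token = np.where(cnt == 0, "", np.where(cnt == 1, el, el + digits))
        parts = parts + token.astype(object)
    return parts


def formula_for_mw(
    target_mw: float,
    config: GeneratorConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> MolecularFormula:
    """One valence-feasible formula within 0.5 Da of the target MW."""
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _sample_compositions(np.asarray([float(target_mw)]), config, rng)
    return MolecularFormula({el: int(v[0]) for el, v in counts.items() if v[0] > 0})


def _structural_price(counts: dict[str, np.ndarray], mw: np.ndarray, model: PriceModel) -> np.ndarray:
    s = model.mw_slope_low * np.minimum(mw, model.breakpoint)
    for el, prem in model.premiums.items():
        s = s + counts[el] * prem
    return s


def price_for_record(
    formula: MolecularFormula,
    mw: float,
    config: GeneratorConfig | None = None,
    noise: float = 0.0,
    base: float = 0.0,
) -> float:
    """Scalar price-model evaluation at an explicit noise draw and intercept.

    Deterministic given its arguments; the library-level intercept
    calibration happens in :func:`generate_catalog`.
    """
    config = config or GeneratorConfig()
    model = config.price_model
    counts = {el: np.asarray([formula.get(el)]) for el in ("C", "H", *_HETERO_ORDER)}
    s = _structural_price(counts, np.asarray([mw]), model)[0]
    return float(max(model.floor_price, base + s + noise))


def generate_catalog(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a full synthetic catalogue and its ground-truth parameters.

    Returns a DataFrame with one row per record — id, Hill formula, WBM and
    MBM prices, SAS, and every descriptor column the pipeline computes — and
    a dict of the planted parameters (calibrated intercepts, premiums,
    mixture, seeds and the closed-form planted P2–MW correlation) for
    recovery tests.  Identical config → identical catalogue, bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    mw = sample_mw(config, config.n, rng)
    counts = _sample_compositions(mw, config, rng)

    # exact masses of the realised formulas (within 0.5 Da of the sampled MW)
    mw_avg = sum(counts[el] * AVERAGE_MASS[el] for el in counts)
    mw_nominal = sum(counts[el] * NOMINAL_MASS[el] for el in counts)

    model = config.price_model
    structural = _structural_price(counts, mw_avg, model)
    base = model.target_mean_price - float(structural.mean())
    price = np.maximum(model.floor_price,
                       base + structural + rng.normal(0.0, model.noise_sd, config.n))

    ac_total = sum(counts[el] for el in counts)
    sas_model = config.sas_model
    b = sas_model.ac_weight
    signal_sd = b * float(ac_total.std())
    rho = sas_model.target_corr_ac
    sas_noise_sd = signal_sd * np.sqrt(1.0 / rho**2 - 1.0)
    sas_base = sas_model.target_mean - b * float(ac_total.mean())
    sas = np.clip(sas_base + b * ac_total + rng.normal(0.0, sas_noise_sd, config.n),
                  *sas_model.clip)

    hetero = ac_total - counts["C"] - counts["H"]
    chno = sum(counts[el] for el in _HETERO_ORDER if el not in ("N", "O")) == 0
    frame = pd.DataFrame(
        {
            "record_id": np.char.add("SYN", np.arange(1, config.n + 1).astype(str)),
            "formula": _formula_strings(counts),
            "price_wbm": price,
            "sas": sas,
            "mw_avg": mw_avg.astype(float),
            "mw_nominal": mw_nominal.astype(np.int64),
            "ac_total": ac_total,
            "ac_c": counts["C"],
            "ac_h": counts["H"],
            "ac_hetero": hetero,
            **{f"n_{el}": counts[el] for el in _HETERO_ORDER},
            "chno_only": chno,
            "mw_parity": mw_nominal % 2,
            "n_parity": counts["N"] % 2,
        }
    )
    frame["price_mbm"] = frame["price_wbm"] * frame["mw_avg"]

    ground_truth = {
        "seed": config.seed,
        "n": config.n,
        "mixture": asdict(config.mixture),
        "price_model": {**asdict(model), "base": base},
        "sas_model": {**asdict(sas_model), "noise_sd": sas_noise_sd, "base": sas_base},
        "element_rates": dict(config.element_rates),
        "planted_p2_mw_r": planted_p2_mw_correlation(structural + base, mw_avg, model.noise_sd),
    }
    return frame, ground_truth


def planted_p2_mw_correlation(structural_price: np.ndarray, mw: np.ndarray,
                              noise_sd: float) -> float:
    """Closed-form planted corr(P2, MW) of the price model, noise integrated out.

    With P1 = S + ε (ε independent, zero-mean, sd ``noise_sd``) and
    P2 = P1·MW: Cov(P2, MW) = Cov(S·MW, MW) and Var(P2) = Var(S·MW) +
    σ²·E[MW²].  The price floor is ignored (it binds with negligible
    probability under the default model).
    """
    s = np.asarray(structural_price, dtype=float)
    w = np.asarray(mw, dtype=float)
    sw = s * w
    cov = float(np.mean(sw * w) - sw.mean() * w.mean())
    var_p2 = float(sw.var() + noise_sd**2 * np.mean(w**2))
    return cov / np.sqrt(var_p2 * w.var())


def write_minimal_sdf(
    frame: pd.DataFrame,
    path,
    mf_field: str = "MF",
    price_field: str = "PRICE",
    sas_field: str = "SAS",
) -> None:
    """Write the catalogue as a minimal SDF: an empty V2000 ctab per record
    with the formula in an MF property field (the reader's MF-wins rule picks
    it up) plus price and SAS data items.  For reader round-trip tests only —
    no structures are invented."""
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.record_id}\n\n\n")
            fh.write("  0  0  0  0  0  0  0  0  0  0999 V2000\n")
            fh.write("M  END\n")
            fh.write(f"> <{mf_field}>\n{row.formula}\n\n")
            fh.write(f"> <{price_field}>\n{row.price_wbm}\n\n")
            if sas_field and hasattr(row, "sas"):
                fh.write(f"> <{sas_field}>\n{row.sas}\n\n")
            fh.write("$$$$\n")
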