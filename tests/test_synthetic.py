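import numpy as np
import pandas as pd
import pytest

from molprice.elements import AVERAGE_MASS
from molprice.formula import degree_of_unsaturation, parse_formula
from molprice.synthetic import (
    GeneratorConfig,
    MwMixture,
    PriceModel,
    _sample_compositions,
    formula_for_mw,
    generate_catalog,
    price_for_record,
    sample_mw,
)

CH_ONLY = {el: 0.0 for el in ("N", "O", "S", "F", "Cl", "Br", "I", "Se")}


def test_sample_mw_range_and_determinism():
    cfg = GeneratorConfig(n=10, seed=3)
    a = sample_mw(cfg, 5000, rng=3)
    b = sample_mw(cfg, 5000, rng=3)
    np.testing.assert_array_equal(a, b)
    lo, hi = cfg.mw_range
    assert a.min() >= lo and a.max() <= hi


def test_mixture_validation():
    with pytest.raises(ValueError):
        MwMixture(weights=(0.5, 0.4), means=(250.0, 300.0), sds=(10.0, 20.0))
    with pytest.raises(ValueError):
        MwMixture(weights=(1.0,), means=(250.0,), sds=(-1.0,))


def test_formula_for_mw_ch_palette_recovers_benzene():
    """With a C/H-only palette, the unique feasible formula within 0.5 Da of
    78.11 is C6H6 (enumeration: all other C/H pairs in range violate DBE)."""
    candidates = [
        (c, h)
        for c in range(1, 10)
        for h in range(0, 25)
        if abs(c * AVERAGE_MASS["C"] + h * AVERAGE_MASS["H"] - 78.11) <= 0.5
        and h % 2 == 0 and 2 * c + 2 - h >= 0
    ]
    assert candidates == [(6, 6)]
    cfg = GeneratorConfig(n=1, seed=0, element_rates=CH_ONLY)
    for seed in range(5):
        f = formula_for_mw(78.11, cfg, seed=seed)
        assert f.counts == {"C": 6, "H": 6}


def test_compositions_hit_target_mass_and_are_valence_feasible():
    cfg = GeneratorConfig(n=1, seed=0)
    rng = np.random.default_rng(11)
    targets = rng.uniform(*cfg.mw_range, 5000)
    counts = _sample_compositions(targets, cfg, rng)
    mw = sum(counts[el] * AVERAGE_MASS[el] for el in counts)
    np.testing.assert_array_less(np.abs(mw - targets), 0.5 + 1e-12)
    halogens = counts["F"] + counts["Cl"] + counts["Br"] + counts["I"]
    dbe2 = 2 * counts["C"] + 2 + counts["N"] - counts["H"] - halogens
    assert (dbe2 >= 0).all() and (dbe2 % 2 == 0).all()
    assert (counts["C"] >= 1).all() and (counts["H"] >= 0).all()


def test_chn_palette_obeys_nitrogen_rule():
    rates = dict(CH_ONLY, N=1.5)
    cfg = GeneratorConfig(n=1, seed=0, element_rates=rates)
    rng = np.random.default_rng(2)
    counts = _sample_compositions(rng.uniform(220, 400, 2000), cfg, rng)
    mw_nominal = 12 * counts["C"] + counts["H"] + 14 * counts["N"]
    assert np.array_equal(mw_nominal % 2, counts["N"] % 2)


def test_price_model_premium_is_exact_in_noise_free_limit():
    cfg = GeneratorConfig(n=1, seed=0)
    f1 = parse_formula("C10H14N2")
    f2 = parse_formula("C10H13ClN2")  # one Cl more, one H less
    mw = 250.0  # same bin; slope term identical
    p1 = price_for_record(f1, mw, cfg, noise=0.0, base=500.0)
    p2 = price_for_record(f2, mw, cfg, noise=0.0, base=500.0)
    prem = cfg.price_model.premiums["Cl"]
    assert p2 - p1 == pytest.approx(prem)
    assert prem < 0  # Cl is planted as a discount


def test_price_floor_applies():
    cfg = GeneratorConfig(n=1, seed=0)
    f = parse_formula("C6H6")
    assert price_for_record(f, 250.0, cfg, noise=-1e9, base=0.0) == cfg.price_model.floor_price


def test_noise_free_binned_price_increases_below_breakpoint():
    """With zero price noise the planted MW slope makes binned mean WBM price
    strictly increasing over the 218-250 Da bins."""
    from molprice.binning import BinSpec, build_bin_table

    model = PriceModel(noise_sd=0.0)
    frame, _ = generate_catalog(GeneratorConfig(n=30_000, seed=5, price_model=model))
    bt = build_bin_table(frame, BinSpec(resolution=1.0), tracked=["price_wbm"])
    occ = bt.occupied(10)
    below = occ[occ["upper"] <= 250.0]
    means = below["mean_price_wbm"].to_numpy()
    assert len(means) > 20
    # bin-to-bin composition (premium content) oscillates with ~2-Da period,
    # so assert the planted trend as a near-perfect rank correlation
    import scipy.stats

    rho = scipy.stats.spearmanr(np.arange(len(means)), means).statistic
    assert rho > 0.9


def test_generate_catalog_deterministic():
    cfg = GeneratorConfig(n=2000, seed=77)
    a, gta = generate_catalog(cfg)
    b, gtb = generate_catalog(cfg)
    pd.testing.assert_frame_equal(a, b)
    assert gta == gtb


def test_generated_formulas_parse_and_match_descriptors(catalog_small):
    frame, _ = catalog_small
    sample = frame.sample(200, random_state=0)
    for _, row in sample.iterrows():
        f = parse_formula(row["formula"])
        assert f.get("C") == row["ac_c"] and f.get("H") == row["ac_h"]
        assert degree_of_unsaturation(f) >= 0
        assert float(degree_of_unsaturation(f)).is_integer()


def test_sas_clipping_and_high_correlation_limit():
    from molprice.synthetic import SasModel

    cfg = GeneratorConfig(n=20_000, seed=9,
                          sas_model=SasModel(target_corr_ac=0.999))
    frame, _ = generate_catalog(cfg)
    assert frame["sas"].between(1.0, 10.0).all()
    assert np.corrcoef(frame["sas"], frame["ac_total"])[0, 1] > 0.98


def test_catalog_survives_curation_without_drops(tmp_path, catalog_small):
    from molprice.catalog import read_catalog_table, write_catalog_table

    frame, _ = catalog_small
    subset = frame.iloc[:2000][["record_id", "formula", "price_wbm", "sas"]]
    path = tmp_path / "catalog.tsv"
    write_catalog_table(subset, path)
    records, report = read_catalog_table(path, sep="\t")
    assert report.n_kept == len(subset)
    assert report.n_dropped_duplicates == 0
    assert report.n_dropped_invalid_structure == 0


def test_ground_truth_planted_correlation_matches_sample(catalog_small):
    """The closed-form planted P2-MW correlation predicts the sample value."""
    frame, gt = catalog_small
    sample_r = np.corrcoef(frame["price_mbm"], frame["mw_avg"])[0, 1]
    assert sample_r == pytest.approx(gt["planted_p2_mw_r"], abs=0.05)
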