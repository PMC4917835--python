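import math
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from molprice.binning import (
    BinSpec,
    assign_bin,
    build_bin_table,
    cumulative_fraction_below,
    frequency_histogram,
    rebin,
    sas_bin_table,
)


def brute_force_bins(frame, spec, tracked):
    """Independent group-by oracle: plain dict accumulation, no pandas."""
    groups = defaultdict(list)
    for _, row in frame.iterrows():
        idx = math.floor((row[spec.variable] - spec.origin) / spec.resolution)
        groups[idx].append(row)
    out = {}
    for idx, rows in groups.items():
        means = {v: sum(r[v] for r in rows) / len(rows) for v in tracked}
        out[idx] = (len(rows), means)
    return out


def random_frame(rng, n=1000):
    return pd.DataFrame(
        {
            "mw_avg": rng.uniform(218, 740, n),
            "price_wbm": rng.lognormal(5, 1, n),
            "ac_total": rng.integers(10, 80, n).astype(float),
            "sas": rng.uniform(1, 10, n),
        }
    )


@pytest.mark.parametrize(
    "value, res, expected",
    [(249.99, 1.0, 249), (250.0, 1.0, 250), (251.3, 2.0, 125), (-0.5, 1.0, -1)],
)
def test_assign_bin_floor_rule(value, res, expected):
    assert assign_bin(value, BinSpec(resolution=res)) == expected


def test_assign_bin_rejects_non_finite():
    with pytest.raises(ValueError):
        assign_bin(float("nan"), BinSpec())


def test_build_bin_table_small_example():
    frame = pd.DataFrame({"mw_avg": [250.1, 250.9, 251.2, 300.0],
                          "price_wbm": [10.0, 20.0, 5.0, 7.0]})
    bt = build_bin_table(frame, BinSpec(resolution=1.0))
    occ = bt.occupied()
    assert dict(zip(occ["bin_index"], occ["count"])) == {250: 2, 251: 1, 300: 1}
    assert occ.set_index("bin_index").loc[250, "mean_price_wbm"] == pytest.approx(15.0)
    # empty interior bins are present, flagged by count 0 and NaN means
    interior = bt.table.set_index("bin_index").loc[252]
    assert interior["count"] == 0 and np.isnan(interior["mean_price_wbm"])
    # disjoint half-open tiling
    assert (bt.table["upper"].to_numpy()[:-1] == bt.table["lower"].to_numpy()[1:]).all()


def test_build_bin_table_matches_brute_force_oracle(rng):
    frame = random_frame(rng, n=1000)
    spec = BinSpec(resolution=1.0)
    tracked = ["price_wbm", "ac_total", "sas"]
    bt = build_bin_table(frame, spec, tracked=tracked)
    oracle = brute_force_bins(frame, spec, tracked)
    occ = bt.occupied().set_index("bin_index")
    assert set(occ.index) == set(oracle)
    for idx, (count, means) in oracle.items():
        assert occ.loc[idx, "count"] == count
        for v in tracked:
            assert occ.loc[idx, f"mean_{v}"] == pytest.approx(means[v], rel=1e-12)


def test_bin_mean_conservation(rng):
    frame = random_frame(rng, n=5000)
    bt = build_bin_table(frame, BinSpec(resolution=2.0))
    t = bt.occupied()
    assert int(bt.table["count"].sum()) == len(frame)
    for var in ("price_wbm", "ac_total"):
        total = (t["count"] * t[f"mean_{var}"]).sum()
        assert total == pytest.approx(frame[var].sum(), rel=1e-9)


def test_build_bin_table_rejections(rng):
    with pytest.raises(ValueError):
        build_bin_table(pd.DataFrame({"mw_avg": []}), BinSpec())
    with pytest.raises(ValueError, match="missing"):
        build_bin_table(random_frame(rng, 10), BinSpec(), tracked=["missing"])


def test_frequency_histogram_and_cumulative(rng):
    frame = random_frame(rng, n=2000)
    bt = build_bin_table(frame, BinSpec(resolution=1.0))
    hist = frequency_histogram(bt)
    assert hist["count"].sum() == 2000
    assert hist["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)
    assert cumulative_fraction_below(bt, 350.0) == pytest.approx(
        (frame["mw_avg"] < 350.0).mean())
    top = math.floor(frame["mw_avg"].max()) + 1
    assert cumulative_fraction_below(bt, float(top)) == 1.0
    with pytest.raises(ValueError, match="boundary"):
        cumulative_fraction_below(bt, 350.5)


def test_single_record_histogram():
    frame = pd.DataFrame({"mw_avg": [300.2], "price_wbm": [3.0]})
    bt = build_bin_table(frame, BinSpec(resolution=1.0))
    assert len(bt.table) == 1 and bt.table.loc[0, "count"] == 1


def test_sas_bin_table_excludes_missing(rng):
    frame = random_frame(rng, n=500)
    frame.loc[:49, "sas"] = np.nan
    bt, n_excluded = sas_bin_table(frame, BinSpec(variable="sas", resolution=0.1))
    assert n_excluded == 50
    assert int(bt.table["count"].sum()) == 450
    # oracle equality on the SAS axis
    present = frame.dropna(subset=["sas"])
    oracle = brute_force_bins(present, BinSpec(variable="sas", resolution=0.1),
                              ["price_wbm"])
    occ = bt.occupied().set_index("bin_index")
    for idx, (count, means) in oracle.items():
        assert occ.loc[idx, "count"] == count
        assert occ.loc[idx, "mean_price_wbm"] == pytest.approx(means["price_wbm"], rel=1e-12)
    all_missing = frame.copy()
    all_missing["sas"] = np.nan
    with pytest.raises(ValueError):
        sas_bin_table(all_missing)


def test_rebin_matches_direct_coarse_table(rng):
    """A 1-Da table aggregated by 2 equals the directly built 2-Da table."""
    frame = random_frame(rng, n=4000)
    fine = build_bin_table(frame, BinSpec(resolution=1.0))
    coarse = build_bin_table(frame, BinSpec(resolution=2.0))
    agg = rebin(fine, 2)
    f, c = agg.occupied().reset_index(drop=True), coarse.occupied().reset_index(drop=True)
    assert (f["bin_index"] == c["bin_index"]).all()
    assert (f["count"] == c["count"]).all()
    np.testing.assert_allclose(f["mean_price_wbm"], c["mean_price_wbm"], rtol=1e-9)


def test_resolution_robustness_on_catalog(catalog_small):
    """The binned mean-price curve is stable under a 1 -> 2 Da resolution
    change below 400 Da (the densely occupied range)."""
    frame, _ = catalog_small
    fine = build_bin_table(frame, BinSpec(resolution=1.0), tracked=["price_wbm"])
    coarse = build_bin_table(frame, BinSpec(resolution=2.0), tracked=["price_wbm"])
    agg = rebin(fine, 2)
    a = agg.occupied().set_index("bin_index")
    c = coarse.occupied().set_index("bin_index")
    sel = a.index.intersection(c.index)
    sel = sel[(a.loc[sel, "upper"] <= 400.0)]
    np.testing.assert_allclose(a.loc[sel, "mean_price_wbm"],
                               c.loc[sel, "mean_price_wbm"], rtol=1e-9)
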