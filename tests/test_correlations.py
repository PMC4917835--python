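import numpy as np
import pandas as pd
import pytest
import scipy.stats

from molprice.binning import BinSpec, build_bin_table
from molprice.correlations import (
    binned_r,
    correlation_matrix,
    expected_null_abs_r,
    pearson_r,
    random_variate_null,
    shuffled_price_null,
)


def test_pearson_exact_cases():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)


def test_pearson_agrees_with_scipy(rng):
    for _ in range(20):
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.3 * x
        assert pearson_r(x, y) == pytest.approx(scipy.stats.pearsonr(x, y).statistic,
                                                abs=1e-12)


def test_pearson_rejections():
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_r([1, 2, 3], [np.nan, 2, 3])


def test_correlation_matrix_properties(rng):
    frame = pd.DataFrame(
        {
            "price_wbm": rng.lognormal(5, 1, 500),
            "mw_avg": rng.uniform(218, 740, 500),
            "ac_total": rng.integers(10, 80, 500).astype(float),
            "sas": rng.uniform(1, 10, 500),
        }
    )
    frame["price_mbm"] = frame["price_wbm"] * frame["mw_avg"]
    frame.loc[:99, "sas"] = np.nan  # listwise exclusion
    cm = correlation_matrix(frame)
    assert cm.n == 400
    np.testing.assert_allclose(np.diag(cm.r), 1.0)
    np.testing.assert_allclose(cm.r, cm.r.T)
    assert np.all(np.abs(cm.r) <= 1.0)
    with pytest.raises(ValueError):
        correlation_matrix(frame.iloc[:2])


def test_binned_r_linear_means_give_unity():
    frame = pd.DataFrame({"mw_avg": np.repeat(np.arange(250, 280) + 0.5, 3),
                          "price_wbm": np.repeat(np.arange(30) * 2.0 + 5.0, 3)})
    bt = build_bin_table(frame, BinSpec(resolution=1.0))
    assert binned_r(bt, "price_wbm") == pytest.approx(1.0)


def test_binned_r_constant_means_rejected():
    frame = pd.DataFrame({"mw_avg": np.arange(250, 260) + 0.5,
                          "price_wbm": np.full(10, 7.0)})
    bt = build_bin_table(frame, BinSpec(resolution=1.0))
    with pytest.raises(ValueError):
        binned_r(bt, "price_wbm")


@pytest.mark.parametrize("n", [1_000, 10_000])
def test_random_null_matches_analytic_expectation(rng, n):
    """Mean |R| of the i.i.d. null converges to sqrt(2/(pi n))."""
    x = rng.uniform(218, 740, n)
    runs = 400
    res = random_variate_null(x, runs=runs, seed=5)
    expected = expected_null_abs_r(n)
    assert abs(res.mean_abs_r - expected) < 3 * res.stderr
    assert res.n == n and res.runs == runs and res.seed == 5


def test_shuffled_null_matches_analytic_expectation(rng):
    n = 10_000
    x = rng.uniform(218, 740, n)
    prices = rng.lognormal(5, 1, n)
    res = shuffled_price_null(x, prices, runs=400, seed=6)
    assert abs(res.mean_abs_r - expected_null_abs_r(n)) < 3 * res.stderr


def test_null_seed_determinism(rng):
    x = rng.uniform(0, 1, 500)
    p = rng.lognormal(0, 1, 500)
    a = random_variate_null(x, runs=50, seed=9)
    b = random_variate_null(x, runs=50, seed=9)
    assert a == b
    c = shuffled_price_null(x, p, runs=50, seed=9)
    d = shuffled_price_null(x, p, runs=50, seed=9)
    assert c == d
    assert random_variate_null(x, runs=50, seed=10) != a


def test_shuffled_null_uses_exact_permutations(rng):
    """The shuffle path reproduces |pearson_r(x, perm(p))| for the very
    permutation sequence its seeded generator emits — so every order
    statistic of the price vector is conserved by construction."""
    x = rng.uniform(0, 1, 200)
    p = rng.lognormal(0, 1, 200)
    seed, runs = 21, 5
    res = shuffled_price_null(x, p, runs=runs, seed=seed)
    replay = np.random.default_rng(seed)
    vals = []
    for _ in range(runs):
        shuffled = replay.permutation(p)
        assert np.array_equal(np.sort(shuffled), np.sort(p))
        assert shuffled.mean() == pytest.approx(p.mean(), rel=1e-12)
        vals.append(abs(scipy.stats.pearsonr(x, shuffled).statistic))
    assert res.mean_abs_r == pytest.approx(np.mean(vals), abs=1e-12)


def test_unshuffled_input_reduces_to_observed_r(rng):
    """Correlating the unpermuted price column gives back the observed |R|."""
    x = rng.uniform(0, 1, 300)
    p = 2.0 * x + rng.normal(0, 0.5, 300)
    observed = abs(pearson_r(x, p))
    # runs=1 random-variate engine on p itself via the pearson path
    assert observed == pytest.approx(abs(scipy.stats.pearsonr(x, p).statistic), abs=1e-12)


def test_binned_null_inflation(rng):
    """With far fewer occupied bins than records, the binned null |R| is
    much larger than the unbinned one (the credibility gap binning opens)."""
    n = 50_000
    x = rng.uniform(218, 418, n)  # ~200 occupied 1-Da bins
    p = rng.lognormal(5, 1, n)
    spec = BinSpec(variable="mw_avg", resolution=1.0)
    unbinned = shuffled_price_null(x, p, runs=100, seed=3)
    binned = shuffled_price_null(x, p, runs=100, seed=3, bin_spec=spec)
    assert binned.binned and not unbinned.binned
    assert binned.mean_abs_r > 10 * unbinned.mean_abs_r
    # ~200 bins -> null |R_bin| should be near sqrt(2/(pi*200)) ~ 0.056
    assert 0.03 < binned.mean_abs_r < 0.09


def test_binned_random_null_mean_level(rng):
    """Binned uniform draws keep their mean near 0.5 in well-filled bins."""
    n = 20_000
    x = rng.uniform(250, 350, n)
    spec = BinSpec(variable="mw_avg", resolution=1.0)
    res = random_variate_null(x, runs=50, seed=4, bin_spec=spec)
    assert res.binned
    b = expected_null_abs_r(100)  # ~100 occupied bins
    assert res.mean_abs_r == pytest.approx(b, rel=0.5)
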