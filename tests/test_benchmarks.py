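import numpy as np
import pytest
import statsmodels.api as sm

from pleiopls.benchmarks import (
    asset_max_subset,
    asset_pvalue,
    benchmark_table,
    metaskat_pvalue_permutation,
    metaskat_score,
    per_study_wald_stats,
)
from pleiopls.errors import IdentifierError, ParameterError
from .conftest import make_dataset


def test_per_study_wald_matches_statsmodels(binary_dataset):
    row = per_study_wald_stats(binary_dataset, "v1")
    for m, (label, rows) in enumerate(binary_dataset.obs_sets.blocks()):
        x = sm.add_constant(binary_dataset.X[rows, 0])
        res = sm.Logit(binary_dataset.Y[rows, 0], x).fit(disp=0)
        assert row.beta[m] == pytest.approx(res.params[1], rel=1e-6)
        assert row.se[m] == pytest.approx(res.bse[1], rel=1e-6)
    with pytest.raises(IdentifierError):
        per_study_wald_stats(binary_dataset, "nope")


def test_wald_linear_for_quantitative(toy_dataset):
    row = per_study_wald_stats(toy_dataset, "v2")
    rows = toy_dataset.study_rows("s1")
    res = sm.OLS(toy_dataset.Y[rows, 0], sm.add_constant(toy_dataset.X[rows, 1])).fit()
    assert row.beta[0] == pytest.approx(res.params[1], rel=1e-8)


def test_wald_flags_constant_column(binary_dataset):
    d = binary_dataset.copy()
    d.X[d.study_rows("s1"), 2] = 1.0
    row = per_study_wald_stats(d, "v3")
    assert np.isnan(row.z[0]) and np.isfinite(row.z[1])


def _brute_force_max_subset(z, sizes):
    """Independent enumeration over bitmasks (oracle for asset_max_subset)."""
    avail = [m for m in range(len(z)) if np.isfinite(z[m])]
    best = -np.inf
    for mask in range(1, 2 ** len(avail)):
        subset = [avail[i] for i in range(len(avail)) if mask >> i & 1]
        total = sum(sizes[m] for m in subset)
        stat = abs(sum(np.sqrt(sizes[m] / total) * z[m] for m in subset))
        best = max(best, stat)
    return best


def test_asset_max_subset_matches_brute_force():
    rng = np.random.default_rng(30)
    for _ in range(50):
        M = int(rng.integers(1, 6))
        z = rng.normal(scale=2, size=M)
        if M > 2:
            z[rng.integers(0, M)] = np.nan  # exercise missing handling
        sizes = rng.integers(20, 200, size=M).astype(float)
        if not np.isfinite(z).any():
            continue
        stat, subset = asset_max_subset(z, sizes)
        assert stat == pytest.approx(_brute_force_max_subset(z, sizes), abs=1e-12)
        assert all(np.isfinite(z[m]) for m in subset)


def test_asset_detects_discordant_studies():
    # strong opposite effects: the best subset drops one study
    z = np.array([4.0, -4.0])
    sizes = np.array([100.0, 100.0])
    stat, subset = asset_max_subset(z, sizes)
    assert stat == pytest.approx(4.0)
    assert len(subset) == 1
    # pooling both would cancel entirely
    assert abs(np.sqrt(0.5) * z[0] + np.sqrt(0.5) * z[1]) == pytest.approx(0.0)


def test_asset_pvalue_bonferroni():
    p_small = asset_pvalue(5.0, M=2)
    p_large = asset_pvalue(1.0, M=2)
    assert 0 < p_small < p_large <= 1
    # cap at 1
    assert asset_pvalue(0.0, M=10) == 1.0
    with pytest.raises(ParameterError):
        asset_pvalue(1.0, M=2, method="unknown")


def test_metaskat_score_hand_computed():
    d = make_dataset(n_per_study=(6, 6), group_sizes=(2, 2), seed=31)
    q = metaskat_score(d, "g1")
    expected = 0.0
    y = d.Y[:, 0]
    for _, rows in d.obs_sets.blocks():
        resid = y[rows] - y[rows].mean()
        S = d.X[np.ix_(rows, [0, 1])].T @ resid
        expected += float((S**2).sum())
    assert q == pytest.approx(expected, rel=1e-12)
    with pytest.raises(IdentifierError):
        metaskat_score(d, "nope")


def test_metaskat_score_sign_insensitive():
    d = make_dataset(n_per_study=(10, 10), group_sizes=(3, 3), seed=32)
    q1 = metaskat_score(d, "g1")
    flipped = d.copy()
    flipped.X[:, 0] *= -1.0
    assert metaskat_score(flipped, "g1") == pytest.approx(q1, rel=1e-12)


def test_metaskat_permutation_null_calibration():
    d = make_dataset(n_per_study=(40, 40), group_sizes=[4] * 10, binary=True, seed=33)
    rng = np.random.default_rng(33)
    d.Y[:, 0] = rng.permutation(d.Y[:, 0])  # break any association
    pvals = [
        metaskat_pvalue_permutation(d, g, R=100, seed=40 + i)
        for i, g in enumerate(d.var_groups.labels)
    ]
    assert all(0 < p <= 1 for p in pvals)
    assert sum(p <= 0.05 for p in pvals) <= 3  # ~0.5 expected under the null
    with pytest.raises(ParameterError):
        metaskat_pvalue_permutation(d, "g1", R=50)


def test_benchmark_tables(binary_dataset):
    t = benchmark_table(binary_dataset, "metaskat", R=100, seed=1)
    assert list(t.columns) == ["feature_id", "statistic", "p_value", "selected"]
    assert len(t) == binary_dataset.K
    t2 = benchmark_table(binary_dataset, "asset")
    assert len(t2) == binary_dataset.p
    assert {"p_adjusted", "selected", "subset"}.issubset(t2.columns)
    ok = t2["p_adjusted"].notna()
    assert (t2.loc[ok, "p_adjusted"] >= t2.loc[ok, "p_value"] - 1e-12).all()
    with pytest.raises(ParameterError):
        benchmark_table(binary_dataset, "other")
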