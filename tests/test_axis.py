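"""Transect binning, co-expression, group PCA and pseudobulk statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spikemap import axis, domains
from spikemap.errors import FormatError
from spikemap.io import counts_from_arrays


def _matrix_with_layer(Z, genes=None, raw=None):
    Z = np.asarray(Z, dtype=float)
    genes = genes or [f"g{i}" for i in range(Z.shape[1])]
    m = counts_from_arrays(raw if raw is not None else np.round(np.abs(Z)),
                           [f"c{i}" for i in range(Z.shape[0])], genes)
    m.layers["lognorm"] = Z
    m.layers["norm_counts"] = Z
    return m


def _cells(ys):
    return pd.DataFrame(
        {"center_x": 0.0, "center_y": np.asarray(ys, float), "volume": 1000.0,
         "sample_id": "s"},
        index=pd.Index([f"c{i}" for i in range(len(ys))], name="cell_id"),
    )


# ---------------------------------------------------------------------------
# transect


def test_transect_extremes_and_uniform():
    cells = _cells([0.0, 29.0])
    m = _matrix_with_layer([[1.0], [1.0]])
    prof = axis.transect_bin(cells, m, n_bins=30)
    assert prof.bin_of_cell["c0"] == 1 and prof.bin_of_cell["c1"] == 30
    assert prof.bin_counts.sum() == 2
    cells = _cells(np.linspace(0, 100, 40))
    m = _matrix_with_layer(np.full((40, 2), 3.0))
    prof = axis.transect_bin(cells, m, n_bins=10)
    filled = prof.bin_means.dropna()
    np.testing.assert_allclose(filled.to_numpy(), 3.0)
    assert prof.bin_counts.sum() == 40  # bins partition the cells
    with pytest.raises(FormatError, match="n_bins"):
        axis.transect_bin(cells, m, n_bins=1)


def test_transect_matches_groupby_oracle():
    rng = np.random.default_rng(0)
    ys = rng.uniform(0, 500, 500)
    Z = rng.normal(0, 1, (500, 4))
    cells, m = _cells(ys), _matrix_with_layer(Z)
    prof = axis.transect_bin(cells, m, n_bins=30)
    edges = np.linspace(ys.min(), ys.max(), 31)
    oracle_bins = np.clip(np.searchsorted(edges, ys, side="right") - 1, 0, 29) + 1
    np.testing.assert_array_equal(prof.bin_of_cell.to_numpy(), oracle_bins)
    oracle = pd.DataFrame(Z).groupby(oracle_bins).mean()
    for b in oracle.index:
        np.testing.assert_allclose(prof.bin_means.loc[b].to_numpy(), oracle.loc[b].to_numpy())


def test_ratio_identity_and_degenerate():
    cells = _cells(np.linspace(0, 290, 60))
    m = _matrix_with_layer(np.full((60, 1), 2.0))
    assert axis.basal_central_ratio(m, cells, "g0") == pytest.approx(1.0)
    Z = np.zeros((60, 1))
    Z[:20] = 4.0  # expression only in the basal third
    m = _matrix_with_layer(Z)
    assert axis.basal_central_ratio(m, cells, "g0") == np.inf
    with pytest.raises(FormatError, match="panel"):
        axis.basal_central_ratio(m, cells, "nope")


# ---------------------------------------------------------------------------
# co-expression


def _coex_labeling(n, labels=None):
    return domains.DomainLabeling(
        labels=pd.Series(labels if labels is not None else [0] * n,
                         index=[f"c{i}" for i in range(n)], dtype=int)
    )


def test_coexpression_enumeration():
    raw = np.array([[1, 0], [0, 2], [3, 4], [0, 0]], dtype=float)
    m = counts_from_arrays(raw, [f"c{i}" for i in range(4)], ["A", "B"])
    cx = axis.coexpression_summary(m, _coex_labeling(4), "A", "B")
    row = cx.table.loc["all"]
    assert row["pct_only_a"] == 25.0 and row["pct_only_b"] == 25.0
    assert row["pct_both"] == 25.0 and row["pct_neither"] == 25.0


def test_coexpression_same_gene_identity():
    raw = np.array([[2], [0], [1]], dtype=float)
    m = counts_from_arrays(raw, ["c0", "c1", "c2"], ["A"])
    cx = axis.coexpression_summary(m, _coex_labeling(3), "A", "A")
    row = cx.table.loc["all"]
    assert row["pct_both"] == pytest.approx(100 * 2 / 3)
    assert row["pct_only_a"] == 0.0 and row["pct_only_b"] == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_coexpression_matches_contingency_oracle(seed):
    rng = np.random.default_rng(seed)
    raw = rng.poisson(0.7, (200, 3)).astype(float)
    labels = rng.integers(0, 4, 200)
    m = counts_from_arrays(raw, [f"c{i}" for i in range(200)], ["A", "B", "C"])
    cx = axis.coexpression_summary(m, _coex_labeling(200, labels), "A", "B")
    a, b = raw[:, 0] >= 1, raw[:, 1] >= 1
    for ed in range(4):
        mask = labels == ed
        n = mask.sum()
        row = cx.table.loc[ed]
        assert row["n_cells"] == n
        assert row["pct_only_a"] == pytest.approx(100 * (a & ~b & mask).sum() / n)
        assert row["pct_only_b"] == pytest.approx(100 * (b & ~a & mask).sum() / n)
        assert row["pct_both"] == pytest.approx(100 * (a & b & mask).sum() / n)
        total = row[["pct_only_a", "pct_only_b", "pct_both", "pct_neither"]].sum()
        assert total == pytest.approx(100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# group means and gene filter


def _groups(assign):
    rows = []
    for gid, (tissue, pos, members) in assign.items():
        for c in members:
            rows.append({"group_id": gid, "tissue_class": tissue, "position": pos, "cell_id": c})
    return pd.DataFrame(rows)


def test_group_means_identity_and_oracle():
    rng = np.random.default_rng(1)
    Z = rng.normal(2, 1, (30, 4))
    m = _matrix_with_layer(Z)
    groups = _groups({"AM-01": ("AM", 1, ["c0"]), "AM-02": ("AM", 2, [f"c{i}" for i in range(1, 30)])})
    gm = axis.group_means(m, groups)
    np.testing.assert_allclose(gm.loc["AM-01"].to_numpy(), Z[0])
    np.testing.assert_allclose(gm.loc["AM-02"].to_numpy(), Z[1:].mean(axis=0))
    two_same = _groups({"AM-01": ("AM", 1, ["c0", "c0"])})  # duplicated member
    with pytest.raises(FormatError, match="no cells|one group"):
        # duplicated membership is rejected upstream by the reader; here an
        # empty group triggers the group_means error path
        axis.group_means(m, _groups({"AM-09": ("AM", 9, ["nope"])}))


def test_filter_group_genes_strict_threshold():
    gm = pd.DataFrame(
        {"at_threshold": [0.30, 0.10], "above": [0.31, 0.0], "low": [0.1, 0.2]},
        index=["g1", "g2"],
    )
    kept = axis.filter_group_genes(gm, min_mean=0.30)
    assert list(kept.columns) == ["above"]
    rng = np.random.default_rng(2)
    M = pd.DataFrame(rng.uniform(0, 1, (5, 20)))
    kept = axis.filter_group_genes(M, 0.30)
    assert list(kept.columns) == [c for c in M.columns if M[c].max() > 0.30]
    with pytest.raises(FormatError):
        axis.filter_group_genes(gm * 0.0, 0.30)


# ---------------------------------------------------------------------------
# axis PCA


def test_axis_pca_single_linear_gene():
    pos = pd.Series(range(1, 14), index=[f"AM-{i:02d}" for i in range(1, 14)])
    gm = pd.DataFrame(
        {"lin": np.arange(13.0), "flat": np.ones(13)}, index=pos.index
    )
    res = axis.axis_pca(gm, pos)
    assert res.spearman_rho == pytest.approx(1.0)
    assert abs(res.loadings.loc["lin", "PC1"]) == pytest.approx(1.0)
    assert res.loadings.loc["flat", "PC1"] == pytest.approx(0.0, abs=1e-12)


def test_spearman_t_approximation_reproduces_printed_pair():
    """rho = 0.68 over 13 ordered groups gives a two-sided p of about 0.01."""
    p = axis.spearman_t_pvalue(0.68, 13)
    t = 0.68 * np.sqrt(11 / (1 - 0.68**2))
    assert p == pytest.approx(2 * stats.t.sf(t, 11))
    assert p == pytest.approx(0.01, abs=0.005)


def test_axis_pca_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    pos = pd.Series(range(1, 14), index=[f"G{i}" for i in range(13)])
    gm = pd.DataFrame(rng.normal(0, 1, (13, 20)), index=pos.index)
    res = axis.axis_pca(gm, pos, n_components=12)
    # loadings: unit norm, orthogonal
    L = res.loadings.to_numpy()
    np.testing.assert_allclose(np.linalg.norm(L, axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
    # eigendecomposition of the covariance gives the same spectrum
    Z = res.standardized.to_numpy()
    Zc = Z - Z.mean(axis=0)
    evals = np.sort(np.linalg.eigvalsh(Zc.T @ Zc))[::-1]
    scores_var = (res.scores.to_numpy() ** 2).sum(axis=0)
    np.testing.assert_allclose(np.sort(scores_var)[::-1], evals[:12], atol=1e-8)
    # full reconstruction
    recon = res.scores.to_numpy() @ res.loadings_aligned.to_numpy().T
    np.testing.assert_allclose(recon, Zc, atol=1e-6)


def test_axis_pca_orientation_and_constant_gene():
    pos = pd.Series(range(1, 14), index=[f"G{i}" for i in range(13)])
    gm = pd.DataFrame({"dec": -np.arange(13.0), "c": np.ones(13), "n": np.sin(np.arange(13))},
                      index=pos.index)
    res = axis.axis_pca(gm, pos)
    assert res.spearman_rho >= 0  # scores flipped towards the axis
    assert res.flipped[0]  # the decreasing gene forces an inversion
    np.testing.assert_allclose(res.standardized["c"].to_numpy(), 0.0)


def test_zscore_profiles():
    gm = pd.DataFrame({"g": [1.0, 2.0, 3.0], "c": [2.0, 2.0, 2.0]})
    z = axis.zscore_profiles(gm)
    np.testing.assert_allclose(z["g"].to_numpy(), [-1.0, 0.0, 1.0])
    np.testing.assert_allclose(z["c"].to_numpy(), 0.0)
    rng = np.random.default_rng(4)
    M = pd.DataFrame(rng.normal(3, 2, (10, 5)))
    z = axis.zscore_profiles(M)
    np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# ridge sizes


def test_ridge_size_closed_form():
    assign = {}
    for i, n in enumerate([20, 30, 40, 40], start=1):
        assign[f"LR-{i:02d}"] = ("LR", i, [f"b{i}_{j}" for j in range(n)])
    for i in (8, 9, 10, 11):
        assign[f"LR-{i:02d}"] = ("LR", i, [f"c{i}_{j}" for j in range(10)])
    stats_ = axis.ridge_size_stats(_groups(assign))
    assert stats_["basal"]["mean"] == pytest.approx(32.5)
    assert stats_["basal"]["sd"] == pytest.approx(9.574, abs=1e-3)
    assert stats_["central"]["sd"] == 0.0
    single = axis.ridge_size_stats(_groups(assign), basal_positions=(1,))
    assert np.isnan(single["basal"]["sd"])
    with pytest.raises(FormatError, match="missing"):
        axis.ridge_size_stats(_groups(assign), basal_positions=(1, 2, 3, 99))


# ---------------------------------------------------------------------------
# pseudobulk


def test_pseudobulk_identity_additivity_oracle():
    rng = np.random.default_rng(5)
    Z = rng.normal(2, 1, (20, 6))
    m = _matrix_with_layer(Z)
    one = axis.pseudobulk(m, ["c3"])
    np.testing.assert_allclose(one.to_numpy(), Z[3])
    s1 = axis.pseudobulk(m, [f"c{i}" for i in range(10)])
    s2 = axis.pseudobulk(m, [f"c{i}" for i in range(10, 20)])
    full = axis.pseudobulk(m, [f"c{i}" for i in range(20)])
    np.testing.assert_allclose((s1 + s2).to_numpy(), full.to_numpy(), rtol=1e-12)
    subset = [f"c{i}" for i in (1, 5, 9)]
    np.testing.assert_allclose(
        axis.pseudobulk(m, subset).to_numpy(), Z[[1, 5, 9]].sum(axis=0)
    )
    with pytest.raises(FormatError, match="empty"):
        axis.pseudobulk(m, [])


def test_pseudobulk_correlation_cases():
    v = pd.Series([1.0, 5.0, 3.0, 10.0], index=list("abcd"))
    assert axis.pseudobulk_correlation(v, v * 7) == pytest.approx(1.0)
    rev = pd.Series(v.rank().max() + 1 - v.rank().to_numpy(), index=v.index)
    assert axis.pseudobulk_correlation(v, rev) == pytest.approx(-1.0)
    rng = np.random.default_rng(6)
    w = pd.Series(rng.uniform(0, 100, 4), index=list("abcd"))
    rho = axis.pseudobulk_correlation(v, w)
    oracle = stats.pearsonr(v.rank(), w.rank()).statistic
    assert rho == pytest.approx(oracle)
    with pytest.raises(FormatError, match="intersection"):
        axis.pseudobulk_correlation(v, pd.Series({"a": 1.0, "b": 2.0}))
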