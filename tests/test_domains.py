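"""Normalization, integration, Leiden domain calling, prevalence, marker
ranking and the +2 SD enrichment rule."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from spikemap import domains
from spikemap.errors import FormatError
from spikemap.io import counts_from_arrays


def _matrix(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return counts_from_arrays(X, [f"c{i}" for i in range(X.shape[0])], genes)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_scale_factors_closed_form():
    m = _matrix([[60, 40], [120, 80]])  # totals 100, 200 -> target median 150
    out = domains.normalize_counts(m)
    np.testing.assert_allclose(
        out.layers["norm_counts"], [[90, 60], [90, 60]]
    )  # scale 1.5 and 0.75
    np.testing.assert_allclose(out.layers["lognorm"], np.log1p(out.layers["norm_counts"]))


def test_normalize_identity_scaling_is_pure_log1p():
    m = _matrix([[10, 20], [20, 10]])  # both cells already at the target total
    out = domains.normalize_counts(m)
    np.testing.assert_allclose(out.layers["lognorm"], np.log1p(np.asarray(m.X)))


def test_normalize_conserves_target_total(normalized_wt):
    m, _, _ = normalized_wt
    back = np.expm1(np.asarray(m.layers["lognorm"])).sum(axis=1)
    target = m.uns["normalization_target_sum"]
    np.testing.assert_allclose(back, target, rtol=1e-6)


def test_normalize_rejects_zero_total_and_blanks():
    with pytest.raises(FormatError, match="zero total"):
        domains.normalize_counts(_matrix([[0, 0], [1, 2]]))
    with pytest.raises(FormatError, match="blank"):
        domains.normalize_counts(_matrix([[1, 2], [3, 4]], ["A", "Blank-1"]))


# ---------------------------------------------------------------------------
# integration


def _norm_sample(X, sample_id, genes=None):
    m = domains.normalize_counts(_matrix(X, genes))
    m.obs["sample_id"] = sample_id
    m.obs_names = [f"{sample_id}-{i}" for i in range(m.n_obs)]
    return m


def test_single_sample_embedding_is_pca():
    rng = np.random.default_rng(1)
    m = _norm_sample(rng.poisson(5, (40, 8)) + 1, "s1")
    emb, _ = domains.integrate_and_embed([m], n_comps=3)
    ref = PCA(n_components=3, svd_solver="full").fit_transform(
        np.asarray(m.layers["lognorm"])
    )
    # PCA is defined up to per-component sign
    for j in range(3):
        assert min(
            np.abs(emb[:, j] - ref[:, j]).max(), np.abs(emb[:, j] + ref[:, j]).max()
        ) < 1e-8


def test_identical_twin_samples_coincide_after_integration():
    rng = np.random.default_rng(2)
    X = rng.poisson(5, (60, 10)) + 1
    m1, m2 = _norm_sample(X, "a"), _norm_sample(X, "b")
    emb, stacked = domains.integrate_and_embed([m1, m2], n_comps=5)
    twins = np.linalg.norm(emb[:60] - emb[60:], axis=1)
    all_pairs = np.linalg.norm(emb[None, :60, :] - emb[60:, None, :], axis=2).ravel()
    assert np.median(twins) <= np.quantile(all_pairs, 0.10)


def _mixing_entropy(emb, batches, k=10):
    from scipy.spatial import cKDTree

    tree = cKDTree(emb)
    _, idx = tree.query(emb, k=k + 1)
    ent = []
    for i in range(len(emb)):
        nb = batches[idx[i, 1:]]
        p = np.bincount(nb, minlength=2) / k
        p = p[p > 0]
        ent.append(-(p * np.log(p)).sum())
    return float(np.mean(ent))


def test_batch_offset_mixing_improves_after_integration():
    rng = np.random.default_rng(3)
    base = rng.poisson(6, (80, 12)).astype(float) + 1
    shifted = base + rng.integers(3, 9, size=(1, 12))  # per-gene batch offset
    m1, m2 = _norm_sample(base, "a"), _norm_sample(shifted, "b")
    emb, stacked = domains.integrate_and_embed([m1, m2], n_comps=5)
    batches = np.array([0] * 80 + [1] * 80)
    Z = np.asarray(stacked.layers["lognorm"])
    Zc = Z - Z.mean(0)
    pre = PCA(n_components=5, svd_solver="full").fit_transform(Zc)
    assert _mixing_entropy(emb, batches) > _mixing_entropy(pre, batches)


def test_differing_gene_panels_rejected():
    m1 = _norm_sample([[1, 2], [3, 4]], "a", ["g1", "g2"])
    m2 = _norm_sample([[1, 2], [3, 4]], "b", ["g1", "g3"])
    with pytest.raises(FormatError, match="g2|g3"):
        domains.integrate_and_embed([m1, m2])


# ---------------------------------------------------------------------------
# clustering


def _two_blobs(n=200, d=25, sep=30.0, seed=0):
    # high-dimensional isotropic blobs: kNN graphs of low-dimensional point
    # clouds carry spurious community structure that Leiden happily splits
    rng = np.random.default_rng(seed)
    emb = rng.normal(0, 1, (n, d))
    emb[n // 2 :, 0] += sep
    truth = np.array([0] * (n // 2) + [1] * (n // 2))
    return emb, truth


def test_two_blobs_recovered_exactly():
    emb, truth = _two_blobs()
    lab = domains.cluster_domains(emb, resolution=1.0, seed=4)
    assert lab.n_domains == 2
    assert adjusted_rand_score(truth, lab.labels.to_numpy()) == 1.0


def test_identical_rows_single_cluster():
    emb = np.zeros((60, 3))
    lab = domains.cluster_domains(emb, resolution=1.0, seed=0)
    assert lab.n_domains == 1


def test_cluster_permutation_invariance():
    emb, _ = _two_blobs(seed=5)
    ids = [f"c{i}" for i in range(len(emb))]
    lab1 = domains.cluster_domains(emb, seed=9, cell_ids=ids)
    perm = np.random.default_rng(0).permutation(len(emb))
    lab2 = domains.cluster_domains(emb[perm], seed=9, cell_ids=[ids[i] for i in perm])
    # same partition of the same cells, up to label names
    df = pd.DataFrame({"a": lab1.labels, "b": lab2.labels.loc[lab1.labels.index]})
    assert df.groupby("a")["b"].nunique().max() == 1
    assert df.groupby("b")["a"].nunique().max() == 1


def test_cluster_too_few_cells_rejected():
    with pytest.raises(FormatError, match="cells"):
        domains.cluster_domains(np.zeros((10, 3)), n_neighbors=15)


# ---------------------------------------------------------------------------
# prevalence


def _labeling(labels, ids=None):
    ids = ids or [f"c{i}" for i in range(len(labels))]
    return domains.DomainLabeling(labels=pd.Series(labels, index=ids, dtype=int))


def test_prevalence_rule_application():
    n = 1000
    labels = [0] * 996 + [1] * 4  # ED 1 at 0.4% of the sample
    cells = pd.DataFrame(
        {"sample_id": "s1"}, index=pd.Index([f"c{i}" for i in range(n)], name="cell_id")
    )
    prev = domains.domain_prevalence(_labeling(labels), cells)
    counted = domains.count_domains_per_sample(prev)
    assert counted["s1"] == 1  # ED 1 excluded
    assert not prev.loc[prev["ed"] == 1, "counted"].iloc[0]


def test_prevalence_inclusive_at_exact_threshold():
    labels = [0] * 995 + [1] * 5  # exactly 0.5%
    cells = pd.DataFrame(
        {"sample_id": "s1"},
        index=pd.Index([f"c{i}" for i in range(1000)], name="cell_id"),
    )
    prev = domains.domain_prevalence(_labeling(labels), cells)
    assert domains.count_domains_per_sample(prev)["s1"] == 2


def test_prevalence_single_domain_and_monotone():
    cells = pd.DataFrame(
        {"sample_id": "s1"}, index=pd.Index([f"c{i}" for i in range(50)], name="cell_id")
    )
    prev = domains.domain_prevalence(_labeling([0] * 50), cells)
    assert domains.count_domains_per_sample(prev)["s1"] == 1
    labels = [0] * 70 + [1] * 20 + [2] * 10
    cells = pd.DataFrame(
        {"sample_id": "s1"},
        index=pd.Index([f"c{i}" for i in range(100)], name="cell_id"),
    )
    lab = _labeling(labels)
    counts = [
        domains.count_domains_per_sample(domains.domain_prevalence(lab, cells, thr))
        .reindex(["s1"], fill_value=0)
        .iloc[0]
        for thr in (0.05, 0.15, 0.25, 0.75)
    ]
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# marker ranking and enrichment


def _labelled_matrix(seed=0):
    rng = np.random.default_rng(seed)
    X = rng.poisson(3, (90, 6)).astype(float) + 1
    X[:30, 0] += 25  # gene g0 exclusive to ED 0
    m = domains.normalize_counts(_matrix(X))
    labels = _labeling([0] * 30 + [1] * 30 + [2] * 30, list(m.obs_names))
    return m, labels


def test_exclusive_gene_ranks_first():
    m, labels = _labelled_matrix()
    table = domains.rank_domain_markers(m, labels)
    assert table.ranked[0][0] == "g0"
    assert table.scores.loc[0, "g0"] == table.scores.loc[0].max()


def test_constant_gene_scores_near_zero():
    rng = np.random.default_rng(1)
    Z = rng.normal(2, 0.5, (60, 4))
    Z[:, 3] = 5.0  # constant gene in the normalized layer
    Z[:30, 0] += 3
    m = _matrix(np.round(np.abs(Z) * 10))
    m.layers["lognorm"] = Z
    labels = _labeling([0] * 30 + [1] * 30, list(m.obs_names))
    table = domains.rank_domain_markers(m, labels)
    for ed in (0, 1):
        assert abs(table.scores.loc[ed, "g3"]) < 0.2
        assert table.ranked[ed][0] != "g3"


def test_ranking_invariant_under_label_permutation():
    m, labels = _labelled_matrix()
    t1 = domains.rank_domain_markers(m, labels)
    remap = {0: 2, 1: 0, 2: 1}
    permuted = domains.DomainLabeling(labels=labels.labels.map(remap))
    t2 = domains.rank_domain_markers(m, permuted)
    for ed in (0, 1, 2):
        assert t1.ranked[ed] == t2.ranked[remap[ed]]


def test_small_domain_excluded_with_warning():
    m, _ = _labelled_matrix()
    labels = _labeling([0] * 89 + [1], list(m.obs_names))
    with pytest.warns(UserWarning, match="fewer than 2"):
        table = domains.rank_domain_markers(m, labels)
    assert list(table.scores.index) == [0]


def test_call_enriched_closed_form():
    """Nine scores at 0 and one at 5: mean 0.5, sample SD 1.581, threshold
    3.66 -> exactly one enriched gene."""
    scores = pd.DataFrame([[0.0] * 9 + [5.0]], index=pd.Index([0], name="ed"),
                          columns=[f"g{i}" for i in range(10)])
    table = domains.EnrichmentTable(scores=scores, mean_expr=scores, ranked={})
    enriched, summary = domains.call_enriched(table, k_sd=2)
    assert enriched.loc[0].sum() == 1 and enriched.loc[0, "g9"]
    assert summary["n_enriched_anywhere"] == 1


def test_call_enriched_degenerate_and_limit():
    flat = pd.DataFrame([[1.0] * 5], index=pd.Index([0], name="ed"),
                        columns=[f"g{i}" for i in range(5)])
    table = domains.EnrichmentTable(scores=flat, mean_expr=flat, ranked={})
    enriched, _ = domains.call_enriched(table, k_sd=2)
    assert not enriched.to_numpy().any()  # zero variance -> no calls
    scores = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=pd.Index([0], name="ed"),
                          columns=list("abcd"))
    table = domains.EnrichmentTable(scores=scores, mean_expr=scores, ranked={})
    enriched, _ = domains.call_enriched(table, k_sd=0)
    assert list(enriched.loc[0]) == [False, False, True, True]  # above the mean
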