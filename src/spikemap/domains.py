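"""Expression-domain calling: per-sample normalization, multi-sample
integration, Leiden clustering on a kNN graph, domain prevalence accounting,
one-vs-rest logistic-regression marker ranking and the +2 SD enrichment call.

Expression domains (EDs) are clusters of cells sharing a transcriptional
signature; mapped back onto tissue space they delineate tissues of the
developing spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.linear_model import LogisticRegression

from .errors import FormatError

LOGNORM_LAYER = "lognorm"
NORM_LAYER = "norm_counts"


@dataclass
class DomainLabeling:
    """Per-cell expression-domain ids (contiguous ints from 0, ordered by
    descending cluster size) plus an optional ED → tissue annotation map."""

    labels: pd.Series  # index cell_id, int ED id
    annotation: dict[int, str] = field(default_factory=dict)

    @property
    def n_domains(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class EnrichmentTable:
    """Per-(ED, gene) logistic-regression scores, per-ED rankings, mean
    normalized expression, and the enriched-call flags."""

    scores: pd.DataFrame  # EDs × genes, fitted coefficients
    mean_expr: pd.DataFrame  # EDs × genes, mean normalized expression
    ranked: dict[int, list[str]]  # ED → genes by descending score
    enriched: pd.DataFrame | None = None  # EDs × genes bool, after call_enriched


def normalize_counts(matrix: ad.AnnData, target_sum: float | None = None) -> ad.AnnData:
    """Total-count normalize each cell then log1p, into ``layers["lognorm"]``.

    Each cell is scaled so its total equals the common target (the median of
    per-cell totals when ``target_sum`` is None), after which the matrix is
    logarithmized.  Called per sample, before integration.  Blank barcodes
    must already be removed; zero-total cells are an error (they should have
    been filtered).
    """
    if "is_blank" in matrix.var and matrix.var["is_blank"].any():
        raise FormatError("normalize_counts: remove blank genes before normalizing")
    X = np.asarray(matrix.X, dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = matrix.obs_names[np.flatnonzero(totals == 0)[0]]
        raise FormatError(f"normalize_counts: cell '{bad}' has zero total counts")
    target = float(np.median(totals)) if target_sum is None else float(target_sum)
    out = matrix.copy()
    scaled = X * (target / totals)[:, None]
    out.layers[NORM_LAYER] = scaled  # linear normalized counts
    out.layers[LOGNORM_LAYER] = np.log1p(scaled)
    out.uns["normalization_target_sum"] = target
    return out


def integrate_and_embed(
    samples: list[ad.AnnData], n_comps: int = 30, batch_key: str = "sample_id"
):
    """Batch-correct normalized samples and embed them jointly.

    Samples are stacked, batch effects removed with ComBat on the lognorm
    layer, and the corrected matrix embedded by PCA.  A single sample passes
    straight to PCA.  Returns ``(embedding, stacked)`` where ``embedding`` is
    cells × d and ``stacked`` the concatenated AnnData (corrected values in
    ``layers["integrated"]``).
    """
    if not samples:
        raise FormatError("integrate_and_embed: no samples")
    panels = [tuple(s.var_names) for s in samples]
    if len(set(panels)) > 1:
        sym = set(panels[0]).symmetric_difference(*(set(p) for p in panels[1:]))
        raise FormatError(f"gene panels differ across samples: {sorted(sym)}")
    for s in samples:
        if LOGNORM_LAYER not in s.layers:
            raise FormatError("samples must be normalized (missing lognorm layer)")

    stacked = ad.concat(samples, join="inner", merge="same", index_unique=None)
    stacked.var = samples[0].var.copy()
    Z = np.asarray(stacked.layers[LOGNORM_LAYER], dtype=float)
    if len(samples) > 1 and stacked.obs[batch_key].nunique() > 1:
        tmp = ad.AnnData(X=Z.copy(), obs=stacked.obs[[batch_key]].copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(tmp, key=batch_key)
        corrected = np.asarray(tmp.X, dtype=float)
    else:
        corrected = Z
    stacked.layers["integrated"] = corrected

    n_comps = int(min(n_comps, corrected.shape[1] - 1, corrected.shape[0] - 1))
    centered = corrected - corrected.mean(axis=0, keepdims=True)
    # PCA via SVD; deterministic sign convention (largest |loading| positive)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    embedding = (U * S)[:, :n_comps] * signs[:n_comps]
    stacked.obsm["X_emb"] = embedding
    return embedding, stacked


def cluster_domains(
    embedding: np.ndarray | ad.AnnData,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    cell_ids=None,
) -> DomainLabeling:
    """Leiden community detection on a kNN graph of the embedding.

    Deterministic given the seed; ED ids are relabelled by descending cluster
    size starting at 0.
    """
    if isinstance(embedding, ad.AnnData):
        cell_ids = embedding.obs_names
        embedding = embedding.obsm["X_emb"]
    embedding = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(embedding)):
        raise FormatError("cluster_domains: embedding has non-finite values")
    if embedding.shape[0] <= n_neighbors:
        raise FormatError(
            f"cluster_domains: need more than {n_neighbors} cells, got {embedding.shape[0]}"
        )
    if cell_ids is None:
        cell_ids = pd.RangeIndex(embedding.shape[0]).astype(str)

    tmp = ad.AnnData(
        X=np.zeros((embedding.shape[0], 1)),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
    )
    tmp.obsm["X_emb"] = embedding
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(tmp, n_neighbors=n_neighbors, use_rep="X_emb", random_state=seed)
        sc.tl.leiden(
            tmp,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    raw = tmp.obs["leiden"].astype(int)
    order = raw.value_counts().sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order)}
    labels = raw.map(remap).astype(int)
    labels.index = pd.Index(cell_ids, name="cell_id")
    return DomainLabeling(labels=labels)


def domain_prevalence(
    labeling: DomainLabeling, cells: pd.DataFrame, threshold: float = 0.005
) -> pd.DataFrame:
    """Per-sample domain accounting under the prevalence rule.

    For each sample, an ED counts towards that sample's domain number when
    its share of the sample's cells is >= ``threshold`` (default 0.5%); the
    global labeling itself is left untouched.  Returns a tidy frame with one
    row per (sample, ED) giving cell counts, shares and the keep flag.
    """
    common = labeling.labels.index.intersection(cells.index)
    df = pd.DataFrame(
        {
            "ed": labeling.labels.loc[common],
            "sample_id": cells.loc[common, "sample_id"],
        }
    )
    out = (
        df.groupby(["sample_id", "ed"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = out.groupby("sample_id")["n_cells"].transform("sum")
    out["share"] = out["n_cells"] / totals
    out["counted"] = out["share"] >= threshold
    return out


def count_domains_per_sample(prevalence: pd.DataFrame) -> pd.Series:
    """Number of EDs per sample after the prevalence rule."""
    return prevalence[prevalence["counted"]].groupby("sample_id")["ed"].nunique()


def rank_domain_markers(
    stacked: ad.AnnData,
    labeling: DomainLabeling,
    layer: str = LOGNORM_LAYER,
    C: float = 1.0,
    max_iter: int = 200,
) -> EnrichmentTable:
    """Rank marker genes per ED by one-vs-rest logistic regression.

    The score of a gene for an ED is its fitted coefficient in an
    L2-regularized (C=1) logistic regression separating the ED's cells from
    all others on the normalized matrix; ranked lists break ties by gene
    name.  EDs with fewer than 2 cells are excluded with a warning.
    """
    Z = np.asarray(stacked.layers[layer], dtype=float)
    labels = labeling.labels.loc[stacked.obs_names]
    eds = sorted(labels.unique())
    if len(eds) < 2:
        raise FormatError("rank_domain_markers: need at least 2 EDs")
    genes = list(stacked.var_names)
    rows = {}
    for ed in eds:
        y = (labels == ed).to_numpy()
        if y.sum() < 2:
            warnings.warn(f"ED {ed} has fewer than 2 cells; excluded from ranking")
            continue
        clf = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")  # L2 penalty
        clf.fit(Z, y)
        rows[ed] = clf.coef_[0]
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    scores.index.name = "ed"
    mean_expr = pd.DataFrame(
        {ed: Z[(labels == ed).to_numpy()].mean(axis=0) for ed in scores.index},
        index=genes,
    ).T
    ranked = {
        int(ed): (
            scores.loc[ed]
            .sort_index()  # tie-break: gene name
            .sort_values(ascending=False, kind="stable")
            .index.tolist()
        )
        for ed in scores.index
    }
    return EnrichmentTable(scores=scores, mean_expr=mean_expr, ranked=ranked)


def call_enriched(table: EnrichmentTable, k_sd: float = 2.0):
    """Flag genes enriched per ED with the +k SD rule.

    Within each ED, a gene is enriched when its score exceeds the mean plus
    ``k_sd`` sample standard deviations of that ED's score distribution over
    genes.  EDs with zero score variance yield no calls.  Returns the flag
    frame and a summary (genes enriched anywhere / in exactly one ED / in
    more than 3 EDs, and the multi-ED fraction).
    """
    scores = table.scores
    mu = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1)
    thresh = mu + k_sd * sd
    enriched = scores.gt(thresh, axis=0)
    enriched.loc[sd == 0] = False
    table.enriched = enriched
    per_gene = enriched.sum(axis=0)
    anywhere = int((per_gene > 0).sum())
    summary = {
        "n_enriched_anywhere": anywhere,
        "n_enriched_single_ed": int((per_gene == 1).sum()),
        "n_enriched_gt3_eds": int((per_gene > 3).sum()),
        "frac_multi_ed": float((per_gene > 1).sum() / anywhere) if anywhere else 0.0,
    }
    return enriched, summary


def call_enriched_per_gene(table: EnrichmentTable, k_sd: float = 2.0):
    """Alternative axis for the +k SD rule: per gene across ED means.

    A (gene, ED) pair is enriched when the ED's mean normalized expression of
    the gene exceeds the gene's mean plus ``k_sd`` sample SDs across EDs.
    """
    m = table.mean_expr
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    enriched = m.gt(mu + k_sd * sd, axis=1)
    enriched.loc[:, sd == 0] = False
    return enriched
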