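"""Statistics along the apical-basal axis of the spike.

Covers the transect analysis (30 equal-width y bins, bin 1 basal), the
pooled basal:central expression ratio, binarized co-expression per expression
domain, AM/LR group means with the 0.30 expression filter, standardized PCA
of group profiles with position correlation, Z-score profiles, ridge-size
summaries and in-silico pseudobulk dissection against a bulk reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .domains import LOGNORM_LAYER, NORM_LAYER, DomainLabeling
from .errors import FormatError


def _layer(matrix: ad.AnnData, layer: str | None) -> np.ndarray:
    if layer is None:
        return np.asarray(matrix.X, dtype=float)
    if layer not in matrix.layers:
        raise FormatError(f"matrix has no '{layer}' layer")
    return np.asarray(matrix.layers[layer], dtype=float)


# ---------------------------------------------------------------------------
# transect binning


@dataclass
class BinProfile:
    """Per-cell transect bin indices (1 = basal) and per-bin gene means."""

    n_bins: int
    bin_of_cell: pd.Series  # index cell_id, int 1..n_bins
    bin_means: pd.DataFrame  # bins × genes mean normalized counts (NaN if empty)
    bin_counts: pd.Series  # cells per bin
    edges: np.ndarray


def transect_bin(
    cells: pd.DataFrame,
    matrix: ad.AnnData,
    n_bins: int = 30,
    layer: str | None = LOGNORM_LAYER,
    flip_axis: bool = False,
) -> BinProfile:
    """Assign ROI cells to equal-width y bins and average expression per bin.

    Bin 1 sits at the basal end (minimal y, or maximal y when ``flip_axis``).
    Cells are assigned by the y coordinate of their centre; empty bins are
    reported with count 0 and NaN means.
    """
    if n_bins < 2:
        raise FormatError("transect_bin: n_bins must be >= 2")
    cells = cells.loc[matrix.obs_names]
    y = cells["center_y"].to_numpy(float)
    if flip_axis:
        y = -y
    edges = np.linspace(y.min(), y.max(), n_bins + 1)
    # right-inclusive top edge so the apical-most cell lands in bin n_bins
    idx = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, n_bins - 1) + 1
    Z = _layer(matrix, layer)
    bins = pd.Series(idx, index=cells.index, name="bin")
    means = np.full((n_bins, Z.shape[1]), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(1, n_bins + 1):
        mask = idx == b
        counts[b - 1] = mask.sum()
        if mask.any():
            means[b - 1] = Z[mask].mean(axis=0)
    return BinProfile(
        n_bins=n_bins,
        bin_of_cell=bins,
        bin_means=pd.DataFrame(means, index=range(1, n_bins + 1), columns=matrix.var_names),
        bin_counts=pd.Series(counts, index=range(1, n_bins + 1)),
        edges=edges,
    )


def basal_central_ratio(
    matrix: ad.AnnData,
    cells: pd.DataFrame,
    gene: str,
    basal_bins: range = range(1, 11),
    other_bins: range = range(11, 31),
    n_bins: int = 30,
    layer: str | None = NORM_LAYER,
    flip_axis: bool = False,
) -> float:
    """Pooled per-cell mean of ``gene`` over the basal bins divided by the
    same over the remaining bins (cells pooled, not a mean of bin means).

    With the defaults this is the bins 1-10 vs bins 11-30 ratio of the
    transect analysis, computed on linear total-normalized counts ("mean
    counts per cell"); pass ``layer=None`` for raw counts or
    ``layer="lognorm"`` for the log scale.  A zero denominator returns
    ``inf``.
    """
    if gene not in matrix.var_names:
        raise FormatError(f"gene '{gene}' not in panel")
    profile = transect_bin(cells, matrix, n_bins=n_bins, layer=layer, flip_axis=flip_axis)
    Z = _layer(matrix, layer)[:, matrix.var_names.get_loc(gene)]
    b = profile.bin_of_cell.to_numpy()
    basal = np.isin(b, list(basal_bins))
    other = np.isin(b, list(other_bins))
    if not basal.any() or not other.any():
        raise FormatError("basal_central_ratio: empty bin range")
    num = Z[basal].mean()
    den = Z[other].mean()
    if den == 0:
        return float("inf")
    return float(num / den)


# ---------------------------------------------------------------------------
# binarized co-expression


@dataclass
class CoexpressionSummary:
    """Percentages of cells detecting only gene A, only gene B, or both,
    per expression domain and over the whole spike."""

    gene_a: str
    gene_b: str
    table: pd.DataFrame  # rows: ED ids + "all"; columns n_cells, pct_only_a, ...


def coexpression_summary(
    matrix: ad.AnnData,
    labeling: DomainLabeling,
    gene_a: str,
    gene_b: str,
) -> CoexpressionSummary:
    """Binarize detection (raw count >= 1) of two genes and tabulate
    only-A / only-B / both percentages per ED and overall.

    Binarization is on raw detections, not normalized values; denominators
    are all cells of each ED.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.var_names:
            raise FormatError(f"gene '{g}' not in panel")
    X = np.asarray(matrix.X, dtype=float)
    a = X[:, matrix.var_names.get_loc(gene_a)] >= 1
    b = X[:, matrix.var_names.get_loc(gene_b)] >= 1
    labels = labeling.labels.loc[matrix.obs_names].to_numpy()

    def summarize(mask: np.ndarray) -> dict:
        n = int(mask.sum())
        aa, bb = a[mask], b[mask]
        both = aa & bb
        return {
            "n_cells": n,
            "pct_only_a": 100.0 * (aa & ~bb).sum() / n if n else np.nan,
            "pct_only_b": 100.0 * (bb & ~aa).sum() / n if n else np.nan,
            "pct_both": 100.0 * both.sum() / n if n else np.nan,
            "pct_neither": 100.0 * (~aa & ~bb).sum() / n if n else np.nan,
        }

    rows = {int(ed): summarize(labels == ed) for ed in sorted(np.unique(labels))}
    rows["all"] = summarize(np.ones_like(a, dtype=bool))
    table = pd.DataFrame.from_dict(rows, orient="index")
    return CoexpressionSummary(gene_a=gene_a, gene_b=gene_b, table=table)


# ---------------------------------------------------------------------------
# AM/LR group analysis


def group_means(
    matrix: ad.AnnData, groups: pd.DataFrame, layer: str | None = LOGNORM_LAYER
) -> pd.DataFrame:
    """Group × gene matrix of mean normalized expression over member cells.

    ``groups`` is the annotation table (group_id, tissue_class, position,
    cell_id); groups with no member present in the matrix are an error.
    """
    if groups.empty:
        raise FormatError("group_means: empty group annotation")
    Z = _layer(matrix, layer)
    idx = pd.Index(matrix.obs_names)
    out = {}
    for gid, sub in groups.groupby("group_id", sort=True):
        pos = idx.get_indexer(sub["cell_id"].astype(str))
        pos = pos[pos >= 0]
        if pos.size == 0:
            raise FormatError(f"group_means: group '{gid}' has no cells in the matrix")
        out[gid] = Z[pos].mean(axis=0)
    return pd.DataFrame.from_dict(out, orient="index", columns=matrix.var_names)


def filter_group_genes(matrix: pd.DataFrame, min_mean: float = 0.30) -> pd.DataFrame:
    """Keep genes with at least one group mean strictly above ``min_mean``."""
    keep = matrix.max(axis=0) > min_mean
    if not keep.any():
        raise FormatError("filter_group_genes: no gene passes the expression filter")
    return matrix.loc[:, keep]


@dataclass
class AxisPcaResult:
    matrix: pd.DataFrame  # groups × genes (input averages)
    standardized: pd.DataFrame
    scores: pd.DataFrame  # groups × PCs, sign-aligned to position
    loadings: pd.DataFrame  # genes × PCs, raw orientation (headline)
    loadings_aligned: pd.DataFrame  # genes × PCs, matching the aligned scores
    explained_variance_ratio: np.ndarray
    positions: pd.Series
    spearman_rho: float
    spearman_p: float
    flipped: np.ndarray  # which PCs were sign-inverted for alignment


def spearman_t_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman correlation via the t approximation with
    n-2 degrees of freedom."""
    if n < 3:
        raise FormatError("spearman_t_pvalue: need n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def axis_pca(
    matrix: pd.DataFrame, positions: pd.Series | dict, n_components: int = 2
) -> AxisPcaResult:
    """Standardized PCA of a group × gene matrix, oriented along the axis.

    Genes are z-standardized across groups (sample SD; constant genes become
    zero columns).  PC scores are sign-oriented so that the Spearman
    correlation of PC1 with position is non-negative, mirroring the score
    inversion used to align the axes with the biological orientation;
    loadings are reported both in the raw orientation (headline, matching
    pre-inversion signs) and the score-aligned one.  The Spearman p-value
    uses the t approximation with n-2 df.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise FormatError("axis_pca: need >= 3 groups and >= 2 genes")
    positions = pd.Series(positions).loc[matrix.index].astype(float)
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    Zcols = {}
    for g in matrix.columns:
        if sd[g] == 0:
            Zcols[g] = np.zeros(len(matrix))
        else:
            Zcols[g] = (matrix[g] - mu[g]).to_numpy() / sd[g]
    Z = pd.DataFrame(Zcols, index=matrix.index)

    n_components = int(min(n_components, min(Z.shape) - 0, Z.shape[0] - 1, Z.shape[1]))
    A = Z.to_numpy() - Z.to_numpy().mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    # deterministic raw orientation: largest-|loading| gene positive per PC
    base_sign = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    base_sign[base_sign == 0] = 1.0
    U, Vt = U * base_sign, Vt * base_sign[:, None]
    scores_raw = U * S
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var

    pcs = [f"PC{i + 1}" for i in range(n_components)]
    scores_raw = scores_raw[:, :n_components]
    load_raw = Vt[:n_components].T

    flips = np.ones(n_components)
    for j in range(min(2, n_components)):
        col = scores_raw[:, j]
        if np.ptp(col) == 0:  # degenerate component: orientation undefined
            continue
        rho_j = stats.spearmanr(col, positions.to_numpy()).statistic
        if np.isfinite(rho_j) and rho_j < 0:
            flips[j] = -1.0
    scores = scores_raw * flips
    rho = float(stats.spearmanr(scores[:, 0], positions.to_numpy()).statistic)
    pval = spearman_t_pvalue(rho, len(positions))

    return AxisPcaResult(
        matrix=matrix,
        standardized=Z,
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(load_raw, index=matrix.columns, columns=pcs),
        loadings_aligned=pd.DataFrame(load_raw * flips, index=matrix.columns, columns=pcs),
        explained_variance_ratio=evr[:n_components],
        positions=positions,
        spearman_rho=rho,
        spearman_p=pval,
        flipped=flips < 0,
    )


def zscore_profiles(matrix: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Per-gene Z-scores across groups (sample SD); constant genes → zeros."""
    if genes is not None:
        missing = [g for g in genes if g not in matrix.columns]
        if missing:
            raise FormatError(f"zscore_profiles: genes not present: {missing}")
        matrix = matrix[list(genes)]
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    z = (matrix - mu) / sd.replace(0, np.nan)
    return z.fillna(0.0)


def ridge_size_stats(
    groups: pd.DataFrame,
    basal_positions=(1, 2, 3, 4),
    central_positions=(8, 9, 10, 11),
    tissue_class: str = "LR",
) -> dict:
    """Mean ± sample SD of cells per group for basal vs central position sets.

    A single-group set has an undefined SD, reported as NaN.
    """
    sub = groups[groups["tissue_class"] == tissue_class]
    sizes = sub.groupby("position")["cell_id"].count()

    def stat(positions):
        missing = [p for p in positions if p not in sizes.index]
        if missing:
            raise FormatError(f"ridge_size_stats: missing positions {missing}")
        vals = sizes.loc[list(positions)].to_numpy(float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
        return {"mean": float(vals.mean()), "sd": sd, "n_groups": len(vals)}

    return {"basal": stat(basal_positions), "central": stat(central_positions)}


# ---------------------------------------------------------------------------
# in-silico pseudobulk dissection


def pseudobulk(
    matrix: ad.AnnData, cell_subset, layer: str | None = LOGNORM_LAYER
) -> pd.Series:
    """Sum normalized expression per gene over the given cell subset."""
    cell_subset = [str(c) for c in cell_subset]
    if not cell_subset:
        raise FormatError("pseudobulk: empty cell subset")
    idx = pd.Index(matrix.obs_names).get_indexer(cell_subset)
    if (idx < 0).any():
        bad = cell_subset[int(np.flatnonzero(idx < 0)[0])]
        raise FormatError(f"pseudobulk: unknown cell '{bad}'")
    Z = _layer(matrix, layer)
    return pd.Series(Z[idx].sum(axis=0), index=matrix.var_names, name="pseudobulk")


def pseudobulk_correlation(vector: pd.Series, reference: pd.Series) -> float:
    """Spearman correlation between a pseudobulk vector and a bulk TPM
    reference over their gene intersection (>= 3 genes; average-rank ties)."""
    shared = vector.index.intersection(reference.index)
    if len(shared) < 3:
        raise FormatError("pseudobulk_correlation: gene intersection < 3")
    rho = stats.spearmanr(vector.loc[shared], reference.loc[shared]).statistic
    return float(rho)
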