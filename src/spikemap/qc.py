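"""Per-cell quality control: metrics, count/volume filtering and error-rate
statistics (blank-barcode false-detection rate, homoeolog cross-hybridization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .errors import FormatError


@dataclass(frozen=True)
class QcThresholds:
    """Boundary-inclusive keep thresholds: cells with non-blank total counts
    >= ``min_counts`` and volume >= ``min_volume`` (µm³) are retained."""

    min_counts: float = 25.0
    min_volume: float = 500.0

    def __post_init__(self):
        if self.min_counts <= 0 or self.min_volume <= 0:
            raise FormatError("QC thresholds must be > 0")


@dataclass
class QcSummary:
    per_cell: pd.DataFrame  # total_counts, n_genes, blank_fraction
    mean_blank_pct: float
    notes: dict = field(default_factory=dict)


def _split_blank(matrix: ad.AnnData):
    if "is_blank" not in matrix.var:
        raise FormatError("count matrix has no blank-barcode flags")
    blank = matrix.var["is_blank"].to_numpy(bool)
    X = np.asarray(matrix.X, dtype=float)
    return X[:, ~blank], X[:, blank]


def qc_metrics(matrix: ad.AnnData) -> QcSummary:
    """Per-cell totals, genes detected (non-blank genes only) and the blank
    fraction of all detections (blanks included in the denominator)."""
    genes, blanks = _split_blank(matrix)
    totals = genes.sum(axis=1)
    n_genes = (genes > 0).sum(axis=1)
    all_counts = totals + blanks.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        blank_frac = np.where(all_counts > 0, blanks.sum(axis=1) / all_counts, np.nan)
    per_cell = pd.DataFrame(
        {
            "total_counts": totals,
            "n_genes": n_genes,
            "blank_fraction": blank_frac,
        },
        index=matrix.obs_names,
    )
    nonzero = per_cell["blank_fraction"].dropna()
    mean_pct = float(nonzero.mean() * 100.0) if len(nonzero) else float("nan")
    return QcSummary(per_cell=per_cell, mean_blank_pct=mean_pct)


def filter_cells(
    matrix: ad.AnnData, cells: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
):
    """Apply the count and volume filters, preserving cell order.

    Keeps cells whose non-blank total is >= ``min_counts`` AND whose segmented
    volume is >= ``min_volume`` (removing low-quality cells and small
    non-cellular segmentation artifacts).  Returns the filtered matrix and
    table plus a log of removal counts by reason.
    """
    if set(matrix.obs_names) != set(cells.index):
        raise FormatError("cell ids of matrix and metadata table differ")
    cells = cells.loc[matrix.obs_names]
    genes, _ = _split_blank(matrix)
    totals = genes.sum(axis=1)
    volumes = cells["volume"].to_numpy(float)
    low_counts = totals < thresholds.min_counts
    low_volume = volumes < thresholds.min_volume
    keep = ~(low_counts | low_volume)
    log = {
        "n_input": int(matrix.n_obs),
        "n_kept": int(keep.sum()),
        "removed_low_counts": int(low_counts.sum()),
        "removed_low_volume": int(low_volume.sum()),
        "removed_both": int((low_counts & low_volume).sum()),
    }
    return matrix[keep].copy(), cells.loc[keep], log


def blank_rate(matrix: ad.AnnData):
    """Mean per-cell blank percentage (and per-sample range when a
    ``sample_id`` obs column is present).

    Per-cell fraction = blank counts / all counts including blanks; cells
    with zero detections are excluded from the average.  Returned on the
    percent scale.
    """
    if "is_blank" not in matrix.var or not matrix.var["is_blank"].any():
        raise FormatError("no blank genes flagged in the matrix")
    summary = qc_metrics(matrix)
    frac = summary.per_cell["blank_fraction"].dropna()
    mean_pct = float(frac.mean() * 100.0)
    per_sample = {}
    if "sample_id" in matrix.obs:
        for sid, idx in matrix.obs.groupby("sample_id", observed=True).groups.items():
            vals = summary.per_cell.loc[idx, "blank_fraction"].dropna()
            if len(vals):
                per_sample[str(sid)] = float(vals.mean() * 100.0)
    return mean_pct, per_sample


def crosshyb_ratio(matrix: ad.AnnData, probe_gene: str):
    """Fold of a probe's mean counts/cell over the mean per-blank-gene
    counts/cell — the homoeolog cross-hybridization check.

    Returns ``(ratio, mean_probe_counts)``; an infinite ratio (no blank
    detections at all) is returned as ``float("inf")``.
    """
    if probe_gene not in matrix.var_names:
        raise FormatError(f"probe gene '{probe_gene}' not in panel")
    blank = matrix.var["is_blank"].to_numpy(bool)
    if not blank.any():
        raise FormatError("no blank genes flagged in the matrix")
    X = np.asarray(matrix.X, dtype=float)
    probe_mean = float(X[:, matrix.var_names.get_loc(probe_gene)].mean())
    blank_mean = float(X[:, blank].mean())  # mean over cells and blank genes
    if blank_mean == 0:
        return float("inf"), probe_mean
    return probe_mean / blank_mean, probe_mean


def strip_blanks(matrix: ad.AnnData) -> ad.AnnData:
    """Drop blank-barcode genes; done after QC, before all downstream work."""
    return matrix[:, ~matrix.var["is_blank"].to_numpy(bool)].copy()
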