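"""Readers and writers for the per-sample file set.

All interchange formats are plain text: delimited tables for cell metadata,
transcripts, groups and bulk references; dense CSV or matrix-market triplets
(with ``.rows`` / ``.cols`` name sidecars) for cell-by-gene counts; GeoJSON
FeatureCollections for cell boundary polygons and regions of interest.

Every ``read_*`` has a matching ``write_*`` and the pair round-trips exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from shapely.geometry import Polygon, mapping, shape

from .errors import FormatError

CELL_COLUMNS = ["center_x", "center_y", "volume", "sample_id", "stage", "genotype"]

STAGES = ("W2.5", "W3.25", "W4", "W5")
GENOTYPES = ("P1WT", "P1POL")


@dataclass
class RoiPolygon:
    """A labelled region-of-interest polygon in micron space."""

    label: str
    polygon: Polygon

    def __post_init__(self):
        _check_polygon(self.polygon, f"ROI '{self.label}'")


def _check_polygon(poly: Polygon, what: str) -> None:
    if len(poly.exterior.coords) < 4:  # closed ring: 3 vertices + repeat
        raise FormatError(f"{what}: polygon needs at least 3 vertices")
    if not poly.is_valid:
        raise FormatError(f"{what}: polygon is not simple (self-intersecting)")
    if poly.area <= 0:
        raise FormatError(f"{what}: polygon has non-positive area")


# ---------------------------------------------------------------------------
# cell metadata


def read_cell_metadata(
    path: str | Path,
    *,
    id_col: str = "cell_id",
    x_col: str = "center_x",
    y_col: str = "center_y",
    volume_col: str = "volume",
) -> pd.DataFrame:
    """Read a cell metadata table into a DataFrame indexed by ``cell_id``.

    Required columns are the id, centre x/y (microns) and volume (µm³);
    ``sample_id``, ``stage`` and ``genotype`` are carried through when
    present.  Duplicate ids, non-finite coordinates and non-positive volumes
    are rejected.
    """
    df = pd.read_csv(path)
    for col in (id_col, x_col, y_col, volume_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    for col in (x_col, y_col, volume_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric or non-finite value in column "
                f"'{col}' at row {int(bad[0]) + 2}"  # 1-based + header
            )
        df[col] = vals
    df = df.rename(
        columns={id_col: "cell_id", x_col: "center_x", y_col: "center_y", volume_col: "volume"}
    )
    df["cell_id"] = df["cell_id"].astype(str)
    dup = df["cell_id"][df["cell_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicated cell_id '{dup.iloc[0]}'")
    if (df["volume"] <= 0).any():
        bad_id = df.loc[df["volume"] <= 0, "cell_id"].iloc[0]
        raise FormatError(f"{path}: cell '{bad_id}' has volume <= 0")
    return df.set_index("cell_id")


def write_cell_metadata(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index_label="cell_id")


# ---------------------------------------------------------------------------
# count matrices


def _validate_counts(values: np.ndarray, where: str) -> np.ndarray:
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{where}: non-finite raw count")
    if (values < 0).any():
        raise FormatError(f"{where}: negative raw count")
    if not np.array_equal(values, np.round(values)):
        raise FormatError(f"{where}: fractional raw count")
    return values.astype(np.float64)


def _flag_blanks(adata: ad.AnnData, blank_prefix: str) -> ad.AnnData:
    adata.var["is_blank"] = adata.var_names.str.startswith(blank_prefix)
    return adata


def read_count_matrix(path: str | Path, blank_prefix: str = "Blank") -> ad.AnnData:
    """Read a cells × genes raw count matrix.

    ``*.csv``: dense, cells as rows (first column = cell id, header = genes).
    ``*.mtx``: matrix-market triplets with ``<path>.rows`` and ``<path>.cols``
    name sidecars (one id per line).  Genes whose name starts with
    ``blank_prefix`` are flagged in ``var["is_blank"]``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(rows), len(cols)):
            raise FormatError(f"{path}: matrix shape does not match sidecar lengths")
        X = _validate_counts(dense, str(path))
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=pd.Index(rows, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(cols, name="gene")),
        )
    else:
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        X = _validate_counts(df.to_numpy(dtype=float), str(path))
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=pd.Index(df.index, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(df.columns, name="gene")),
        )
    if adata.obs_names.duplicated().any():
        raise FormatError(f"{path}: duplicated cell ids")
    return _flag_blanks(adata, blank_prefix)


def write_count_matrix(adata: ad.AnnData, path: str | Path) -> None:
    """Write raw counts as dense CSV (``.csv``) or matrix-market (``.mtx``)."""
    path = Path(path)
    X = np.asarray(adata.X, dtype=float)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(X.astype(int)))
        Path(str(path) + ".rows").write_text("\n".join(adata.obs_names) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(adata.var_names) + "\n")
    else:
        pd.DataFrame(X.astype(int), index=adata.obs_names, columns=adata.var_names).to_csv(
            path, index_label="cell_id"
        )


def counts_from_arrays(
    X: np.ndarray,
    cell_ids,
    genes,
    blank_prefix: str = "Blank",
) -> ad.AnnData:
    """Assemble a validated AnnData count matrix from in-memory arrays."""
    X = _validate_counts(np.asarray(X, dtype=float), "count matrix")
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index([str(c) for c in cell_ids], name="cell_id")),
        var=pd.DataFrame(index=pd.Index(list(genes), name="gene")),
    )
    return _flag_blanks(adata, blank_prefix)


# ---------------------------------------------------------------------------
# transcripts


def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read a detected-transcript table (gene, global_x, global_y[, cell_id])."""
    df = pd.read_csv(path)
    for col in ("gene", "global_x", "global_y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    xy = df[["global_x", "global_y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise FormatError(f"{path}: non-finite transcript coordinate")
    return df


def write_transcripts(transcripts: pd.DataFrame, path: str | Path) -> None:
    transcripts.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# polygons (GeoJSON)


def _read_feature_collection(path: str | Path, key: str) -> list[tuple[str, Polygon]]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if key not in props:
            raise FormatError(f"{path}: feature missing '{key}' property")
        poly = shape(feat["geometry"])
        if not isinstance(poly, Polygon):
            raise FormatError(f"{path}: feature '{props[key]}' is not a Polygon")
        _check_polygon(poly, f"{path}: '{props[key]}'")
        out.append((str(props[key]), poly))
    return out


def _write_feature_collection(items, key: str, path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {key: name}, "geometry": mapping(poly)}
        for name, poly in items
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons(path: str | Path) -> dict[str, Polygon]:
    """Read cell-boundary polygons; returns a ``cell_id → Polygon`` mapping."""
    items = _read_feature_collection(path, "cell_id")
    out: dict[str, Polygon] = {}
    for cell_id, poly in items:
        if cell_id in out:
            raise FormatError(f"{path}: duplicated cell_id '{cell_id}'")
        out[cell_id] = poly
    return out


def write_polygons(polygons: dict[str, Polygon], path: str | Path) -> None:
    _write_feature_collection(polygons.items(), "cell_id", path)


def read_rois(path: str | Path) -> list[RoiPolygon]:
    """Read region-of-interest polygons labelled via a ``label`` property."""
    return [RoiPolygon(label, poly) for label, poly in _read_feature_collection(path, "label")]


def write_rois(rois: list[RoiPolygon], path: str | Path) -> None:
    _write_feature_collection([(r.label, r.polygon) for r in rois], "label", path)


# ---------------------------------------------------------------------------
# group annotations and bulk reference


def read_groups(path: str | Path) -> pd.DataFrame:
    """Read AM/LR group annotations (group_id, tissue_class, position, cell_id).

    One row per member cell.  Positions must be unique within a tissue class,
    and no cell may belong to two groups.
    """
    df = pd.read_csv(path)
    for col in ("group_id", "tissue_class", "position", "cell_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df["cell_id"] = df["cell_id"].astype(str)
    df["position"] = df["position"].astype(int)
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: cell '{dup}' assigned to more than one group")
    per_group = df.drop_duplicates("group_id")
    if per_group.duplicated(["tissue_class", "position"]).any():
        raise FormatError(f"{path}: duplicated position within a tissue class")
    return df


def write_groups(groups: pd.DataFrame, path: str | Path) -> None:
    groups.to_csv(path, index=False)


def read_bulk_reference(path: str | Path) -> pd.Series:
    """Read a per-gene mean-TPM reference table (columns: gene, tpm)."""
    df = pd.read_csv(path)
    for col in ("gene", "tpm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    s = df.set_index("gene")["tpm"].astype(float)
    if (s < 0).any():
        raise FormatError(f"{path}: negative TPM value")
    return s


def write_bulk_reference(ref: pd.Series, path: str | Path) -> None:
    ref.rename("tpm").to_csv(path, index_label="gene")
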