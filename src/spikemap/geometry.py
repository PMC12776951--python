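"""Spatial primitives: transcript-to-cell assignment, cell metadata from
polygons, and ROI selection.

Point-in-polygon tests are boundary-inclusive.  When segmentation polygons
overlap, a transcript falling in several cells is assigned to the cell whose
centroid is nearest (deterministic tie-break).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, Polygon

from .errors import FormatError
from . import io as _io


def assign_transcripts(
    transcripts: pd.DataFrame, polygons: dict[str, Polygon]
) -> pd.DataFrame:
    """Assign each detected transcript to the segmented cell containing it.

    Transcripts outside every cell boundary are dropped.  Containment is
    boundary-inclusive; overlaps are resolved towards the nearest centroid.

    Parameters
    ----------
    transcripts
        Table with ``gene``, ``global_x``, ``global_y`` columns.
    polygons
        ``cell_id → Polygon`` mapping of cell boundaries.

    Returns
    -------
    The retained transcripts with a ``cell_id`` column added.
    """
    if not polygons:
        raise FormatError("assign_transcripts: empty polygon set")
    cell_ids = list(polygons)
    geoms = [polygons[c] for c in cell_ids]
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    tree = STRtree(geoms)
    pts = [Point(x, y) for x, y in transcripts[["global_x", "global_y"]].to_numpy(float)]
    # 'covered_by' includes the polygon boundary, unlike 'within'
    hit_pt, hit_poly = tree.query(pts, predicate="covered_by")

    assigned = np.full(len(transcripts), -1, dtype=int)
    if hit_pt.size:
        order = np.argsort(hit_pt, kind="stable")
        hit_pt, hit_poly = hit_pt[order], hit_poly[order]
        starts = np.searchsorted(hit_pt, np.unique(hit_pt))
        bounds = np.append(starts, hit_pt.size)
        for i in range(len(bounds) - 1):
            lo, hi = bounds[i], bounds[i + 1]
            ti = hit_pt[lo]
            cands = hit_poly[lo:hi]
            if hi - lo == 1:
                assigned[ti] = cands[0]
            else:
                p = np.array([pts[ti].x, pts[ti].y])
                d2 = ((centroids[cands] - p) ** 2).sum(axis=1)
                assigned[ti] = cands[int(np.argmin(d2))]

    keep = assigned >= 0
    out = transcripts.loc[keep].copy()
    out["cell_id"] = [cell_ids[i] for i in assigned[keep]]
    return out.reset_index(drop=True)


def aggregate_counts(
    assigned: pd.DataFrame,
    cell_ids,
    genes,
    blank_prefix: str = "Blank",
):
    """Aggregate assigned transcripts into a cells × genes count matrix.

    Cells or genes without any transcript get zero rows/columns, so the
    matrix shape is fixed by the provided id lists and the total count equals
    the number of assigned transcripts.
    """
    cell_ids = [str(c) for c in cell_ids]
    genes = list(genes)
    ci = {c: i for i, c in enumerate(cell_ids)}
    gi = {g: j for j, g in enumerate(genes)}
    X = np.zeros((len(cell_ids), len(genes)))
    rows = assigned["cell_id"].astype(str).map(ci)
    cols = assigned["gene"].map(gi)
    if rows.isna().any():
        bad = assigned.loc[rows.isna(), "cell_id"].iloc[0]
        raise FormatError(f"aggregate_counts: unknown cell_id '{bad}'")
    if cols.isna().any():
        bad = assigned.loc[cols.isna(), "gene"].iloc[0]
        raise FormatError(f"aggregate_counts: gene '{bad}' not in panel")
    np.add.at(X, (rows.to_numpy(int), cols.to_numpy(int)), 1)
    return _io.counts_from_arrays(X, cell_ids, genes, blank_prefix=blank_prefix)


def derive_cell_metadata(
    polygons: dict[str, Polygon], section_thickness: float = 10.0
) -> pd.DataFrame:
    """Derive per-cell centre and volume from boundary polygons.

    Volume is the 2D segmented area times the tissue section thickness
    (10 µm for standard cryosections); the centre is the polygon centroid.
    """
    if section_thickness <= 0:
        raise FormatError("section thickness must be > 0")
    rows = []
    for cell_id, poly in polygons.items():
        if poly.area <= 0:
            raise FormatError(f"cell '{cell_id}': degenerate polygon (zero area)")
        rows.append(
            {
                "cell_id": str(cell_id),
                "center_x": poly.centroid.x,
                "center_y": poly.centroid.y,
                "volume": poly.area * section_thickness,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def roi_filter(cells: pd.DataFrame, roi: _io.RoiPolygon) -> pd.DataFrame:
    """Keep cells whose centre lies inside or on the boundary of the ROI."""
    pts = [Point(x, y) for x, y in cells[["center_x", "center_y"]].to_numpy(float)]
    keep = [roi.polygon.covers(p) for p in pts]
    return cells.loc[keep]
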