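"""Park-wide extrapolation: fishnet grid, spatial join, prediction, Jenks.

Given a park boundary polygon (projected coordinates in meters), a set
of geotagged, segmentation-scored image points, and the four fitted
intensity models, this module

1. filters the crowdsourced points (resolution / duplicate / relevance),
2. tiles the boundary's bounding box with a square fishnet (default
   30 m, matching the field plot size) and keeps cells intersecting the
   boundary,
3. assigns points to cells by half-open containment ([xmin, xmin+s) x
   [ymin, ymin+s); the outermost top/right edges are closed so the
   tiling partitions the grid extent),
4. averages each cell's point features and predicts OBI/EBI/LBI/SBI,
5. classifies each index with Jenks natural breaks (Fisher's optimal
   1-D partition, computed by dynamic programming), and
6. exports GeoJSON / CSV maps.

Cells without any retained point carry no-data and are excluded from
prediction and classification (no interpolation is attempted).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .behavior import IntensityScores
from .landscape import FeatureVector
from .reference import FEATURES, OUTCOMES
from .regression import RegressionModel, predict

__all__ = [
    "ClassBreaks",
    "GeoImagePoint",
    "GridCell",
    "assign_points",
    "build_fishnet",
    "cell_features",
    "cells_to_frame",
    "export_maps",
    "filter_images",
    "jenks_classify",
    "points_from_csv",
    "points_to_csv",
    "predict_cells",
    "read_boundary",
    "read_cells_geojson",
    "write_boundary",
]


@dataclass(frozen=True)
class GeoImagePoint:
    """One crowdsourced geotagged photo with its landscape fractions."""

    image_id: str
    x: float
    y: float
    resolution: int          # pixel count of the image short side
    features: FeatureVector
    is_landscape: bool = True
    duplicate_key: str = ""  # content hash; equal keys mean duplicates

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for {self.image_id}")
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive for {self.image_id}")


@dataclass
class GridCell:
    """One square fishnet cell; analysis fields fill in stage by stage."""

    cell_id: str
    row: int
    col: int
    bounds: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)
    point_ids: list[str] = field(default_factory=list)
    mean_features: FeatureVector | None = None
    scores: IntensityScores | None = None
    jenks_class: dict[str, int] | None = None

    @property
    def polygon(self):
        return box(*self.bounds)


@dataclass(frozen=True)
class ClassBreaks:
    """Jenks classification result for one score series."""

    k: int
    breaks: tuple[float, ...]  # interior upper cut values, len k-1
    gvf: float                 # goodness of variance fit in [0, 1]

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")


# ---------------------------------------------------------------------------
# Image filtering
# ---------------------------------------------------------------------------

def filter_images(
    points: Iterable[GeoImagePoint],
    min_resolution: int = 1080,
) -> tuple[list[GeoImagePoint], dict[str, int]]:
    """Drop low-resolution, duplicate and non-landscape photos.

    A point is kept iff its short side is >= ``min_resolution`` pixels,
    it is landscape-related, and its content hash has not been seen
    before (first occurrence wins).  Returns the retained points and a
    per-reason rejection count.
    """
    retained: list[GeoImagePoint] = []
    seen: set[str] = set()
    log = {"low_resolution": 0, "non_landscape": 0, "duplicate": 0, "retained": 0}
    for p in points:
        if p.resolution < min_resolution:
            log["low_resolution"] += 1
            continue
        if not p.is_landscape:
            log["non_landscape"] += 1
            continue
        if p.duplicate_key:
            if p.duplicate_key in seen:
                log["duplicate"] += 1
                continue
            seen.add(p.duplicate_key)
        retained.append(p)
    log["retained"] = len(retained)
    return retained, log


# ---------------------------------------------------------------------------
# Fishnet construction and spatial join
# ---------------------------------------------------------------------------

def _check_projected(geom: BaseGeometry) -> None:
    xmin, ymin, xmax, ymax = geom.bounds
    if abs(xmin) <= 180 and abs(xmax) <= 180 and abs(ymin) <= 90 and abs(ymax) <= 90:
        raise ValueError(
            "boundary coordinates look geographic (lon/lat degrees); "
            "reproject to a metric CRS before building the fishnet"
        )


def build_fishnet(boundary: BaseGeometry, cell_size: float = 30.0) -> list[GridCell]:
    """Tile the boundary bounding box with cells intersecting the boundary.

    The grid origin sits at the bounding-box minimum; rows index
    northward and columns eastward from there.
    """
    if boundary.is_empty or not boundary.is_valid:
        raise ValueError("boundary polygon is empty or invalid")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    _check_projected(boundary)
    xmin, ymin, xmax, ymax = boundary.bounds
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate boundary (zero width or height)")
    ncols = max(1, math.ceil((xmax - xmin) / cell_size - 1e-9))
    nrows = max(1, math.ceil((ymax - ymin) / cell_size - 1e-9))
    cells = []
    for row in range(nrows):
        for col in range(ncols):
            b = (
                xmin + col * cell_size,
                ymin + row * cell_size,
                xmin + (col + 1) * cell_size,
                ymin + (row + 1) * cell_size,
            )
            if boundary.intersects(box(*b)):
                cells.append(GridCell(cell_id=f"r{row}c{col}", row=row, col=col,
                                      bounds=b))
    return cells


def assign_points(
    points: Sequence[GeoImagePoint],
    cells: Sequence[GridCell],
    cell_size: float | None = None,
) -> tuple[dict[str, list[GeoImagePoint]], list[str]]:
    """Spatial join of points into cells under the half-open convention.

    A point at a shared edge belongs to the higher-index (right/upper)
    cell, except on the grid's outermost top/right edges, which are
    closed so boundary points are not lost.  Returns the cell_id ->
    points mapping (also recorded on each cell) and the ids of points
    falling in no retained cell.
    """
    if not cells:
        raise ValueError("no cells to assign into")
    size = cell_size or (cells[0].bounds[2] - cells[0].bounds[0])
    x0 = min(c.bounds[0] for c in cells)
    y0 = min(c.bounds[1] for c in cells)
    max_col = max(c.col for c in cells)
    max_row = max(c.row for c in cells)
    by_index = {(c.row, c.col): c for c in cells}
    for c in cells:
        c.point_ids = []

    assigned: dict[str, list[GeoImagePoint]] = {c.cell_id: [] for c in cells}
    unassigned: list[str] = []
    for p in points:
        col = math.floor((p.x - x0) / size)
        row = math.floor((p.y - y0) / size)
        # closed outer edges: the last row/col also owns its far boundary
        if col == max_col + 1 and math.isclose(p.x, x0 + (max_col + 1) * size):
            col = max_col
        if row == max_row + 1 and math.isclose(p.y, y0 + (max_row + 1) * size):
            row = max_row
        cell = by_index.get((row, col))
        if cell is None:
            unassigned.append(p.image_id)
            continue
        assigned[cell.cell_id].append(p)
        cell.point_ids.append(p.image_id)
    return assigned, unassigned


def cell_features(
    cells: Sequence[GridCell],
    assigned: Mapping[str, Sequence[GeoImagePoint]],
) -> list[GridCell]:
    """Average the assigned points' fractions into each cell.

    Cells with no points keep ``mean_features=None`` (no-data) and are
    skipped by prediction and classification.
    """
    for cell in cells:
        pts = assigned.get(cell.cell_id, ())
        if not pts:
            cell.mean_features = None
            continue
        arr = np.vstack([p.features.as_array() for p in pts])
        other = float(np.mean([p.features.other for p in pts]))
        cell.mean_features = FeatureVector.from_array(arr.mean(axis=0), other=other)
    return list(cells)


def predict_cells(
    cells: Sequence[GridCell],
    models: Mapping[str, RegressionModel],
) -> list[GridCell]:
    """Evaluate the four intensity models on every data cell."""
    for cell in cells:
        if cell.mean_features is None:
            cell.scores = None
            continue
        vals = {o: predict(models[o], cell.mean_features) for o in OUTCOMES}
        cell.scores = IntensityScores(plot_id=cell.cell_id, **vals)
    return list(cells)


# ---------------------------------------------------------------------------
# Jenks natural breaks (Fisher's optimal 1-D partition)
# ---------------------------------------------------------------------------

def _prefix_ssd(sorted_vals: np.ndarray) -> "callable":
    """O(1) within-segment sum of squared deviations via prefix sums."""
    s1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_vals ** 2)])

    def ssd(i: int, j: int) -> float:  # segment [i, j) of sorted_vals
        n = j - i
        tot = s1[j] - s1[i]
        return max(0.0, (s2[j] - s2[i]) - tot * tot / n)

    return ssd


def jenks_classify(
    values: Sequence[float],
    k: int = 5,
) -> tuple[ClassBreaks, np.ndarray]:
    """Optimal 1-D classification minimizing within-class squared deviation.

    Dynamic programming over the sorted values gives the exact Fisher
    partition (deterministic; among equally good partitions the one with
    the smallest upper classes is returned).  Returns the breaks --- the
    k-1 interior cut values, each the largest member of its class ---
    with the goodness of variance fit, plus a per-input class label array
    (0-based, ordered by value).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if k <= 0:
        raise ValueError("number of classes must be positive")
    n_distinct = np.unique(vals).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")

    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    n = sv.size
    ssd = _prefix_ssd(sv)

    # dp[m][i]: min cost of splitting the first i values into m classes
    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for m in range(1, k + 1):
        for i in range(m, n - (k - m) + 1):
            best, best_j = INF, m - 1
            for j in range(m - 1, i):
                c = dp[m - 1][j]
                if c == INF:
                    continue
                c += ssd(j, i)
                if c <= best + 1e-12 and (c < best - 1e-12 or j > best_j):
                    best, best_j = min(best, c), j
            dp[m][i] = best
            back[m][i] = best_j

    # recover split positions
    cuts = [n]
    i = n
    for m in range(k, 0, -1):
        i = back[m][i]
        cuts.append(i)
    cuts = cuts[::-1]  # [0, ..., n]

    labels_sorted = np.empty(n, dtype=int)
    for cls in range(k):
        labels_sorted[cuts[cls]:cuts[cls + 1]] = cls
    # never split runs of equal values across classes
    for t in range(1, n):
        if sv[t] == sv[t - 1] and labels_sorted[t] != labels_sorted[t - 1]:
            labels_sorted[t] = labels_sorted[t - 1]

    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    present = np.unique(labels_sorted)
    remap = {c: i for i, c in enumerate(present)}
    labels = np.array([remap[c] for c in labels])
    labels_sorted = np.array([remap[c] for c in labels_sorted])
    k_eff = len(present)

    breaks = tuple(
        float(sv[np.where(labels_sorted == cls)[0][-1]]) for cls in range(k_eff - 1)
    )
    total = ssd(0, n)
    within = sum(
        ssd(int(np.where(labels_sorted == cls)[0][0]),
            int(np.where(labels_sorted == cls)[0][-1]) + 1)
        for cls in range(k_eff)
    )
    gvf = 1.0 - within / total if total > 0 else (1.0 if k_eff > 1 else 0.0)
    if k_eff == 1:
        gvf = 0.0
    return ClassBreaks(k=k_eff, breaks=breaks, gvf=float(gvf)), labels


def classify_cells(
    cells: Sequence[GridCell],
    k: int = 5,
) -> dict[str, ClassBreaks]:
    """Jenks-classify each of the four indices over all data cells."""
    data_cells = [c for c in cells if c.scores is not None]
    if not data_cells:
        raise ValueError("no cells with predictions to classify")
    out: dict[str, ClassBreaks] = {}
    for c in data_cells:
        c.jenks_class = {}
    for outcome in OUTCOMES:
        vals = [c.scores.as_dict()[outcome] for c in data_cells]
        k_use = min(k, len(np.unique(vals)))
        breaks, labels = jenks_classify(vals, k_use)
        out[outcome] = breaks
        for c, lab in zip(data_cells, labels):
            c.jenks_class[outcome] = int(lab)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_boundary(path) -> BaseGeometry:
    """Read a Polygon/MultiPolygon from GeoJSON (projected meters)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        gj = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        gj = gj["geometry"]
    geom = geom_shape(gj)
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"boundary must be (Multi)Polygon, got {geom.geom_type}")
    _check_projected(geom)
    return geom


def write_boundary(geom: BaseGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "Feature", "properties": {},
                   "geometry": geom_mapping(geom)}, fh)
        fh.write("\n")


def points_from_csv(path) -> list[GeoImagePoint]:
    """Read image points: image_id,x,y,resolution,is_landscape,duplicate_key + features."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    pts = []
    for _, r in df.iterrows():
        fv = FeatureVector({f: float(r[f]) for f in FEATURES})
        pts.append(GeoImagePoint(
            image_id=str(r["image_id"]), x=float(r["x"]), y=float(r["y"]),
            resolution=int(r["resolution"]),
            is_landscape=str(r.get("is_landscape", "True")).lower()
            in ("true", "1", "yes"),
            duplicate_key=str(r.get("duplicate_key", "")),
            features=fv,
        ))
    return pts


def points_to_csv(points: Sequence[GeoImagePoint], path) -> None:
    rows = [
        {"image_id": p.image_id, "x": p.x, "y": p.y,
         "resolution": p.resolution, "is_landscape": p.is_landscape,
         "duplicate_key": p.duplicate_key, **p.features.fractions}
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def cells_to_frame(cells: Sequence[GridCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row: dict[str, object] = {
            "cell_id": c.cell_id, "row": c.row, "col": c.col,
            "n_points": len(c.point_ids),
        }
        for o in OUTCOMES:
            row[o] = c.scores.as_dict()[o] if c.scores else np.nan
            row[f"class_{o}"] = (c.jenks_class.get(o) if c.jenks_class else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def export_maps(cells: Sequence[GridCell], out_dir, stem: str = "intensity_map",
                render: bool = False) -> dict[str, str]:
    """Write the classified grid as GeoJSON + CSV (optionally PNG rasters).

    No-data cells appear with null scores/classes so the exported grid
    tiles the park completely.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    features = []
    for c in cells:
        props: dict[str, object] = {"cell_id": c.cell_id, "row": c.row,
                                    "col": c.col, "n_points": len(c.point_ids)}
        for o in OUTCOMES:
            props[o] = c.scores.as_dict()[o] if c.scores else None
            props[f"class_{o}"] = c.jenks_class.get(o) if c.jenks_class else None
        features.append({"type": "Feature", "properties": props,
                         "geometry": geom_mapping(c.polygon)})
    gj_path = os.path.join(out_dir, f"{stem}.geojson")
    with open(gj_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
        fh.write("\n")
    csv_path = os.path.join(out_dir, f"{stem}.csv")
    cells_to_frame(cells).to_csv(csv_path, index=False)
    out = {"geojson": gj_path, "csv": csv_path}
    if render:
        out.update(_render_rasters(cells, out_dir, stem))
    return out


def _render_rasters(cells, out_dir, stem) -> dict[str, str]:
    import os

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = {}
    nrows = max(c.row for c in cells) + 1
    ncols = max(c.col for c in cells) + 1
    for o in OUTCOMES:
        img = np.full((nrows, ncols), np.nan)
        for c in cells:
            if c.jenks_class:
                img[c.row, c.col] = c.jenks_class.get(o, np.nan)
        fig, ax = plt.subplots(figsize=(6, 6 * nrows / max(ncols, 1)))
        ax.imshow(img, origin="lower", cmap="YlOrRd")
        ax.set_title(f"{o} (Jenks class)")
        ax.set_xticks([]), ax.set_yticks([])
        path = os.path.join(out_dir, f"{stem}_{o}.png")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        out[f"raster_{o}"] = path
    return out


def read_cells_geojson(path) -> list[GridCell]:
    """Re-import an exported map (round-trip of :func:`export_maps`)."""
    with open(path) as fh:
        gj = json.load(fh)
    cells = []
    for feat in gj["features"]:
        props = feat["properties"]
        geom = geom_shape(feat["geometry"])
        cell = GridCell(cell_id=props["cell_id"], row=int(props["row"]),
                        col=int(props["col"]), bounds=geom.bounds)
        if props.get("OBI") is not None:
            cell.scores = IntensityScores(
                plot_id=cell.cell_id,
                **{o: float(props[o]) for o in OUTCOMES},
            )
            cell.jenks_class = {
                o: int(props[f"class_{o}"]) for o in OUTCOMES
                if props.get(f"class_{o}") is not None
            }
        cells.append(cell)
    return cells
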