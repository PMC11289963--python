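"""Core data structures for molecule-resolved spatial transcriptomics.

A dataset is a table of detected transcripts (2D coordinates + gene label)
linked to per-cell segmentation polygons ("cell", "nucleus", and optionally
other named compartments).  This module validates and links the two, derives
gene x cell count matrices, computes per-cell geometry QC statistics, and
applies the standard preprocessing filters (minimum per-gene molecule count,
removal of cells lacking an annotated nucleus).

Conventions
-----------
* Coordinates are continuous 2D values in arbitrary "data units" (pixels or
  micrometers); no unit conversion is attempted.
* A point exactly on a polygon boundary counts as *inside* (segmentation
  masks are closed sets).
* When cell polygons overlap, a point is assigned to the smallest-area
  containing cell, ties broken by lexicographic cell id; a warning is issued.
* Gene and cell identifiers are opaque strings; lexicographic order is the
  canonical order wherever one is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.strtree import STRtree

UNASSIGNED = "unassigned"
CYTOPLASM = "cytoplasm"
NUCLEUS = "nucleus"
CELL = "cell"

POINT_COLUMNS = ["x", "y", "gene", "cell_id", "compartment"]
SHAPE_COLUMNS = ["cell_id", "compartment", "geometry"]


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class GeometryError(ValueError):
    """A segmentation geometry is invalid (self-intersecting, wrong type...)."""


class EmptyResultError(ValueError):
    """A filter removed every gene or cell."""


def validate_points(points: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a point table in place; returns the table.

    Requires columns x, y, gene; adds cell_id/compartment (= unassigned)
    when missing.  Raises :class:`SchemaError` on missing columns and a
    parse error naming the first offending row on non-finite coordinates.
    """
    for col in ("x", "y", "gene"):
        if col not in points.columns:
            raise SchemaError(f"point table is missing required column {col!r}")
    for col in ("x", "y"):
        vals = pd.to_numeric(points[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"non-finite or non-numeric coordinate in column {col!r} at row {row}"
            )
        points[col] = vals
    points["gene"] = points["gene"].astype(str)
    if "cell_id" not in points.columns:
        points["cell_id"] = UNASSIGNED
    if "compartment" not in points.columns:
        points["compartment"] = UNASSIGNED
    return points


def validate_shapes(shapes: pd.DataFrame, split_multipolygons: bool = False) -> pd.DataFrame:
    """Validate a shape table (cell_id, compartment, geometry).

    Every geometry must be a simple polygon with positive area.
    MultiPolygons are split into suffixed records when
    ``split_multipolygons`` is set, otherwise rejected.
    """
    for col in ("cell_id", "compartment"):
        if col not in shapes.columns:
            raise SchemaError(f"shape table is missing required column {col!r}")
    records = []
    for _, row in shapes.iterrows():
        geom = row["geometry"]
        if geom.geom_type == "MultiPolygon":
            if not split_multipolygons:
                raise GeometryError(
                    f"MultiPolygon for cell {row['cell_id']!r}; pass "
                    "split_multipolygons=True to split into parts"
                )
            parts = list(geom.geoms)
            for i, part in enumerate(parts):
                rec = row.copy()
                rec["geometry"] = part
                rec["cell_id"] = f"{row['cell_id']}-{i}"
                records.append(rec)
            continue
        if geom.geom_type != "Polygon":
            raise GeometryError(
                f"geometry for cell {row['cell_id']!r} is {geom.geom_type}, expected Polygon"
            )
        if not geom.is_valid:
            raise GeometryError(
                f"invalid (e.g. self-intersecting) polygon for cell {row['cell_id']!r}"
            )
        if geom.area <= 0:
            raise GeometryError(f"zero-area polygon for cell {row['cell_id']!r}")
        records.append(row)
    out = pd.DataFrame(records).reset_index(drop=True)
    out["cell_id"] = out["cell_id"].astype(str)
    out["compartment"] = out["compartment"].astype(str)
    counts = out[out["compartment"] == CELL]["cell_id"].value_counts()
    dup = counts[counts > 1]
    if len(dup):
        raise GeometryError(f"multiple 'cell' polygons for cell id(s) {list(dup.index)}")
    return out[SHAPE_COLUMNS + [c for c in out.columns if c not in SHAPE_COLUMNS]]


def points_in_polygon(x: np.ndarray, y: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Vectorized point-in-polygon with boundary counted as inside."""
    return shapely.intersects_xy(polygon, np.asarray(x, float), np.asarray(y, float))


def assign_points(points: pd.DataFrame, shapes: pd.DataFrame) -> pd.DataFrame:
    """Assign each molecule to a cell and a compartment.

    A point is assigned to the cell polygon containing it (boundary
    inclusive).  If several cell polygons contain it, the smallest area wins
    (ties: lexicographic cell id) and a warning is issued.  Within the cell,
    compartment is "nucleus" if the point lies inside that cell's nucleus
    polygon, else "cytoplasm".  Points inside no cell stay unassigned.
    """
    if shapes.empty:
        raise ValueError("shape set is empty")
    points = validate_points(points.copy())
    cells = shapes[shapes["compartment"] == CELL].reset_index(drop=True)
    nuclei = shapes[shapes["compartment"] == NUCLEUS]
    nucleus_by_cell = dict(zip(nuclei["cell_id"], nuclei["geometry"]))

    geoms = list(cells["geometry"])
    tree = STRtree(geoms)
    pts = shapely.points(points["x"].to_numpy(), points["y"].to_numpy())
    pt_idx, cell_idx = tree.query(pts, predicate="intersects")

    cell_ids = cells["cell_id"].to_numpy()
    areas = np.array([g.area for g in geoms])
    assigned = np.full(len(points), UNASSIGNED, dtype=object)
    if len(pt_idx):
        order = np.lexsort(
            (cell_ids[cell_idx], areas[cell_idx], pt_idx)
        )  # per point: smallest area first, then lexicographic id
        pt_sorted = pt_idx[order]
        first = np.ones(len(pt_sorted), dtype=bool)
        first[1:] = pt_sorted[1:] != pt_sorted[:-1]
        if (~first).any():
            warnings.warn(
                "overlapping cell polygons: points assigned to the smallest "
                "containing cell",
                stacklevel=2,
            )
        assigned[pt_sorted[first]] = cell_ids[cell_idx[order][first]]

    points["cell_id"] = assigned
    comp = np.full(len(points), UNASSIGNED, dtype=object)
    for cid in np.unique(assigned[assigned != UNASSIGNED]):
        m = assigned == cid
        comp[m] = CYTOPLASM
        nuc = nucleus_by_cell.get(cid)
        if nuc is not None:
            in_nuc = points_in_polygon(
                points.loc[m, "x"].to_numpy(), points.loc[m, "y"].to_numpy(), nuc
            )
            idx = np.flatnonzero(m)[in_nuc]
            comp[idx] = NUCLEUS
    points["compartment"] = comp
    return points


def count_matrix(points: pd.DataFrame) -> pd.DataFrame:
    """Gene x cell matrix of assigned molecule counts (lexicographic axes)."""
    assigned = points[points["cell_id"] != UNASSIGNED]
    if assigned.empty:
        warnings.warn("no assigned points; count matrix is empty", stacklevel=2)
        return pd.DataFrame(dtype=int)
    mat = pd.crosstab(assigned["gene"], assigned["cell_id"])
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.index.name = "gene"
    mat.columns.name = "cell_id"
    return mat


@dataclass
class CellDataset:
    """Linked molecules + segmentation + derived counts for one sample."""

    points: pd.DataFrame
    shapes: pd.DataFrame
    counts: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    per_cell_stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = count_matrix(self.points)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.shapes.loc[self.shapes["compartment"] == CELL, "cell_id"])

    def cell_polygon(self, cell_id: str) -> Polygon:
        sel = self.shapes[
            (self.shapes["cell_id"] == cell_id) & (self.shapes["compartment"] == CELL)
        ]
        return sel["geometry"].iloc[0]

    def nucleus_polygon(self, cell_id: str) -> Polygon | None:
        sel = self.shapes[
            (self.shapes["cell_id"] == cell_id) & (self.shapes["compartment"] == NUCLEUS)
        ]
        return sel["geometry"].iloc[0] if len(sel) else None


def make_dataset(points: pd.DataFrame, shapes: pd.DataFrame) -> CellDataset:
    """Validate shapes, assign points, and build the linked dataset."""
    shapes = validate_shapes(shapes)
    points = assign_points(points, shapes)
    ds = CellDataset(points=points, shapes=shapes)
    ds.per_cell_stats = shape_stats(ds)
    return ds


def shape_stats(dataset: CellDataset) -> pd.DataFrame:
    """Per-cell geometry QC metrics.

    Columns: cell_area, cell_perimeter, nucleus_area, nucleus_area_ratio,
    equivalent_radius (sqrt(area/pi)), aspect_ratio (long/short side of the
    minimum rotated bounding rectangle), molecule_density (assigned
    molecules per unit cell area).  Nucleus columns are NaN when the cell
    has no nucleus polygon.
    """
    rows = []
    n_per_cell = dataset.points[dataset.points["cell_id"] != UNASSIGNED][
        "cell_id"
    ].value_counts()
    for cid in dataset.cell_ids:
        cell = dataset.cell_polygon(cid)
        nuc = dataset.nucleus_polygon(cid)
        rect = cell.minimum_rotated_rectangle
        if rect.geom_type == "Polygon":
            xs, ys = rect.exterior.coords.xy
            e1 = float(np.hypot(xs[1] - xs[0], ys[1] - ys[0]))
            e2 = float(np.hypot(xs[2] - xs[1], ys[2] - ys[1]))
            lo, hi = sorted((e1, e2))
            aspect = hi / lo if lo > 0 else np.nan
        else:  # degenerate (line/point) rectangle
            aspect = np.nan
        n = int(n_per_cell.get(cid, 0))
        rows.append(
            {
                "cell_id": cid,
                "cell_area": cell.area,
                "cell_perimeter": cell.length,
                "nucleus_area": nuc.area if nuc is not None else np.nan,
                "nucleus_area_ratio": nuc.area / cell.area if nuc is not None else np.nan,
                "equivalent_radius": np.sqrt(cell.area / np.pi),
                "aspect_ratio": aspect,
                "molecule_count": n,
                "molecule_density": n / cell.area,
            }
        )
    return pd.DataFrame(rows).set_index("cell_id")


def filter_dataset(
    dataset: CellDataset, min_gene_count: int = 10, require_nucleus: bool = True
) -> CellDataset:
    """Apply the standard preprocessing filters.

    Keeps genes detected with at least ``min_gene_count`` molecules in at
    least one cell, and (when ``require_nucleus``) drops cells without an
    annotated nucleus polygon.  Points, shapes and counts stay consistent.
    """
    shapes = dataset.shapes
    keep_cells = set(dataset.cell_ids)
    if require_nucleus:
        with_nuc = set(shapes.loc[shapes["compartment"] == NUCLEUS, "cell_id"])
        keep_cells &= with_nuc

    counts = dataset.counts
    if counts.empty:
        raise EmptyResultError("dataset has no assigned molecules")
    counts = counts[[c for c in counts.columns if c in keep_cells]]
    keep_genes = counts.index[counts.max(axis=1) >= min_gene_count] if len(counts.columns) else []
    if len(keep_genes) == 0:
        raise EmptyResultError(
            f"no gene reaches {min_gene_count} molecules in any remaining cell"
        )

    points = dataset.points.copy()
    drop = ~points["cell_id"].isin(keep_cells) & (points["cell_id"] != UNASSIGNED)
    points.loc[drop, ["cell_id", "compartment"]] = UNASSIGNED
    points = points[points["gene"].isin(keep_genes)].reset_index(drop=True)
    shapes = shapes[shapes["cell_id"].isin(keep_cells)].reset_index(drop=True)
    ds = CellDataset(points=points, shapes=shapes)
    ds.per_cell_stats = shape_stats(ds)
    return ds
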