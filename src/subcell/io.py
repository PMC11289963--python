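"""Readers and writers for point tables, segmentation shapes, and counts.

Points come as CSV/TSV/Parquet with a configurable column map; shapes as a
GeoJSON FeatureCollection (feature properties ``cell_id``/``compartment``)
or a WKT table; count matrices round-trip through MatrixMarket with
``genes.tsv``/``cells.tsv`` index files.  A dataset bundle is a plain
directory holding ``points.parquet``, ``shapes.geojson`` and the counts
triplet, so every artifact stays human-inspectable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse
import shapely
from shapely.geometry import mapping, shape

from .core import CellDataset, SchemaError, validate_points, validate_shapes

DEFAULT_COLUMNS = {"x": "x", "y": "y", "gene": "gene", "cell_id": "cell"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".parquet", ".pq"):
        return pd.read_parquet(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def load_points(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a molecule table.

    ``column_map`` maps canonical names (x, y, gene, cell_id) to the file's
    column names; unmapped canonical names default to themselves.  Gene
    labels are preserved verbatim and row order is kept.  A z column, if
    present, is dropped with a warning (analysis is strictly 2D).
    """
    table = _read_table(path)
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    rename = {src: dst for dst, src in cmap.items() if src in table.columns and src != dst}
    table = table.rename(columns=rename)
    if "z" in table.columns:
        warnings.warn("dropping z column: analysis is 2D", stacklevel=2)
        table = table.drop(columns="z")
    for col in ("x", "y", "gene"):
        if col not in table.columns:
            raise SchemaError(
                f"column {cmap.get(col, col)!r} (mapped to {col!r}) not found in {path}"
            )
    return validate_points(table)


def load_shapes(
    path: str | Path, format: str | None = None, split_multipolygons: bool = False
) -> pd.DataFrame:
    """Load segmentation polygons from GeoJSON or a WKT table.

    GeoJSON: a FeatureCollection whose feature properties carry ``cell_id``
    and ``compartment``.  WKT table: CSV/TSV with columns cell_id,
    compartment, wkt.  Format is inferred from the extension when not given.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix in (".geojson", ".json") else "wkt-table"
    if format == "geojson":
        payload = json.loads(path.read_text())
        rows = []
        for feat in payload.get("features", []):
            props = feat.get("properties", {}) or {}
            rows.append(
                {
                    "cell_id": props.get("cell_id"),
                    "compartment": props.get("compartment", "cell"),
                    "geometry": shape(feat["geometry"]),
                }
            )
        table = pd.DataFrame(rows)
    elif format == "wkt-table":
        table = _read_table(path)
        if "wkt" not in table.columns:
            raise SchemaError(f"WKT shape table {path} lacks a 'wkt' column")
        table = table.assign(geometry=[shapely.from_wkt(w) for w in table["wkt"]]).drop(
            columns="wkt"
        )
    else:
        raise ValueError(f"unknown shape format {format!r}")
    return validate_shapes(table, split_multipolygons=split_multipolygons)


def save_shapes(shapes: pd.DataFrame, path: str | Path) -> None:
    """Write a shape table as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"cell_id": row["cell_id"], "compartment": row["compartment"]},
            "geometry": mapping(row["geometry"]),
        }
        for _, row in shapes.iterrows()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def save_counts_mtx(counts: pd.DataFrame, outdir: str | Path) -> None:
    """Write counts as MatrixMarket plus genes.tsv / cells.tsv index files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / "counts.mtx", scipy.sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(outdir / "cells.tsv", sep="\t", index=False, header=False)


def load_counts_mtx(outdir: str | Path) -> pd.DataFrame:
    """Read a MatrixMarket counts triplet written by :func:`save_counts_mtx`."""
    outdir = Path(outdir)
    mat = scipy.io.mmread(outdir / "counts.mtx").toarray().astype(int)
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t", header=None)[0].astype(str)
    out = pd.DataFrame(mat, index=genes, columns=cells)
    out.index.name = "gene"
    out.columns.name = "cell_id"
    return out


def save_dataset(dataset: CellDataset, outdir: str | Path) -> None:
    """Persist a dataset bundle (points.parquet + shapes.geojson + counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.points.to_parquet(outdir / "points.parquet")
    save_shapes(dataset.shapes, outdir / "shapes.geojson")
    if not dataset.counts.empty:
        save_counts_mtx(dataset.counts, outdir)
    if dataset.per_cell_stats is not None:
        dataset.per_cell_stats.to_csv(outdir / "per_cell_stats.tsv", sep="\t")


def load_dataset(outdir: str | Path) -> CellDataset:
    """Load a dataset bundle written by :func:`save_dataset`."""
    outdir = Path(outdir)
    points = pd.read_parquet(outdir / "points.parquet")
    shapes = load_shapes(outdir / "shapes.geojson")
    ds = CellDataset(points=points, shapes=shapes)
    stats = outdir / "per_cell_stats.tsv"
    if stats.exists():
        ds.per_cell_stats = pd.read_csv(stats, sep="\t", index_col=0)
    return ds
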