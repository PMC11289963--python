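"""Unsupervised pixel-embedding segmentation of subcellular domains.

A uniform grid of query coordinates (step s, clipped to each cell) is laid
over every cell.  Each query gets a local gene-composition vector v_i (gene
counts within a fixed radius, normalized to sum to one); the cell's overall
composition x_j plays the role of the expected composition.  The embedding

    r_i = (v_i - x_j) / sigma_v

measures the local deviation of composition from the whole-cell mixture in
units of the composition standard deviation sigma_v (computed per cell by
default).  Embeddings are reduced with (uncentered) truncated SVD to the
top 10 components and quantized with a 1 x k self-organizing map; the k
minimizing-curve elbow of the quantization error selects the number of
"fluxmap" domains.  Domains are relabeled canonically (descending nucleus
overlap, then size) and can be vectorized to per-cell polygons or rendered
as an RGB image from the top-3 components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from shapely.geometry import box

from ._geometry import contains_fn
from ._som import SOM1D
from ._util import elbow_index
from .core import CELL, NUCLEUS, UNASSIGNED, CellDataset

DEFAULT_STEP = 10.0
DEFAULT_RADIUS = 40.0


@dataclass
class FluxGrid:
    """Uniform in-cell query coordinates (columns cell_id, x, y)."""

    table: pd.DataFrame
    step: float


def make_grid(shapes: pd.DataFrame, step: float = DEFAULT_STEP) -> FluxGrid:
    """Uniform grid of query points per cell, anchored at the bbox minimum.

    Only queries inside the cell polygon (boundary inclusive) are kept; a
    cell smaller than the step still contributes one query at its centroid
    (or an interior representative point for non-convex cells).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rows = []
    for _, rec in shapes[shapes["compartment"] == CELL].iterrows():
        poly = rec["geometry"]
        minx, miny, maxx, maxy = poly.bounds
        nx = int(np.floor((maxx - minx) / step + 1e-9)) + 1
        ny = int(np.floor((maxy - miny) / step + 1e-9)) + 1
        gx = minx + step * np.arange(nx)
        gy = miny + step * np.arange(ny)
        xx, yy = np.meshgrid(gx, gy)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[contains_fn(poly)(pts)]
        if len(pts) == 0:
            c = poly.centroid
            if not shapely.intersects_xy(poly, c.x, c.y):
                c = poly.representative_point()
            pts = np.array([[c.x, c.y]])
        for x, y in pts:
            rows.append({"cell_id": rec["cell_id"], "x": x, "y": y})
    return FluxGrid(table=pd.DataFrame(rows), step=float(step))


def local_composition(
    points: pd.DataFrame, queries: np.ndarray, radius: float, genes: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-query gene composition within ``radius`` (boundary inclusive).

    Returns (v, empty): v is (n_queries, n_genes) with rows summing to one
    where any molecule is in range, and ``empty`` flags all-zero
    neighborhoods (their v row is left as zeros, never NaN).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    gene_idx = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(queries), len(genes)))
    if len(points):
        xy = points[["x", "y"]].to_numpy(float)
        cols = points["gene"].map(gene_idx).to_numpy()
        tree = cKDTree(xy)
        for qi, nbrs in enumerate(tree.query_ball_point(np.asarray(queries, float), radius)):
            for j in nbrs:
                counts[qi, cols[j]] += 1
    totals = counts.sum(axis=1)
    empty = totals == 0
    v = np.zeros_like(counts)
    v[~empty] = counts[~empty] / totals[~empty, None]
    return v, empty


@dataclass
class FluxEmbedding:
    """Per-query composition-deviation embeddings for a dataset."""

    grid: FluxGrid
    genes: list[str]
    v: np.ndarray  # (n_q, G) local compositions
    cell_composition: np.ndarray  # (n_q, G) owning cell's composition
    sigma: np.ndarray  # (n_q, G) sigma_v used per query (scope-dependent)
    embedding: np.ndarray  # (n_q, G) r_i
    empty: np.ndarray  # (n_q,) all-zero neighborhood flag
    radius: float
    scope: str
    shapes: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    reduced: np.ndarray | None = None  # (n_q, n_components)
    components: np.ndarray | None = None  # (n_components, G)
    explained_variance_ratio: np.ndarray | None = None


def flux_embed(
    dataset: CellDataset,
    step: float = DEFAULT_STEP,
    radius: float = DEFAULT_RADIUS,
    scope: str = "per_cell",
    min_queries: int = 10,
) -> FluxEmbedding:
    """Compute r_i = (v_i - x_j) / sigma_v on a uniform grid over each cell.

    ``scope`` selects whether sigma_v is the standard deviation of local
    compositions within each cell ("per_cell", the default: the embedding
    then measures intracellular variation) or across the whole dataset
    ("global").  Cells with fewer than ``min_queries`` grid queries are
    skipped with a warning.  Zero-variance genes get a sigma component of
    1 so their embedding entry is exactly v - x.
    """
    if scope not in ("per_cell", "global"):
        raise ValueError("scope must be 'per_cell' or 'global'")
    genes = sorted(dataset.counts.index)
    grid = make_grid(dataset.shapes, step)
    assigned = dataset.points[dataset.points["cell_id"] != UNASSIGNED]

    tables, vs, empties, xs = [], [], [], []
    for cell_id, sub in grid.table.groupby("cell_id", sort=True):
        if len(sub) < min_queries:
            warnings.warn(
                f"cell {cell_id!r}: only {len(sub)} grid queries (<{min_queries}); skipped",
                stacklevel=2,
            )
            continue
        pts = assigned[assigned["cell_id"] == cell_id]
        v, empty = local_composition(pts, sub[["x", "y"]].to_numpy(float), radius, genes)
        col = dataset.counts.reindex(genes)[cell_id].to_numpy(float) if cell_id in dataset.counts.columns else np.zeros(len(genes))
        total = col.sum()
        x_j = col / total if total > 0 else np.zeros(len(genes))
        tables.append(sub)
        vs.append(v)
        empties.append(empty)
        xs.append(np.tile(x_j, (len(sub), 1)))
    if not tables:
        raise ValueError("no cell has enough grid queries")
    table = pd.concat(tables, ignore_index=True)
    v = np.vstack(vs)
    empty = np.concatenate(empties)
    x_mat = np.vstack(xs)

    sigma = np.ones_like(v)
    if scope == "global":
        valid = ~empty
        sd = v[valid].std(axis=0) if valid.any() else np.zeros(len(genes))
        sd[sd == 0] = 1.0
        sigma[:] = sd
    else:
        start = 0
        for sub, emp in zip(tables, empties):
            n = len(sub)
            rows = slice(start, start + n)
            valid = ~emp
            sd = v[rows][valid].std(axis=0) if valid.any() else np.zeros(len(genes))
            sd[sd == 0] = 1.0
            sigma[rows] = sd
            start += n

    embedding = np.zeros_like(v)
    embedding[~empty] = (v[~empty] - x_mat[~empty]) / sigma[~empty]
    return FluxEmbedding(
        grid=FluxGrid(table=table, step=grid.step),
        genes=genes,
        v=v,
        cell_composition=x_mat,
        sigma=sigma,
        embedding=embedding,
        empty=empty,
        radius=float(radius),
        scope=scope,
        shapes=dataset.shapes,
    )


def reduce(embedding: FluxEmbedding, n_components: int = 10) -> FluxEmbedding:
    """Uncentered truncated SVD of the embedding matrix, top components.

    Component signs follow a fixed convention (largest-magnitude loading
    positive) so results are deterministic.  If fewer non-degenerate
    dimensions exist than requested the reduction shrinks with a warning.
    """
    r = embedding.embedding[~embedding.empty]
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    effective = int((s > max(s.max(), 1e-300) * 1e-10).sum())
    if n_components > effective:
        warnings.warn(
            f"only {effective} non-degenerate dimensions available; "
            f"reducing to {effective}",
            stacklevel=2,
        )
        n_components = effective
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    flip = np.sign(vt[np.arange(len(vt)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    scores = np.zeros((len(embedding.embedding), n_components))
    scores[~embedding.empty] = u * s
    total_var = (embedding.embedding[~embedding.empty] ** 2).sum()
    embedding.reduced = scores
    embedding.components = vt
    embedding.explained_variance_ratio = (s**2) / total_var if total_var > 0 else s * 0
    return embedding


@dataclass
class FluxmapResult:
    """SOM quantization of flux embeddings into subcellular domains."""

    labels: np.ndarray  # (n_q,) domain in 1..k, aligned with grid rows
    k: int
    quantization_curve: pd.DataFrame  # columns k, quantization_error
    som: SOM1D
    degenerate: bool = False


def fit_fluxmaps(
    embedding: FluxEmbedding,
    k_range: range = range(2, 13),
    seed: int = 0,
    n_iter: int = 10_000,
) -> FluxmapResult:
    """Quantize reduced embeddings with 1 x k SOMs and pick k at the elbow.

    The SOM is fit jointly across all cells (the embeddings are
    cell-normalized, so domains are shared).  Empty-neighborhood queries
    are excluded from fitting and inherit the label of the nearest labeled
    query of the same cell.  Domains are relabeled canonically: descending
    mean nucleus overlap, then descending size, so domain 1 is the most
    nuclear.
    """
    if embedding.reduced is None:
        reduce(embedding)
    ks = list(k_range)
    x = embedding.reduced[~embedding.empty]
    rows_ok = np.isfinite(x).all(axis=1)
    if not rows_ok.all():  # pragma: no cover - contract guard
        warnings.warn("non-finite embedding rows excluded from SOM fit", stacklevel=2)
        x = x[rows_ok]
    if len(x) < max(ks):
        raise ValueError(f"need at least {max(ks)} queries to search k in {ks}")
    soms, errors = {}, []
    for k in ks:
        som = SOM1D(k, n_iter=n_iter, seed=seed).fit(x)
        soms[k] = som
        errors.append(som.quantization_error(x))
    # anchor the curve with the trivial one-prototype quantizer so the
    # perpendicular-distance rule can select the smallest searched k
    anchor = float(np.sqrt(((x - x.mean(axis=0)) ** 2).sum(axis=1)).mean())
    idx, degenerate = elbow_index(
        np.array([ks[0] - 1] + ks, dtype=float), np.array([anchor] + errors)
    )
    idx = max(idx - 1, 0)
    scale = float(np.sqrt((x**2).sum(axis=1).mean()))
    if max(errors) <= 1e-8 * max(scale, 1.0):
        idx, degenerate = 0, True  # constant embedding: quantization error ~0
    k = ks[idx]
    som = soms[k]

    labels = np.zeros(len(embedding.reduced), dtype=int)
    labels[~embedding.empty] = som.predict(embedding.reduced[~embedding.empty]) + 1
    # empty queries inherit the nearest labeled query's domain within the cell
    table = embedding.grid.table
    for cell_id, sub in table.groupby("cell_id", sort=False):
        rows = sub.index.to_numpy()
        emp = embedding.empty[rows]
        if not emp.any():
            continue
        lab_rows = rows[~emp]
        if len(lab_rows) == 0:
            labels[rows] = 1  # all-empty cell: single default domain
            continue
        tree = cKDTree(table.loc[lab_rows, ["x", "y"]].to_numpy(float))
        _, nearest = tree.query(table.loc[rows[emp], ["x", "y"]].to_numpy(float))
        labels[rows[emp]] = labels[lab_rows[nearest]]

    labels = _relabel_canonical(labels, embedding)
    return FluxmapResult(
        labels=labels,
        k=k,
        quantization_curve=pd.DataFrame({"k": ks, "quantization_error": errors}),
        som=som,
        degenerate=degenerate,
    )


def _relabel_canonical(labels: np.ndarray, embedding: FluxEmbedding) -> np.ndarray:
    """Order domains by descending mean nucleus overlap, then size."""
    table = embedding.grid.table
    shapes = embedding.shapes
    nuc_by_cell = {}
    if shapes is not None:
        nuc = shapes[shapes["compartment"] == NUCLEUS]
        nuc_by_cell = dict(zip(nuc["cell_id"], nuc["geometry"]))
    in_nucleus = np.zeros(len(table), dtype=bool)
    for cell_id, sub in table.groupby("cell_id", sort=False):
        poly = nuc_by_cell.get(cell_id)
        if poly is None:
            continue
        pts = sub[["x", "y"]].to_numpy(float)
        in_nucleus[sub.index.to_numpy()] = contains_fn(poly)(pts)
    domains = np.unique(labels)
    stats = []
    for d in domains:
        m = labels == d
        stats.append((d, float(in_nucleus[m].mean()), int(m.sum())))
    order = sorted(stats, key=lambda t: (-t[1], -t[2], t[0]))
    remap = {old: new + 1 for new, (old, _, _) in enumerate(order)}
    return np.array([remap[l] for l in labels])


def domain_polygons(
    result: FluxmapResult, embedding: FluxEmbedding
) -> pd.DataFrame:
    """Vectorize domain labels into per-cell per-domain polygons.

    Each query contributes its step x step grid tile; tiles of a domain are
    unioned and clipped to the cell polygon.  Rows: cell_id, domain,
    geometry (Polygon or MultiPolygon), area.
    """
    table = embedding.grid.table
    step = embedding.grid.step
    cell_polys = dict(
        zip(
            embedding.shapes.loc[embedding.shapes["compartment"] == CELL, "cell_id"],
            embedding.shapes.loc[embedding.shapes["compartment"] == CELL, "geometry"],
        )
    )
    rows = []
    for cell_id, sub in table.groupby("cell_id", sort=True):
        cell_poly = cell_polys[cell_id]
        labs = result.labels[sub.index.to_numpy()]
        for d in np.unique(labs):
            pts = sub[["x", "y"]].to_numpy(float)[labs == d]
            tiles = [
                box(x - step / 2, y - step / 2, x + step / 2, y + step / 2) for x, y in pts
            ]
            geom = shapely.unary_union(tiles).intersection(cell_poly)
            rows.append(
                {"cell_id": cell_id, "domain": int(d), "geometry": geom, "area": geom.area}
            )
    return pd.DataFrame(rows)


def save_embedding(embedding: FluxEmbedding, outdir) -> None:
    """Persist an embedding bundle (npz arrays + grid parquet + shapes)."""
    import json
    from pathlib import Path

    from .io import save_shapes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = {
        "v": embedding.v,
        "cell_composition": embedding.cell_composition,
        "sigma": embedding.sigma,
        "embedding": embedding.embedding,
        "empty": embedding.empty,
    }
    if embedding.reduced is not None:
        arrays["reduced"] = embedding.reduced
        arrays["components"] = embedding.components
        arrays["explained_variance_ratio"] = embedding.explained_variance_ratio
    np.savez(outdir / "flux.npz", **arrays)
    embedding.grid.table.to_parquet(outdir / "grid.parquet")
    save_shapes(embedding.shapes, outdir / "shapes.geojson")
    meta = {
        "genes": embedding.genes,
        "radius": embedding.radius,
        "step": embedding.grid.step,
        "scope": embedding.scope,
    }
    (outdir / "meta.json").write_text(json.dumps(meta))


def load_embedding(outdir) -> FluxEmbedding:
    """Load an embedding bundle written by :func:`save_embedding`."""
    import json
    from pathlib import Path

    from .io import load_shapes

    outdir = Path(outdir)
    arrays = np.load(outdir / "flux.npz")
    meta = json.loads((outdir / "meta.json").read_text())
    emb = FluxEmbedding(
        grid=FluxGrid(table=pd.read_parquet(outdir / "grid.parquet"), step=meta["step"]),
        genes=meta["genes"],
        v=arrays["v"],
        cell_composition=arrays["cell_composition"],
        sigma=arrays["sigma"],
        embedding=arrays["embedding"],
        empty=arrays["empty"],
        radius=meta["radius"],
        scope=meta["scope"],
        shapes=load_shapes(outdir / "shapes.geojson"),
    )
    if "reduced" in arrays:
        emb.reduced = arrays["reduced"]
        emb.components = arrays["components"]
        emb.explained_variance_ratio = arrays["explained_variance_ratio"]
    return emb


def render_rgb(
    embedding: FluxEmbedding, resolution: float = 1.0
) -> np.ndarray:
    """RGBA raster of the top-3 reduced components across all cells.

    Per-query quantile ranks of each component are mapped affinely to
    [0.1, 0.9] (so the extremes avoid saturating to black/white) and used
    as red, green, blue; values between grid points are filled by linear
    interpolation; pixels outside every cell are transparent.  A constant
    component renders as 0.5 everywhere.  With fewer than 3 components a
    single-channel (grayscale replicated) image is produced with a warning.
    """
    from scipy.interpolate import griddata

    if embedding.reduced is None:
        reduce(embedding)
    scores = embedding.reduced[~embedding.empty]
    pts = embedding.grid.table.loc[~embedding.empty, ["x", "y"]].to_numpy(float)
    n_comp = scores.shape[1]
    if n_comp < 3:
        warnings.warn("fewer than 3 components; rendering grayscale", stacklevel=2)
        comps = scores[:, :1].repeat(3, axis=1)
    else:
        comps = scores[:, :3]
    n = len(comps)
    channels = np.empty_like(comps)
    for c in range(3):
        ranks = rankdata(comps[:, c], method="average")
        q = (ranks - 1) / (n - 1) if n > 1 else np.full(n, 0.5)
        channels[:, c] = 0.1 + 0.8 * q

    cells = embedding.shapes[embedding.shapes["compartment"] == CELL]["geometry"]
    minx, miny, maxx, maxy = shapely.unary_union(list(cells)).bounds
    w = max(int(np.ceil((maxx - minx) / resolution)), 1)
    h = max(int(np.ceil((maxy - miny) / resolution)), 1)
    gx = minx + (np.arange(w) + 0.5) * resolution
    gy = miny + (np.arange(h) + 0.5) * resolution
    xx, yy = np.meshgrid(gx, gy)
    img = np.zeros((h, w, 4))
    for c in range(3):
        vals = griddata(pts, channels[:, c], (xx, yy), method="linear")
        nearest = griddata(pts, channels[:, c], (xx, yy), method="nearest")
        vals = np.where(np.isnan(vals), nearest, vals)
        img[:, :, c] = vals
    inside = np.zeros((h, w), dtype=bool)
    flat = np.column_stack([xx.ravel(), yy.ravel()])
    for poly in cells:
        inside |= contains_fn(poly)(flat).reshape(h, w)
    img[:, :, 3] = inside.astype(float)
    img[~inside, :3] = 0.0
    return img
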