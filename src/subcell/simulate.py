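"""Ground-truth simulation of subcellular RNA localization patterns.

Generates synthetic cells (smoothed random star-convex cell + nucleus
polygons) and patterned transcript point sets for five localization
classes — cell_edge, cytoplasmic, none, nuclear, nuclear_edge — each at
three strengths (weak, moderate, strong).  Transcript abundance is drawn
per sample from Poisson distributions at three expression levels (40, 100,
200 molecules per average-sized cell, scaled by cell area) and clamped to
[5, 300].  The default training set is 2,000 samples per class (10,000
total) with a stratified 80/20 train/test split.

Pattern strength is realized as a mixture: each molecule is drawn from the
class-specific density with probability w (0.25 / 0.5 / 0.9 for weak /
moderate / strong) and from complete spatial randomness (CSR) over the cell
otherwise, so "weak" is close to spatially random.  Edge classes use an
exponential distance-to-boundary kernel exp(-d/tau) with tau defaulting to
5% of the cell equivalent radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from ._geometry import StarRing

LABELS = ("cell_edge", "cytoplasmic", "none", "nuclear", "nuclear_edge")
STRENGTHS = ("weak", "moderate", "strong")
ABUNDANCE_LEVELS = (40, 100, 200)
COUNT_MIN, COUNT_MAX = 5, 300

#: mixture weight of the pattern density vs CSR, per strength
STRENGTH_WEIGHTS = {"weak": 0.25, "moderate": 0.5, "strong": 0.9}

#: mean cell area in data units^2 (equivalent radius 50 data units)
DEFAULT_MEAN_AREA = float(np.pi * 50.0**2)


@dataclass
class SyntheticCell:
    """A generated cell/nucleus polygon pair.

    ``area_scale`` is the cell area relative to the cohort mean area and
    scales the expected molecule abundance.
    """

    cell: Polygon
    nucleus: Polygon
    area_scale: float

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.cell.area / np.pi))


@dataclass
class SimSample:
    """One simulated gene-in-cell point set with its ground-truth label."""

    points: np.ndarray  # (n, 2)
    label: str
    strength: str
    abundance_level: int
    cell: SyntheticCell
    seed: int


@dataclass
class TrainingSet:
    samples: list[SimSample]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])


def _star_blob(
    rng: np.random.Generator,
    center: np.ndarray,
    base_radius: float,
    amplitude: float,
    n_vertices: int = 48,
    n_harmonics: int = 5,
) -> Polygon:
    """Smoothed star-convex blob: r(theta) = R (1 + sum_k a_k cos(k theta + phi_k))."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 2 + n_harmonics):
        a_k = rng.normal(0.0, amplitude / k)
        phi_k = rng.uniform(0, 2 * np.pi)
        r += a_k * np.cos(k * theta + phi_k)
    r = np.clip(r, 0.25, None) * base_radius
    xy = center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Polygon(xy)


def make_cells(
    n: int,
    seed: int,
    mean_area: float = DEFAULT_MEAN_AREA,
    area_sigma: float = 0.25,
    perturbation: float = 0.18,
    max_retries: int = 50,
) -> list[SyntheticCell]:
    """Generate ``n`` synthetic cells with nuclei, deterministic per seed.

    Cell areas are lognormal around ``mean_area``; boundary irregularity is
    controlled by ``perturbation`` (the Fourier amplitude scale; 0 gives
    circles).  The nucleus is a smaller blob at a jittered interior point,
    resampled (shrinking) until strictly inside the cell with area between
    10% and 50% of the cell area.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E11]))
    cells: list[SyntheticCell] = []
    base_mean_radius = np.sqrt(mean_area / np.pi)
    for _ in range(n):
        for _attempt in range(max_retries):
            area = mean_area * rng.lognormal(-0.5 * area_sigma**2, area_sigma)
            radius = np.sqrt(area / np.pi)
            cell = _star_blob(rng, np.zeros(2), radius, perturbation)
            if not (cell.is_valid and cell.area > 0):
                continue
            nuc = _fit_nucleus(rng, cell)
            if nuc is not None:
                break
        else:  # pragma: no cover - bounded-retry safety net
            raise RuntimeError("failed to generate a valid cell after retries")
        cells.append(SyntheticCell(cell=cell, nucleus=nuc, area_scale=cell.area / mean_area))
    del base_mean_radius
    return cells


def _fit_nucleus(rng: np.random.Generator, cell: Polygon) -> Polygon | None:
    """Place a nucleus blob strictly inside the cell (10-50% of its area)."""
    r_eq = np.sqrt(cell.area / np.pi)
    cx, cy = cell.centroid.x, cell.centroid.y
    center = np.array([cx, cy]) + rng.normal(0, 0.1 * r_eq, 2)
    frac = rng.uniform(0.42, 0.62)  # nucleus radius fraction -> area ~18-38%
    for _ in range(12):
        nuc = _star_blob(rng, center, frac * r_eq, 0.08, n_vertices=32)
        if (
            nuc.is_valid
            and cell.contains(nuc)
            and 0.10 * cell.area <= nuc.area <= 0.50 * cell.area
        ):
            return nuc
        frac *= 0.92
        center = 0.8 * center + 0.2 * np.array([cx, cy])
    return None


def sample_abundance(level: int, cell: SyntheticCell, rng: np.random.Generator) -> int:
    """Poisson(level x area_scale) molecule count clamped to [5, 300]."""
    if level not in ABUNDANCE_LEVELS:
        raise ValueError(f"abundance level must be one of {ABUNDANCE_LEVELS}")
    draw = int(rng.poisson(level * cell.area_scale))
    return int(np.clip(draw, COUNT_MIN, COUNT_MAX))


def _uniform_in(polygon: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon (CSR)."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(64, int(2.0 * (n - len(out)) * (maxx - minx) * (maxy - miny) / polygon.area))
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.intersects_xy(polygon, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


@dataclass
class _CellSamplers:
    """Vectorized accept/distance closures for one cell, star-ring fast path
    with a shapely fallback for arbitrary polygons."""

    in_cell: object
    in_nucleus: object
    d_cell: object
    d_nucleus: object


def _samplers(cell: SyntheticCell) -> _CellSamplers:
    cache = cell.__dict__.get("_sampler_cache")
    if cache is not None:
        return cache
    cell_ring = StarRing(np.asarray(cell.cell.exterior.coords)[:-1])
    nuc_ring = StarRing(np.asarray(cell.nucleus.exterior.coords)[:-1])
    if cell_ring.radial_ok and nuc_ring.radial_ok:
        s = _CellSamplers(
            cell_ring.contains, nuc_ring.contains, cell_ring.distance, nuc_ring.distance
        )
    else:
        cell_poly, nuc_poly = cell.cell, cell.nucleus
        s = _CellSamplers(
            lambda p: shapely.intersects_xy(cell_poly, p[:, 0], p[:, 1]),
            lambda p: shapely.intersects_xy(nuc_poly, p[:, 0], p[:, 1]),
            lambda p: shapely.distance(shapely.points(p), cell_poly.exterior),
            lambda p: shapely.distance(shapely.points(p), nuc_poly.exterior),
        )
    cell.__dict__["_sampler_cache"] = s
    return s


def _rejection(
    bounds: tuple[float, float, float, float],
    n: int,
    rng: np.random.Generator,
    accept,
    batch: int,
) -> np.ndarray:
    """Generic batched rejection sampler; ``accept(cand, rng) -> bool mask``."""
    minx, miny, maxx, maxy = bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(batch, 4 * (n - len(out)))
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        out = np.vstack([out, cand[accept(cand, rng)]])
    return out[:n]


def _sample_pattern_points(
    cell: SyntheticCell,
    geo: _CellSamplers,
    label: str,
    n: int,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` points from the pure (unmixed) pattern density of a class."""
    if n == 0 or label == "none":
        return np.empty((0, 2))
    bounds = cell.cell.bounds
    if label == "nuclear":
        return _rejection(cell.nucleus.bounds, n, rng, lambda p, _: geo.in_nucleus(p), 64)
    if label == "cytoplasmic":
        if cell.cell.area - cell.nucleus.area <= 0:
            raise ValueError("cell has no cytoplasm (nucleus covers the cell)")
        return _rejection(
            bounds, n, rng, lambda p, _: geo.in_cell(p) & ~geo.in_nucleus(p), 64
        )
    d_fn = geo.d_nucleus if label == "nuclear_edge" else geo.d_cell

    def accept(p, r):
        keep = geo.in_cell(p)
        keep[keep] &= r.random(int(keep.sum())) < np.exp(-d_fn(p[keep]) / tau)
        return keep

    return _rejection(bounds, n, rng, accept, max(256, 12 * n))


def simulate_pattern(
    cell: SyntheticCell,
    label: str,
    strength: str,
    count: int,
    seed: int,
    tau_fraction: float = 0.05,
    strength_weights: dict[str, float] | None = None,
    abundance_level: int = 0,
) -> SimSample:
    """Draw ``count`` molecules from the class-specific mixture density.

    With probability w (the strength's mixture weight) a molecule follows
    the pattern density, otherwise CSR over the whole cell:

    * none          - CSR (the mixture is CSR regardless of w)
    * nuclear       - uniform over the nucleus
    * cytoplasmic   - uniform over cell minus nucleus
    * nuclear_edge  - exp(-d/tau) kernel on distance to the nuclear boundary
    * cell_edge     - exp(-d/tau) kernel on distance to the cell boundary

    tau = ``tau_fraction`` x cell equivalent radius.  Deterministic per seed.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    if strength not in STRENGTHS:
        raise ValueError(f"strength must be one of {STRENGTHS}")
    if not (COUNT_MIN <= count <= COUNT_MAX):
        raise ValueError(f"count must lie in [{COUNT_MIN}, {COUNT_MAX}]")
    weights = dict(STRENGTH_WEIGHTS)
    if strength_weights:
        weights.update(strength_weights)
    w = weights[strength]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9A77]))
    tau = tau_fraction * cell.equivalent_radius
    geo = _samplers(cell)
    bounds = cell.cell.bounds

    n_pattern = int(rng.binomial(count, w)) if label != "none" else 0
    n_csr = count - n_pattern

    pattern_pts = _sample_pattern_points(cell, geo, label, n_pattern, tau, rng)
    csr_pts = _rejection(bounds, n_csr, rng, lambda p, _: geo.in_cell(p), 64)
    points = np.vstack([pattern_pts, csr_pts])
    # hard guarantee: every emitted point lies inside the cell polygon
    ok = shapely.intersects_xy(cell.cell, points[:, 0], points[:, 1])
    if not ok.all():  # float-epsilon stragglers from the fast path
        points = np.vstack([points[ok], _uniform_in(cell.cell, int((~ok).sum()), rng)])
    return SimSample(
        points=points,
        label=label,
        strength=strength,
        abundance_level=abundance_level,
        cell=cell,
        seed=int(seed),
    )


def make_segregated_dataset(
    n_cells: int = 10,
    molecules_per_cell: int = 600,
    seed: int = 0,
):
    """Benchmark dataset: two genes fully segregated left/right per cell.

    Molecules are CSR over each cell; those left of the cell centroid are
    gene "A", the rest gene "B".  Cells are translated apart so polygons
    never overlap.  Returns (dataset, midlines) where ``midlines`` maps
    cell_id to the absolute x coordinate of the split, the ground truth
    for domain-recovery benchmarks.
    """
    import pandas as pd
    import shapely.affinity as aff

    from .core import make_dataset

    cells = make_cells(n_cells, seed)
    points, shapes, midlines = [], [], {}
    for i, c in enumerate(cells):
        dx = i * 8.0 * c.equivalent_radius
        cx = c.cell.centroid.x
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB1, i]))
        csr = _uniform_in(c.cell, molecules_per_cell, rng)
        genes = np.where(csr[:, 0] < cx, "A", "B")
        for (x, y), g in zip(csr, genes):
            points.append({"x": x + dx, "y": y, "gene": g})
        cid = f"c{i:03d}"
        midlines[cid] = cx + dx
        shapes.append(
            {"cell_id": cid, "compartment": "cell", "geometry": aff.translate(c.cell, dx, 0)}
        )
        shapes.append(
            {
                "cell_id": cid,
                "compartment": "nucleus",
                "geometry": aff.translate(c.nucleus, dx, 0),
            }
        )
    return make_dataset(pd.DataFrame(points), pd.DataFrame(shapes)), midlines


def make_compartment_dataset(
    n_cells: int = 50,
    molecules_per_gene: int = 200,
    seed: int = 0,
    n_nuclear_genes: int = 1,
    n_cyto_genes: int = 1,
):
    """Benchmark dataset: gene sets confined to the nucleus vs the cytoplasm.

    Nuclear genes (NUC*) are uniform over the nucleus; cytoplasmic genes
    (CYT*) uniform over cell-minus-nucleus.  Ground truth for
    nuclear-domain recovery is each cell's nucleus polygon.
    """
    import pandas as pd
    import shapely.affinity as aff

    from .core import make_dataset

    cells = make_cells(n_cells, seed)
    points, shapes = [], []
    gene_names = [f"NUC{j}" for j in range(n_nuclear_genes)] + [
        f"CYT{j}" for j in range(n_cyto_genes)
    ]
    for i, c in enumerate(cells):
        dx = i * 8.0 * c.equivalent_radius
        for j, gene in enumerate(gene_names):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB2, i, j]))
            if gene.startswith("NUC"):
                xy = _uniform_in(c.nucleus, molecules_per_gene, rng)
            else:
                geo = _samplers(c)
                xy = _rejection(
                    c.cell.bounds,
                    molecules_per_gene,
                    rng,
                    lambda p, _: geo.in_cell(p) & ~geo.in_nucleus(p),
                    64,
                )
            for x, y in xy:
                points.append({"x": x + dx, "y": y, "gene": gene})
        cid = f"c{i:03d}"
        shapes.append(
            {"cell_id": cid, "compartment": "cell", "geometry": aff.translate(c.cell, dx, 0)}
        )
        shapes.append(
            {
                "cell_id": cid,
                "compartment": "nucleus",
                "geometry": aff.translate(c.nucleus, dx, 0),
            }
        )
    return make_dataset(pd.DataFrame(points), pd.DataFrame(shapes))


def build_training_set(
    per_class: int = 2000,
    seed: int = 0,
    n_cells: int = 300,
    test_fraction: float = 0.2,
    **pattern_kwargs,
) -> TrainingSet:
    """Simulate ``per_class`` samples for each of the five classes.

    Strengths and abundance levels cycle uniformly within each class; cells
    are drawn from a pool of ``n_cells`` generated morphologies (the pool
    plays the role of a segmented-cell shape catalog).  Returns the samples
    with a stratified 80/20 train/test index split, fully reproducible per
    seed (per-sample seeds are derived from the master seed by counter).
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    tau_fraction = pattern_kwargs.pop("tau_fraction", 0.05)
    weights = dict(STRENGTH_WEIGHTS)
    weights.update(pattern_kwargs.pop("strength_weights", None) or {})
    if pattern_kwargs:
        raise TypeError(f"unknown arguments {sorted(pattern_kwargs)}")

    cells = make_cells(n_cells, seed)
    master = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))

    # sample plan: label/strength/abundance cycled, cell and count drawn
    plan = []
    for label in LABELS:
        for i in range(per_class):
            strength = STRENGTHS[i % len(STRENGTHS)]
            level = ABUNDANCE_LEVELS[(i // len(STRENGTHS)) % len(ABUNDANCE_LEVELS)]
            ci = int(master.integers(len(cells)))
            count = sample_abundance(level, cells[ci], master)
            w = weights[strength] if label != "none" else 0.0
            n_pat = int(master.binomial(count, w))
            plan.append((label, strength, level, ci, count, n_pat))

    # pooled generation: one vectorized rejection run per (cell, label) group
    # and per cell for the CSR component, then partitioned among samples
    pattern_parts: dict[int, np.ndarray] = {}
    csr_parts: dict[int, np.ndarray] = {}
    by_group: dict[tuple[int, str], list[int]] = {}
    by_cell: dict[int, list[int]] = {}
    for si, (label, _s, _l, ci, count, n_pat) in enumerate(plan):
        by_group.setdefault((ci, label), []).append(si)
        by_cell.setdefault(ci, []).append(si)

    for (ci, label), sis in sorted(by_group.items()):
        cell = cells[ci]
        geo = _samplers(cell)
        tau = tau_fraction * cell.equivalent_radius
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0xA001, ci, LABELS.index(label)])
        )
        sizes = [plan[si][5] for si in sis]
        pool = _sample_pattern_points(cell, geo, label, int(np.sum(sizes)), tau, rng)
        for si, lo, hi in zip(sis, np.cumsum([0] + sizes[:-1]), np.cumsum(sizes)):
            pattern_parts[si] = pool[lo:hi]

    for ci, sis in sorted(by_cell.items()):
        cell = cells[ci]
        geo = _samplers(cell)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA002, ci]))
        sizes = [plan[si][4] - plan[si][5] for si in sis]
        pool = _rejection(
            cell.cell.bounds, int(np.sum(sizes)), rng, lambda p, _: geo.in_cell(p), 64
        )
        # hard guarantee on the pooled fast path (see simulate_pattern)
        ok = shapely.intersects_xy(cell.cell, pool[:, 0], pool[:, 1])
        if not ok.all():  # pragma: no cover - float-epsilon stragglers
            pool = np.vstack([pool[ok], _uniform_in(cell.cell, int((~ok).sum()), rng)])
        for si, lo, hi in zip(sis, np.cumsum([0] + sizes[:-1]), np.cumsum(sizes)):
            csr_parts[si] = pool[lo:hi]

    samples = [
        SimSample(
            points=np.vstack([pattern_parts[si], csr_parts[si]]),
            label=label,
            strength=strength,
            abundance_level=level,
            cell=cells[ci],
            seed=int(seed),
        )
        for si, (label, strength, level, ci, _count, _np) in enumerate(plan)
    ]

    labels = np.array([s.label for s in samples])
    train_idx, test_idx = [], []
    split_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B11]))
    for label in LABELS:
        idx = np.flatnonzero(labels == label)
        idx = split_rng.permutation(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return TrainingSet(
        samples=samples,
        train_idx=np.sort(np.concatenate(train_idx)),
        test_idx=np.sort(np.concatenate(test_idx)),
        seed=int(seed),
    )
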