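"""Shared fixtures: small synthetic datasets built from the simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import shapely.affinity as aff
from shapely.geometry import Polygon

from subcell import core, simulate as sim


@pytest.fixture(scope="session")
def cell_pool():
    """A reusable pool of generated cell/nucleus shapes."""
    return sim.make_cells(10, seed=42)


@pytest.fixture()
def square_shapes():
    """One 10x10 cell with a 4x4 nucleus."""
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c1"],
            "compartment": ["cell", "nucleus"],
            "geometry": [
                Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
                Polygon([(3, 3), (7, 3), (7, 7), (3, 7)]),
            ],
        }
    )


def build_two_gene_dataset(
    n_cells: int = 4, count: int = 150, seed: int = 7, strength: str = "strong"
) -> core.CellDataset:
    """Cells with a nucleus-patterned gene NUC1 and a cytoplasmic gene CYT1,
    translated apart so cell polygons never overlap."""
    cells = sim.make_cells(n_cells, seed)
    points, shapes = [], []
    for i, c in enumerate(cells):
        dx = i * 400.0
        for gene, label, s_off in (("NUC1", "nuclear", 0), ("CYT1", "cytoplasmic", 1000)):
            pts = sim.simulate_pattern(c, label, strength, count, seed=seed * 100 + i + s_off)
            for x, y in pts.points:
                points.append({"x": x + dx, "y": y, "gene": gene})
        shapes.append(
            {"cell_id": f"c{i}", "compartment": "cell", "geometry": aff.translate(c.cell, dx, 0)}
        )
        shapes.append(
            {
                "cell_id": f"c{i}",
                "compartment": "nucleus",
                "geometry": aff.translate(c.nucleus, dx, 0),
            }
        )
    return core.make_dataset(pd.DataFrame(points), pd.DataFrame(shapes))


@pytest.fixture(scope="session")
def two_gene_dataset():
    return build_two_gene_dataset()


@pytest.fixture(scope="session")
def small_training_set():
    """A small but complete labeled simulation (5 classes x 150)."""
    return sim.build_training_set(per_class=150, seed=0, n_cells=40)


def random_convex_polygon(rng: np.random.Generator, n_vertices: int = 8) -> Polygon:
    """Convex hull of random points — oracle geometry for containment tests."""
    pts = rng.uniform(-1, 1, size=(n_vertices * 3, 2))
    from scipy.spatial import ConvexHull

    hull = ConvexHull(pts)
    return Polygon(pts[hull.vertices])
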