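"""Core data layer: ingestion, point-polygon linkage, counts, QC, filters."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from subcell import core, io
from subcell.core import (
    EmptyResultError,
    GeometryError,
    SchemaError,
    assign_points,
    count_matrix,
    filter_dataset,
    shape_stats,
)

from conftest import build_two_gene_dataset, random_convex_polygon


class TestLoadPoints:
    def test_plain_csv_roundtrip(self, tmp_path):
        path = tmp_path / "pts.csv"
        pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [4.0, 5.0, 6.0], "gene": list("abc")}).to_csv(
            path, index=False
        )
        table = io.load_points(path)
        assert len(table) == 3
        assert (table["compartment"] == "unassigned").all()
        assert list(table["gene"]) == ["a", "b", "c"]

    def test_column_map_is_identity_on_values(self, tmp_path):
        plain = tmp_path / "plain.csv"
        mapped = tmp_path / "mapped.csv"
        frame = pd.DataFrame({"x": [1.0], "y": [2.0], "gene": ["g"]})
        frame.to_csv(plain, index=False)
        frame.rename(columns={"gene": "feature_name"}).to_csv(mapped, index=False)
        a = io.load_points(plain)
        b = io.load_points(mapped, column_map={"gene": "feature_name"})
        pd.testing.assert_frame_equal(a, b)

    def test_nan_coordinate_names_offending_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"x": [1.0, np.nan, 3.0], "y": [0.0, 0.0, 0.0], "gene": list("abc")}).to_csv(
            path, index=False
        )
        with pytest.raises(SchemaError, match="row 1"):
            io.load_points(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "noy.csv"
        pd.DataFrame({"x": [1.0], "gene": ["a"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            io.load_points(path)

    def test_z_column_dropped_with_warning(self, tmp_path):
        path = tmp_path / "z.csv"
        pd.DataFrame({"x": [1.0], "y": [2.0], "z": [3.0], "gene": ["a"]}).to_csv(path, index=False)
        with pytest.warns(UserWarning, match="2D"):
            table = io.load_points(path)
        assert "z" not in table.columns


class TestLoadShapes:
    def test_geojson_unit_square(self, tmp_path):
        path = tmp_path / "s.geojson"
        path.write_text(
            """{"type": "FeatureCollection", "features": [{"type": "Feature",
            "properties": {"cell_id": "c1", "compartment": "cell"},
            "geometry": {"type": "Polygon", "coordinates": [[[0,0],[1,0],[1,1],[0,1],[0,0]]]}}]}"""
        )
        shapes = io.load_shapes(path)
        assert len(shapes) == 1
        assert shapes["geometry"].iloc[0].area == pytest.approx(1.0)

    def test_cell_with_nucleus(self, square_shapes, tmp_path):
        path = tmp_path / "s.geojson"
        io.save_shapes(square_shapes, path)
        shapes = io.load_shapes(path)
        assert len(shapes) == 2
        nuc = shapes[shapes["compartment"] == "nucleus"]["geometry"].iloc[0]
        assert nuc.area == pytest.approx(16.0)

    def test_bowtie_polygon_rejected(self, tmp_path):
        path = tmp_path / "bow.csv"
        pd.DataFrame(
            {
                "cell_id": ["c1"],
                "compartment": ["cell"],
                "wkt": ["POLYGON ((0 0, 1 1, 1 0, 0 1, 0 0))"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(GeometryError):
            io.load_shapes(path)

    def test_wkt_table_roundtrip(self, tmp_path):
        path = tmp_path / "s.tsv"
        pd.DataFrame(
            {
                "cell_id": ["c1"],
                "compartment": ["cell"],
                "wkt": ["POLYGON ((0 0, 2 0, 2 2, 0 2, 0 0))"],
            }
        ).to_csv(path, sep="\t", index=False)
        shapes = io.load_shapes(path)
        assert shapes["geometry"].iloc[0].area == pytest.approx(4.0)


class TestAssignPoints:
    @pytest.mark.parametrize(
        "xy,cell,comp",
        [
            ((5.0, 5.0), "c1", "nucleus"),
            ((1.0, 1.0), "c1", "cytoplasm"),
            ((20.0, 20.0), "unassigned", "unassigned"),
            ((0.0, 0.0), "c1", "cytoplasm"),  # cell boundary counts as inside
            ((3.0, 3.0), "c1", "nucleus"),  # nucleus boundary counts as inside
        ],
    )
    def test_single_points(self, square_shapes, xy, cell, comp):
        pts = pd.DataFrame({"x": [xy[0]], "y": [xy[1]], "gene": ["g"]})
        out = assign_points(pts, square_shapes)
        assert out["cell_id"].iloc[0] == cell
        assert out["compartment"].iloc[0] == comp

    def test_overlap_smallest_area_wins_with_warning(self):
        shapes = pd.DataFrame(
            {
                "cell_id": ["big", "small"],
                "compartment": ["cell", "cell"],
                "geometry": [
                    Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
                    Polygon([(2, 2), (6, 2), (6, 6), (2, 6)]),
                ],
            }
        )
        pts = pd.DataFrame({"x": [4.0], "y": [4.0], "gene": ["g"]})
        with pytest.warns(UserWarning, match="overlap"):
            out = assign_points(pts, shapes)
        assert out["cell_id"].iloc[0] == "small"

    def test_matches_ray_casting_oracle_on_convex_polygons(self):
        def ray_cast_inside(px, py, poly: Polygon) -> bool:
            # even-odd rule; boundary handled separately via segment distance
            verts = list(poly.exterior.coords)
            inside = False
            for (x1, y1), (x2, y2) in zip(verts[:-1], verts[1:]):
                seg = np.array([x2 - x1, y2 - y1])
                rel = np.array([px - x1, py - y1])
                cross = seg[0] * rel[1] - seg[1] * rel[0]
                dot = rel @ seg
                if abs(cross) < 1e-12 and -1e-12 <= dot <= seg @ seg + 1e-12:
                    return True  # on boundary -> inside by convention
                if (y1 > py) != (y2 > py):
                    x_int = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
                    if px < x_int:
                        inside = not inside
            return inside

        rng = np.random.default_rng(11)
        for _ in range(10):
            poly = random_convex_polygon(rng)
            pts = rng.uniform(-1.2, 1.2, size=(100, 2))
            expected = np.array([ray_cast_inside(x, y, poly) for x, y in pts])
            got = core.points_in_polygon(pts[:, 0], pts[:, 1], poly)
            assert np.array_equal(got, expected)


class TestCounts:
    def test_two_genes_one_cell(self, square_shapes):
        pts = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 20.0], "y": [1.0, 2.0, 3.0, 20.0], "gene": ["a", "a", "a", "b"]}
        )
        out = assign_points(pts, square_shapes)
        mat = count_matrix(out)
        assert mat.loc["a", "c1"] == 3
        assert "b" not in mat.index  # unassigned molecules are not counted

    def test_total_equals_assigned_points(self, two_gene_dataset):
        assigned = two_gene_dataset.points[two_gene_dataset.points["cell_id"] != "unassigned"]
        assert two_gene_dataset.counts.to_numpy().sum() == len(assigned)

    def test_mtx_roundtrip_exact(self, two_gene_dataset, tmp_path):
        io.save_counts_mtx(two_gene_dataset.counts, tmp_path)
        back = io.load_counts_mtx(tmp_path)
        pd.testing.assert_frame_equal(back, two_gene_dataset.counts, check_dtype=False)

    def test_point_row_permutation_invariance(self, square_shapes):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 10, 50),
                "y": rng.uniform(0, 10, 50),
                "gene": rng.choice(["a", "b"], 50),
            }
        )
        mat1 = count_matrix(assign_points(pts, square_shapes))
        shuffled = pts.sample(frac=1, random_state=1).reset_index(drop=True)
        mat2 = count_matrix(assign_points(shuffled, square_shapes))
        pd.testing.assert_frame_equal(mat1, mat2)


class TestShapeStats:
    def test_unit_square_geometry(self):
        shapes = pd.DataFrame(
            {
                "cell_id": ["c1"],
                "compartment": ["cell"],
                "geometry": [Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])],
            }
        )
        pts = pd.DataFrame({"x": [0.5], "y": [0.5], "gene": ["g"]})
        ds = core.make_dataset(pts, shapes)
        row = shape_stats(ds).loc["c1"]
        assert row["cell_area"] == pytest.approx(1.0)
        assert row["cell_perimeter"] == pytest.approx(4.0)
        assert row["equivalent_radius"] == pytest.approx(1 / np.sqrt(np.pi), abs=1e-9)
        assert row["aspect_ratio"] == pytest.approx(1.0)
        assert np.isnan(row["nucleus_area"])

    def test_density(self, square_shapes):
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 10, 50), "y": rng.uniform(0, 10, 50), "gene": ["g"] * 50}
        )
        ds = core.make_dataset(pts, square_shapes)
        row = shape_stats(ds).loc["c1"]
        assert row["molecule_density"] == pytest.approx(50 / 100.0)


class TestFilter:
    def _dataset(self):
        shapes = pd.DataFrame(
            {
                "cell_id": ["c1", "c1", "c2"],
                "compartment": ["cell", "nucleus", "cell"],
                "geometry": [
                    Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]),
                    Polygon([(3, 3), (7, 3), (7, 7), (3, 7)]),
                    Polygon([(20, 0), (30, 0), (30, 10), (20, 10)]),
                ],
            }
        )
        rows = []
        for i in range(12):  # gene 'hi' has 12 in c1
            rows.append({"x": 1 + 0.1 * i, "y": 1.0, "gene": "hi"})
        for i in range(3):  # and 3 in c2
            rows.append({"x": 21 + 0.1 * i, "y": 1.0, "gene": "hi"})
        for i in range(9):  # gene 'lo' peaks at 9 < 10
            rows.append({"x": 2 + 0.1 * i, "y": 2.0, "gene": "lo"})
        return core.make_dataset(pd.DataFrame(rows), shapes)

    def test_max_count_rule_and_nucleus_rule(self):
        ds = self._dataset()
        out = filter_dataset(ds, min_gene_count=10, require_nucleus=True)
        assert list(out.counts.index) == ["hi"]  # max count {12, 3} >= 10 kept, 9 dropped
        assert out.cell_ids == ["c1"]  # c2 lacks a nucleus

    def test_idempotent(self):
        ds = self._dataset()
        once = filter_dataset(ds, min_gene_count=10, require_nucleus=True)
        twice = filter_dataset(once, min_gene_count=10, require_nucleus=True)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        pd.testing.assert_frame_equal(
            once.points.reset_index(drop=True), twice.points.reset_index(drop=True)
        )

    def test_all_genes_filtered_raises(self):
        ds = self._dataset()
        with pytest.raises(EmptyResultError):
            filter_dataset(ds, min_gene_count=1000)


def test_dataset_bundle_roundtrip(tmp_path):
    ds = build_two_gene_dataset(n_cells=2, count=30)
    io.save_dataset(ds, tmp_path / "bundle")
    back = io.load_dataset(tmp_path / "bundle")
    pd.testing.assert_frame_equal(back.counts, ds.counts, check_dtype=False)
    assert len(back.points) == len(ds.points)
    assert set(back.cell_ids) == set(ds.cell_ids)
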