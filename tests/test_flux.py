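"""Pixel-grid composition embeddings, SVD reduction, and SOM fluxmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

from subcell import core, flux
from subcell._som import SOM1D

from conftest import build_two_gene_dataset


def square_cell_shapes(side=100.0, nucleus=None):
    rows = [
        {
            "cell_id": "c1",
            "compartment": "cell",
            "geometry": Polygon([(0, 0), (side, 0), (side, side), (0, side)]),
        }
    ]
    if nucleus is not None:
        rows.append({"cell_id": "c1", "compartment": "nucleus", "geometry": nucleus})
    return pd.DataFrame(rows)


class TestMakeGrid:
    @pytest.mark.parametrize(
        "side,step,expected",
        [(1.0, 0.5, 9), (100.0, 10.0, 121), (1.0, 1.0, 4)],
    )
    def test_query_counts_on_squares(self, side, step, expected):
        grid = flux.make_grid(square_cell_shapes(side), step)
        assert len(grid.table) == expected

    def test_no_query_outside_nonconvex_cell(self):
        ell = Polygon([(0, 0), (30, 0), (30, 10), (10, 10), (10, 30), (0, 30)])
        shapes = pd.DataFrame(
            {"cell_id": ["c1"], "compartment": ["cell"], "geometry": [ell]}
        )
        grid = flux.make_grid(shapes, 4.0)
        pts = grid.table[["x", "y"]].to_numpy()
        assert shapely.intersects_xy(ell, pts[:, 0], pts[:, 1]).all()

    def test_tiny_cell_gets_centroid_query(self):
        grid = flux.make_grid(square_cell_shapes(1.0), step=50.0)
        assert len(grid.table) >= 1

    def test_grid_spacing_is_exact(self):
        grid = flux.make_grid(square_cell_shapes(100.0), 10.0)
        xs = np.sort(grid.table["x"].unique())
        assert np.allclose(np.diff(xs), 10.0)


class TestLocalComposition:
    def test_simple_fractions(self):
        pts = pd.DataFrame(
            {"x": [0.0, 1.0, -1.0, 0.0, 50.0], "y": [0.0] * 5, "gene": ["a", "a", "a", "b", "b"]}
        )
        v, empty = flux.local_composition(pts, np.array([[0.0, 0.0]]), radius=2.0, genes=["a", "b"])
        assert not empty[0]
        np.testing.assert_allclose(v[0], [0.75, 0.25])

    def test_empty_neighborhood_flagged_not_nan(self):
        pts = pd.DataFrame({"x": [100.0], "y": [100.0], "gene": ["a"]})
        v, empty = flux.local_composition(pts, np.array([[0.0, 0.0]]), radius=5.0, genes=["a"])
        assert empty[0]
        assert np.isfinite(v).all()

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 50, 500),
                "y": rng.uniform(0, 50, 500),
                "gene": rng.choice(["a", "b", "c"], 500),
            }
        )
        queries = rng.uniform(0, 50, size=(20, 2))
        v, empty = flux.local_composition(pts, queries, radius=7.0, genes=["a", "b", "c"])
        xy = pts[["x", "y"]].to_numpy()
        for qi, q in enumerate(queries):
            d = np.hypot(*(xy - q).T)
            near = pts[d <= 7.0]
            if len(near) == 0:
                assert empty[qi]
                continue
            expected = near["gene"].value_counts(normalize=True).reindex(
                ["a", "b", "c"], fill_value=0.0
            )
            np.testing.assert_allclose(v[qi], expected.to_numpy())


class TestFluxEmbed:
    def test_single_gene_embedding_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 100, 400), "y": rng.uniform(0, 100, 400), "gene": ["g"] * 400}
        )
        ds = core.make_dataset(pts, square_cell_shapes())
        emb = flux.flux_embed(ds, step=10, radius=30)
        assert np.array_equal(emb.embedding[~emb.empty], np.zeros_like(emb.embedding[~emb.empty]))

    def test_mixed_genes_give_small_embedding(self):
        """Two well-mixed CSR genes: deviations stay within the CSR envelope."""
        rng = np.random.default_rng(2)
        n = 2000
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n),
                "gene": rng.choice(["a", "b"], n),
            }
        )
        ds = core.make_dataset(pts, square_cell_shapes())
        emb = flux.flux_embed(ds, step=10, radius=30)
        # sigma-normalized deviations should look standard-normal-ish
        assert np.abs(emb.embedding[~emb.empty]).mean() < 2.0

    def test_segregated_genes_separate_by_sign(self):
        rng = np.random.default_rng(3)
        xa = rng.uniform(0, 45, size=(500, 2)) * [1, 100 / 45]
        xb = rng.uniform(0, 45, size=(500, 2)) * [1, 100 / 45] + [55, 0]
        pts = pd.DataFrame(
            {
                "x": np.r_[xa[:, 0], xb[:, 0]],
                "y": np.r_[xa[:, 1], xb[:, 1]],
                "gene": ["a"] * 500 + ["b"] * 500,
            }
        )
        ds = core.make_dataset(pts, square_cell_shapes())
        emb = flux.flux_embed(ds, step=10, radius=20)
        gi = emb.genes.index("a")
        x = emb.grid.table["x"].to_numpy()
        valid = ~emb.empty
        left = valid & (x < 30)
        right = valid & (x > 70)
        assert (emb.embedding[left, gi] > 0).mean() > 0.95
        assert (emb.embedding[right, gi] < 0).mean() > 0.95

    def test_invariant_to_molecule_duplication(self, two_gene_dataset):
        emb1 = flux.flux_embed(two_gene_dataset, step=15, radius=30)
        doubled = core.CellDataset(
            points=pd.concat(
                [two_gene_dataset.points, two_gene_dataset.points], ignore_index=True
            ),
            shapes=two_gene_dataset.shapes,
        )
        emb2 = flux.flux_embed(doubled, step=15, radius=30)
        np.testing.assert_allclose(emb2.embedding, emb1.embedding, atol=1e-12)

    def test_sigma_scope_changes_scale_not_sign(self, two_gene_dataset):
        per_cell = flux.flux_embed(two_gene_dataset, step=15, radius=30, scope="per_cell")
        global_ = flux.flux_embed(two_gene_dataset, step=15, radius=30, scope="global")
        valid = ~per_cell.empty
        a = per_cell.embedding[valid]
        b = global_.embedding[valid]
        nonzero = (np.abs(a) > 1e-12) & (np.abs(b) > 1e-12)
        assert np.array_equal(np.sign(a[nonzero]), np.sign(b[nonzero]))

    def test_small_cells_skipped_with_warning(self):
        shapes = square_cell_shapes(5.0)
        pts = pd.DataFrame({"x": [2.0], "y": [2.0], "gene": ["g"]})
        ds = core.make_dataset(pts, shapes)
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning, match="skipped"):
                flux.flux_embed(ds, step=10, radius=30)


class TestReduce:
    def _embedding(self, mat):
        n, g = mat.shape
        genes = [f"g{i}" for i in range(g)]
        table = pd.DataFrame(
            {"cell_id": "c1", "x": np.arange(n, dtype=float), "y": 0.0}
        )
        return flux.FluxEmbedding(
            grid=flux.FluxGrid(table=table, step=1.0),
            genes=genes,
            v=mat,
            cell_composition=np.zeros_like(mat),
            sigma=np.ones_like(mat),
            embedding=mat,
            empty=np.zeros(n, dtype=bool),
            radius=1.0,
            scope="per_cell",
        )

    def test_rank2_matrix_has_two_informative_components(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(200, 2)) @ rng.normal(size=(2, 12))
        emb = self._embedding(mat)
        with pytest.warns(UserWarning):
            flux.reduce(emb, n_components=12)  # 12 requested, rank 2 available
        assert emb.explained_variance_ratio[:2].sum() > 1 - 1e-9

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(size=(50, 8))
        emb = self._embedding(mat)
        flux.reduce(emb, n_components=8)
        np.testing.assert_allclose(emb.reduced @ emb.components, mat, atol=1e-8)

    def test_query_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(size=(60, 5))
        perm = rng.permutation(60)
        a = self._embedding(mat)
        b = self._embedding(mat[perm])
        flux.reduce(a, 3)
        flux.reduce(b, 3)
        np.testing.assert_allclose(b.reduced, a.reduced[perm], atol=1e-9)

    def test_retains_ten_components_by_default(self, two_gene_dataset):
        # panel has 2 genes -> at most 2; build a wider synthetic matrix
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(300, 40))
        emb = self._embedding(mat)
        flux.reduce(emb)
        assert emb.reduced.shape[1] == 10
        assert emb.components.shape == (10, 40)


class TestSom:
    def test_two_blobs_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        a = rng.normal([0, 0], 0.3, size=(150, 2))
        b = rng.normal([5, 5], 0.3, size=(150, 2))
        x = np.vstack([a, b])
        truth = np.r_[np.zeros(150), np.ones(150)]
        som = SOM1D(2, seed=0).fit(x)
        labels = som.predict(x)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(100, 3))
        l1 = SOM1D(4, seed=1).fit(x).predict(x)
        l2 = SOM1D(4, seed=1).fit(x).predict(x)
        assert np.array_equal(l1, l2)

    def test_quantization_error_decreases_with_k(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(300, 4))
        errs = [SOM1D(k, seed=0, n_iter=3000).fit(x).quantization_error(x) for k in (2, 6, 12)]
        assert errs[0] > errs[-1]


class TestFluxmaps:
    def test_two_separated_blobs_select_k2_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(11)
        n = 200
        blob = np.r_[np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)]
        reduced = np.where(blob[:, None] == 0, -4.0, 4.0) + rng.normal(0, 0.3, size=(n, 3))
        table = pd.DataFrame({"cell_id": "c1", "x": np.arange(n, dtype=float), "y": 0.0})
        emb = flux.FluxEmbedding(
            grid=flux.FluxGrid(table=table, step=1.0),
            genes=["g0", "g1", "g2"],
            v=np.zeros((n, 3)),
            cell_composition=np.zeros((n, 3)),
            sigma=np.ones((n, 3)),
            embedding=np.zeros((n, 3)),
            empty=np.zeros(n, dtype=bool),
            radius=1.0,
            scope="per_cell",
            shapes=square_cell_shapes(),
        )
        emb.reduced = reduced
        result = flux.fit_fluxmaps(emb, k_range=range(2, 7), seed=0, n_iter=3000)
        assert result.k == 2
        assert adjusted_rand_score(blob, result.labels) > 0.9

    def test_same_seed_identical_labels(self, two_gene_dataset):
        emb = flux.flux_embed(two_gene_dataset, step=12, radius=30)
        flux.reduce(emb)
        r1 = flux.fit_fluxmaps(emb, k_range=range(2, 5), seed=0, n_iter=2000)
        r2 = flux.fit_fluxmaps(emb, k_range=range(2, 5), seed=0, n_iter=2000)
        assert np.array_equal(r1.labels, r2.labels)

    def test_canonical_domain_one_is_most_nuclear(self, two_gene_dataset):
        emb = flux.flux_embed(two_gene_dataset, step=10, radius=30)
        flux.reduce(emb)
        result = flux.fit_fluxmaps(emb, k_range=range(2, 3), seed=0, n_iter=3000)
        table = emb.grid.table
        nuc_frac = {}
        for d in np.unique(result.labels):
            rows = table[result.labels == d]
            inside = []
            for cell_id, sub in rows.groupby("cell_id"):
                nuc = two_gene_dataset.nucleus_polygon(cell_id)
                pts = sub[["x", "y"]].to_numpy()
                inside.append(shapely.intersects_xy(nuc, pts[:, 0], pts[:, 1]))
            nuc_frac[d] = np.concatenate(inside).mean()
        assert nuc_frac[1] == max(nuc_frac.values())


class TestDomainPolygonsAndRender:
    def test_single_domain_covers_cell(self):
        rng = np.random.default_rng(12)
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 100, 500), "y": rng.uniform(0, 100, 500), "gene": ["g"] * 500}
        )
        ds = core.make_dataset(pts, square_cell_shapes())
        emb = flux.flux_embed(ds, step=10, radius=30)
        flux.reduce(emb)
        labels = np.ones(len(emb.grid.table), dtype=int)
        result = flux.FluxmapResult(
            labels=labels, k=1, quantization_curve=pd.DataFrame(), som=None
        )
        polys = flux.domain_polygons(result, emb)
        cell_area = 100.0 * 100.0
        assert polys["area"].sum() == pytest.approx(cell_area, rel=0.15)

    def test_split_labels_partition_cell(self, two_gene_dataset):
        emb = flux.flux_embed(two_gene_dataset, step=10, radius=30)
        flux.reduce(emb)
        result = flux.fit_fluxmaps(emb, k_range=range(2, 3), seed=0, n_iter=2000)
        polys = flux.domain_polygons(result, emb)
        for cell_id, sub in polys.groupby("cell_id"):
            cell_area = two_gene_dataset.cell_polygon(cell_id).area
            # tiles cover the cell up to a one-tile boundary band
            assert sub["area"].sum() <= cell_area + 1e-6
            assert sub["area"].sum() >= 0.5 * cell_area

    def test_area_tracks_label_counts(self, two_gene_dataset):
        emb = flux.flux_embed(two_gene_dataset, step=10, radius=30)
        flux.reduce(emb)
        result = flux.fit_fluxmaps(emb, k_range=range(2, 3), seed=0, n_iter=2000)
        polys = flux.domain_polygons(result, emb)
        step2 = emb.grid.step**2
        for cell_id, sub in polys.groupby("cell_id"):
            rows = emb.grid.table["cell_id"] == cell_id
            for _, rec in sub.iterrows():
                n_tiles = ((result.labels == rec["domain"]) & rows.to_numpy()).sum()
                assert rec["area"] <= n_tiles * step2 + 1e-9

    def test_render_quantile_scaling(self, two_gene_dataset):
        emb = flux.flux_embed(two_gene_dataset, step=10, radius=30)
        flux.reduce(emb)
        # constant third component -> channel 0.5 everywhere
        emb.reduced = np.column_stack(
            [emb.reduced[:, 0], emb.reduced[:, 1] if emb.reduced.shape[1] > 1 else emb.reduced[:, 0], np.ones(len(emb.reduced))]
        )
        img = flux.render_rgb(emb, resolution=5.0)
        assert img.shape[2] == 4
        inside = img[:, :, 3] > 0
        assert inside.any()
        # blue channel (constant component) is 0.5 wherever defined
        np.testing.assert_allclose(img[inside, 2], 0.5, atol=1e-9)
        # non-constant channels span [0.1, 0.9] at the extreme queries
        assert img[inside, 0].min() >= 0.1 - 1e-9
        assert img[inside, 0].max() <= 0.9 + 1e-9

    def test_embedding_bundle_roundtrip(self, two_gene_dataset, tmp_path):
        emb = flux.flux_embed(two_gene_dataset, step=12, radius=30)
        flux.reduce(emb)
        flux.save_embedding(emb, tmp_path / "flux")
        back = flux.load_embedding(tmp_path / "flux")
        np.testing.assert_allclose(back.embedding, emb.embedding)
        np.testing.assert_allclose(back.reduced, emb.reduced)
        assert back.genes == emb.genes
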