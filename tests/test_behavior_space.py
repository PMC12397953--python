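import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from bplast.behavior_space import (
    EmbeddingModel,
    assign_clusters,
    cluster_field_from_points,
    density_map,
    embed_points,
    fit_embedding,
    kmeans_clusters,
    watershed_clusters,
    _grid_edges,
    _histogram,
)
from bplast.wavelets import FeatureMatrix


def _fm(X):
    T = len(X)
    idx = pd.DataFrame({"individual_id": "f1", "day_index": 1, "time_s": 0.2 * np.arange(T)})
    n_freq = X.shape[1] // 3
    return FeatureMatrix(X.astype(np.float32), idx, np.geomspace(0.01, 2.5, n_freq))


def _blobs(rng, centers, n_per, scale=0.5, dim=75):
    X = np.concatenate(
        [c + scale * rng.normal(size=(n_per, dim)) for c in centers]
    )
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y


class TestEmbedding:
    def test_separated_blobs_stay_separable(self):
        rng = np.random.default_rng(0)
        centers = [np.zeros(75), np.full(75, 6.0)]
        X, y = _blobs(rng, centers, 600)
        model = fit_embedding(_fm(X), sample_fraction=1.0, seed=1, n_neighbors=15)
        emb = embed_points(model, _fm(X))
        from sklearn.cluster import KMeans

        pred = KMeans(2, random_state=0, n_init=4).fit_predict(emb)
        agree = max((pred == y).mean(), (pred != y).mean())
        assert agree > 0.95

    def test_sample_fraction_one_uses_all_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1000, 75))
        model = fit_embedding(_fm(X), sample_fraction=1.0, seed=0, n_neighbors=10)
        assert len(model.templates) == 1000

    def test_same_seed_identical_embedding(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(800, 75))
        m1 = fit_embedding(_fm(X), 0.5, seed=5, n_neighbors=10)
        m2 = fit_embedding(_fm(X), 0.5, seed=5, n_neighbors=10)
        np.testing.assert_array_equal(m1.fit_indices, m2.fit_indices)
        np.testing.assert_array_equal(m1.template_embedding, m2.template_embedding)

    def test_too_small_sample_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 75))
        with pytest.raises(ValueError, match="n_neighbors"):
            fit_embedding(_fm(X), sample_fraction=1.0, seed=0, n_neighbors=50)


class TestEmbedPoints:
    def _model(self, rng, n=300):
        T = rng.normal(size=(n, 75)).astype(np.float32)
        emb = rng.normal(size=(n, 2)).astype(np.float32)
        return EmbeddingModel(T, emb, np.arange(n), seed=0)

    def test_fit_sample_reproduces_fit_coordinates(self):
        rng = np.random.default_rng(0)
        m = self._model(rng)
        out = embed_points(m, m.templates)
        np.testing.assert_allclose(out, m.template_embedding, atol=1e-5)

    def test_duplicated_rows_identical_outputs(self):
        rng = np.random.default_rng(1)
        m = self._model(rng)
        q = rng.normal(size=(1, 75)).astype(np.float32)
        out = embed_points(m, np.vstack([q, q]))
        np.testing.assert_array_equal(out[0], out[1])

    def test_batch_split_equals_whole(self):
        rng = np.random.default_rng(2)
        m = self._model(rng)
        Q = rng.normal(size=(5000, 75)).astype(np.float32)
        whole = embed_points(m, Q, batch_rows=5000)
        split = embed_points(m, Q, batch_rows=700)
        np.testing.assert_allclose(whole, split, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        m = self._model(rng)
        with pytest.raises(ValueError, match="dimension"):
            embed_points(m, rng.normal(size=(10, 40)).astype(np.float32))


class TestDensityMap:
    def test_single_point_gaussian_bump_mass_one(self):
        d = density_map(np.array([[0.3, -0.2]]), grid=64, sigma=3.0)
        np.testing.assert_allclose(d.density.sum(), 1.0, atol=1e-6)
        peak = np.unravel_index(d.density.argmax(), d.density.shape)
        # the single point sits mid-grid
        assert abs(peak[0] - 32) <= 1 and abs(peak[1] - 32) <= 1

    def test_two_identical_points_double_density(self):
        p = np.array([[1.0, 2.0]])
        d1 = density_map(p, grid=32, sigma=2.0)
        d2 = density_map(np.vstack([p, p]), grid=32, sigma=2.0)
        np.testing.assert_allclose(d2.density, 2 * d1.density, atol=1e-12)

    def test_histogram_mass_equals_count(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(5000, 2))
        x_edges, y_edges = _grid_edges(pts, 128)
        H = _histogram(pts, x_edges, y_edges)
        assert H.sum() == 5000

    def test_large_sigma_flattens(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(size=(20000, 2))
        interior = (slice(40, 88), slice(40, 88))
        r_small = density_map(pts, 128, sigma=1.0).density[interior]
        r_large = density_map(pts, 128, sigma=30.0).density[interior]
        ratio = lambda a: a.max() / a.min()
        assert ratio(r_large) < ratio(r_small)
        assert ratio(r_large) < 1.5


def _mode_grid(rng, n_modes, n_per=400, spread=0.02):
    """Well-separated 2-D Gaussian modes on a unit lattice."""
    side = int(np.ceil(np.sqrt(n_modes)))
    centers = np.array([[i % side, i // side] for i in range(n_modes)], float)
    pts = np.concatenate(
        [c + spread * rng.normal(size=(n_per, 2)) for c in centers]
    )
    return centers, pts


class TestWatershed:
    def test_two_modes_two_regions_each_containing_a_peak(self):
        rng = np.random.default_rng(0)
        centers, pts = _mode_grid(rng, 2)
        field = cluster_field_from_points(pts, 2, grid=128)
        labels = assign_clusters(centers, field)
        assert field.k == 2
        assert set(np.unique(field.labels)) == {1, 2}
        assert labels[0] != labels[1]

    def test_k1_rejected(self):
        rng = np.random.default_rng(1)
        _, pts = _mode_grid(rng, 2)
        with pytest.raises(ValueError, match="k_target"):
            cluster_field_from_points(pts, 1)

    def test_twenty_modes_peaks_in_distinct_regions(self):
        rng = np.random.default_rng(2)
        centers, pts = _mode_grid(rng, 20)
        field = cluster_field_from_points(pts, 20, grid=256)
        peak_labels = assign_clusters(centers, field)
        assert len(set(peak_labels.tolist())) == 20

    def test_every_cell_labeled_with_k_labels(self):
        rng = np.random.default_rng(3)
        _, pts = _mode_grid(rng, 6)
        field = cluster_field_from_points(pts, 6, grid=128)
        present = np.unique(field.labels)
        assert len(present) == 6 and present.min() == 1 and present.max() == 6

    def test_unreachable_k_reports_range(self):
        # a single tight blob can't produce 50 basins at any bandwidth
        rng = np.random.default_rng(4)
        pts = 0.01 * rng.normal(size=(500, 2))
        with pytest.raises(ValueError, match="achievable"):
            cluster_field_from_points(pts, 50, grid=64, sigma_range=(2.0, 16.0))


class TestAssign:
    def test_outside_point_snaps_to_border_cell(self):
        rng = np.random.default_rng(5)
        _, pts = _mode_grid(rng, 2)
        field = cluster_field_from_points(pts, 2, grid=64)
        far = np.array([[1e3, 1e3]])
        lab = assign_clusters(far, field)
        assert lab[0] in (1, 2)

    def test_full_assignment_hungarian_one_to_one(self):
        """Cluster labels of 20-mode data map one-to-one onto true modes."""
        rng = np.random.default_rng(6)
        n_modes, n_per = 20, 400
        centers, pts = _mode_grid(rng, n_modes, n_per)
        truth = np.repeat(np.arange(n_modes), n_per)
        field = cluster_field_from_points(pts, n_modes, grid=256)
        labels = assign_clusters(pts, field) - 1
        C = np.zeros((n_modes, n_modes))
        for t, l in zip(truth, labels):
            C[t, l] += 1
        row, col = linear_sum_assignment(-C)
        accuracy = C[row, col].sum() / len(truth)
        assert accuracy > 0.95


class TestKMeans:
    def test_two_blobs_pure(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng, [np.zeros(75), np.full(75, 8.0)], 200)
        lab = kmeans_clusters(_fm(X), 2, seed=0)
        assert set(lab) == {1, 2}
        purity = max((lab - 1 == y).mean(), (lab - 1 != y).mean())
        assert purity == 1.0

    def test_k_equals_rows(self):
        rng = np.random.default_rng(1)
        X = 10 * rng.normal(size=(8, 75))
        lab = kmeans_clusters(_fm(X), 8, seed=0)
        assert len(set(lab.tolist())) == 8

    def test_degenerate_rejected(self):
        X = np.ones((50, 75))
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_clusters(_fm(X), 3, seed=0)
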