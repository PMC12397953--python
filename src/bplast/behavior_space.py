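"""Discretizing the 75-dim behavioral phenotype space into k clusters.

The default route follows the unsupervised behavioral-mapping recipe:
embed the wavelet feature space into 2-D with UMAP (fit on a uniform
subsample, default 1/500 of rows), re-embed every frame, estimate a
Gaussian-smoothed data density on a regular grid, and run a watershed
transform on the inverse density so that density peaks become cluster
cores.  The smoothing bandwidth is searched so the watershed yields the
requested number of basins.  A k-means alternative clusters the raw
75-dim rows directly.

Bulk re-embedding uses inverse-distance-weighted k-nearest-neighbor
interpolation against the fit subsample in feature space (the standard
template re-embedding approach for behavioral maps); it is deterministic,
exactly reproduces the fit sample's coordinates, and scales to millions
of rows on one core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.cluster import KMeans, MiniBatchKMeans

from .wavelets import FeatureMatrix

__all__ = [
    "EmbeddingModel",
    "fit_embedding",
    "embed_points",
    "DensityGrid",
    "density_map",
    "ClusterField",
    "watershed_clusters",
    "assign_clusters",
    "kmeans_clusters",
]

log = logging.getLogger(__name__)

DEFAULT_SAMPLE_FRACTION = 1.0 / 500.0
DEFAULT_N_NEIGHBORS = 50
DEFAULT_MIN_DIST = 0.1
DEFAULT_GRID = 512
PAD_FRAC = 0.05


@dataclass
class EmbeddingModel:
    """A fitted 2-D embedding of the behavioral feature space.

    Stores the fit subsample (templates) and their embedded coordinates;
    new rows are embedded by kNN interpolation against the templates.
    """

    templates: np.ndarray          # (m, 75) float32, the fit subsample
    template_embedding: np.ndarray  # (m, 2) float32
    fit_indices: np.ndarray        # row indices into the pooled FeatureMatrix
    seed: int
    n_neighbors: int = DEFAULT_N_NEIGHBORS
    min_dist: float = DEFAULT_MIN_DIST

    def __post_init__(self):
        if len(self.templates) != len(self.template_embedding):
            raise ValueError("templates and embedding misaligned")


def fit_embedding(
    features: FeatureMatrix,
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION,
    seed: int = 0,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
) -> EmbeddingModel:
    """Fit UMAP on a uniform random subsample of the pooled feature rows.

    Fitting a neighborhood embedding on every frame of a month of 5 Hz
    tracking is unnecessary as well as infeasible; a 1/500 uniform
    subsample preserves the density structure of the space.  The seed
    controls both the subsample and the (single-threaded, reproducible)
    UMAP optimization.
    """
    import umap  # deferred: slow import

    X = features.values
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")
    n = X.shape[0]
    m = max(int(round(n * sample_fraction)), min(n, 10 * n_neighbors))
    if m > n:
        m = n
    if m <= n_neighbors:
        raise ValueError(
            f"fit sample of {m} rows is too small for n_neighbors={n_neighbors}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    sample = np.ascontiguousarray(X[idx], dtype=np.float32)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    emb = reducer.fit_transform(sample)
    return EmbeddingModel(
        templates=sample,
        template_embedding=np.asarray(emb, dtype=np.float32),
        fit_indices=idx,
        seed=seed,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
    )


def embed_points(
    model: EmbeddingModel,
    features: FeatureMatrix | np.ndarray,
    k: int = 5,
    batch_rows: int = 10_000,
) -> np.ndarray:
    """Embed feature rows as inverse-square-distance kNN template averages.

    A row coinciding with a template receives that template's coordinates
    exactly; other rows land at a convex combination of their k nearest
    templates' positions.  Neighbor scores come from a single augmented
    matrix product per (cache-sized) chunk, so batch-split and
    whole-matrix calls agree to float precision.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.shape[1] != model.templates.shape[1]:
        raise ValueError(
            f"expected rows of dimension {model.templates.shape[1]}, got {X.shape}"
        )
    X = X.astype(np.float32, copy=False)
    T = model.templates
    k = min(k, len(T))
    t_sq = np.einsum("ij,ij->i", T, T)
    # score g = q.t - ||t||^2/2 maximized by the nearest template;
    # d^2 = ||q||^2 - 2 g recovers the true squared distance.
    A = np.vstack([np.ascontiguousarray(T.T), -0.5 * t_sq[None, :]]).astype(np.float32)
    out = np.empty((X.shape[0], 2), dtype=np.float32)
    for i in range(0, X.shape[0], batch_rows):
        q = X[i : i + batch_rows]
        qa = np.concatenate([q, np.ones((len(q), 1), np.float32)], axis=1)
        g = qa @ A
        if k < g.shape[1]:
            nn = np.argpartition(-g, k - 1, axis=1)[:, :k]
        else:
            nn = np.broadcast_to(np.arange(k), (g.shape[0], k)).copy()
        q_sq = np.einsum("ij,ij->i", q, q)
        dd = np.maximum(q_sq[:, None] - 2.0 * np.take_along_axis(g, nn, axis=1), 0.0)
        w = 1.0 / np.maximum(dd, 1e-8)
        exact = dd.min(axis=1) < 1e-6
        w /= w.sum(axis=1, keepdims=True)
        coords = np.einsum("ij,ijk->ik", w, model.template_embedding[nn])
        if exact.any():
            best = nn[np.arange(len(nn)), np.argmin(dd, axis=1)]
            coords[exact] = model.template_embedding[best[exact]]
        out[i : i + batch_rows] = coords
    return out


@dataclass
class DensityGrid:
    """Gaussian-smoothed data density over the embedding bounding box."""

    density: np.ndarray  # (G, G), row i = y bin, col j = x bin
    x_edges: np.ndarray
    y_edges: np.ndarray
    sigma: float

    @property
    def grid_size(self) -> int:
        return self.density.shape[0]


def _grid_edges(embedded: np.ndarray, grid: int, pad_frac: float = PAD_FRAC):
    lo = embedded.min(axis=0).astype(float)
    hi = embedded.max(axis=0).astype(float)
    span = np.maximum(hi - lo, 1e-6)
    lo -= pad_frac * span
    hi += pad_frac * span
    return np.linspace(lo[0], hi[0], grid + 1), np.linspace(lo[1], hi[1], grid + 1)


def _histogram(embedded, x_edges, y_edges):
    H, _, _ = np.histogram2d(embedded[:, 1], embedded[:, 0], bins=[y_edges, x_edges])
    return H


def density_map(
    embedded: np.ndarray,
    grid: int = DEFAULT_GRID,
    sigma: float = 4.0,
    pad_frac: float = PAD_FRAC,
) -> DensityGrid:
    """2-D histogram over a padded bounding box, Gaussian-smoothed.

    ``sigma`` is in grid-cell units.  The raw histogram sums exactly to
    the number of points; smoothing uses nearest-mode boundaries so the
    mass stays on the grid.
    """
    embedded = np.asarray(embedded, dtype=float)
    if embedded.ndim != 2 or embedded.shape[1] != 2 or len(embedded) == 0:
        raise ValueError("embedded must be a non-empty (T, 2) array")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x_edges, y_edges = _grid_edges(embedded, grid, pad_frac)
    H = _histogram(embedded, x_edges, y_edges)
    smooth = gaussian_filter(H, sigma=sigma, mode="nearest")
    return DensityGrid(density=smooth, x_edges=x_edges, y_edges=y_edges, sigma=sigma)


@dataclass
class ClusterField:
    """Watershed (or other) labelling of the embedding grid, labels 1..k."""

    labels: np.ndarray  # (G, G) int, 1-based
    x_edges: np.ndarray
    y_edges: np.ndarray
    sigma: float
    k: int

    def __post_init__(self):
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")


def _watershed_once(H: np.ndarray, sigma: float):
    dens = gaussian_filter(H, sigma=sigma, mode="nearest")
    peaks = peak_local_max(dens, exclude_border=False, min_distance=1)
    markers = np.zeros_like(dens, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dens, markers=markers)
    return dens, labels, len(peaks)


def _merge_smallest(labels: np.ndarray, dens: np.ndarray, k_target: int) -> np.ndarray:
    """Merge smallest-area basins into the neighbor behind the densest ridge."""
    labels = labels.copy()
    while len(np.unique(labels)) > k_target:
        ids, counts = np.unique(labels, return_counts=True)
        smallest = ids[np.argmin(counts)]
        mask = labels == smallest
        # ridge cells: 4-neighborhood border of the basin
        border = np.zeros_like(mask)
        border[:-1] |= mask[1:]
        border[1:] |= mask[:-1]
        border[:, :-1] |= mask[:, 1:]
        border[:, 1:] |= mask[:, :-1]
        border &= ~mask
        neigh = labels[border]
        if neigh.size == 0:  # isolated; merge into global largest
            target = ids[np.argmax(counts + (ids == smallest) * -1)]
        else:
            ridge = dens[border]
            best = -np.inf
            target = None
            for nb in np.unique(neigh):
                h = ridge[neigh == nb].max()
                if h > best:
                    best, target = h, nb
        labels[mask] = target
    # relabel 1..k densely
    ids = np.unique(labels)
    remap = np.zeros(ids.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]


def watershed_clusters(
    hist: np.ndarray,
    k_target: int,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    sigma_range: tuple[float, float] = (0.5, 64.0),
    max_iter: int = 40,
) -> ClusterField:
    """Watershed on inverse smoothed density, tuned to exactly k basins.

    Larger smoothing bandwidths merge density modes and reduce the basin
    count, so the bandwidth is found by bisection on ``sigma``; if no
    bandwidth yields exactly ``k_target`` basins (the count is not
    strictly monotone), the smallest bandwidth giving at least ``k_target``
    is used and surplus basins are merged smallest-first into the neighbor
    across their densest shared ridge.  Every grid cell receives a label.
    """
    if k_target < 2:
        raise ValueError("k_target must be >= 2")
    H = np.asarray(hist, dtype=float)
    if H.min() < 0:
        raise ValueError("density histogram must be nonnegative")
    lo, hi = sigma_range
    dens_lo, labels_lo, n_lo = _watershed_once(H, lo)
    if n_lo < k_target:
        raise ValueError(
            f"cannot reach k={k_target}: at minimum bandwidth {lo} only "
            f"{n_lo} basins exist (achievable range is 1..{n_lo})"
        )
    _, _, n_hi = _watershed_once(H, hi)
    best = (lo, dens_lo, labels_lo, n_lo)
    for _ in range(max_iter):
        if best[3] == k_target:
            break
        mid = float(np.sqrt(lo * hi))
        dens, labels, n = _watershed_once(H, mid)
        if n >= k_target:
            lo = mid
            if n < best[3] or best[3] < k_target:
                best = (mid, dens, labels, n)
        else:
            hi = mid
        if hi / lo < 1.01:
            break
    sigma, dens, labels, n = best
    if n != k_target:
        log.info(
            "bandwidth search reached %d basins at sigma=%.3g; merging down to %d",
            n,
            sigma,
            k_target,
        )
        labels = _merge_smallest(labels, dens, k_target)
    return ClusterField(
        labels=labels.astype(np.int32), x_edges=x_edges, y_edges=y_edges, sigma=sigma, k=k_target
    )


def cluster_field_from_points(
    embedded: np.ndarray,
    k_target: int,
    grid: int = DEFAULT_GRID,
    pad_frac: float = PAD_FRAC,
    sigma_range: tuple[float, float] = (0.5, 64.0),
) -> ClusterField:
    """Convenience: histogram the embedding and watershed it to k clusters."""
    x_edges, y_edges = _grid_edges(np.asarray(embedded, float), grid, pad_frac)
    H = _histogram(np.asarray(embedded, float), x_edges, y_edges)
    return watershed_clusters(H, k_target, x_edges, y_edges, sigma_range=sigma_range)


def assign_clusters(embedded: np.ndarray, field: ClusterField) -> np.ndarray:
    """Label each embedded point by its containing grid cell (1..k).

    Points outside the padded bounding box are snapped to the nearest
    boundary cell and counted in the log.
    """
    embedded = np.asarray(embedded, dtype=float)
    G = field.labels.shape[0]
    ix = np.searchsorted(field.x_edges, embedded[:, 0], side="right") - 1
    iy = np.searchsorted(field.y_edges, embedded[:, 1], side="right") - 1
    outside = (ix < 0) | (ix >= G) | (iy < 0) | (iy >= G)
    if outside.any():
        log.info("%d points outside the embedding box snapped to the border", int(outside.sum()))
    ix = np.clip(ix, 0, G - 1)
    iy = np.clip(iy, 0, G - 1)
    return field.labels[iy, ix].astype(np.int32)


def kmeans_clusters(
    features: FeatureMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    minibatch_threshold: int = 200_000,
) -> np.ndarray:
    """k-means over the full 75-dim feature rows; labels 1..k.

    For row counts above ``minibatch_threshold`` the mini-batch variant is
    used so month-scale recordings stay tractable on one core.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    if np.all(X == X[0]):
        raise ValueError("degenerate feature matrix: all rows identical")
    if X.shape[0] > minibatch_threshold:
        km = MiniBatchKMeans(n_clusters=k, random_state=seed, n_init=3, batch_size=4096)
    else:
        km = KMeans(n_clusters=k, random_state=seed, n_init=4)
    return km.fit_predict(X).astype(np.int32) + 1
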