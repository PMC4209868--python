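"""Isomap shape spaces from depth-derivative features.

Canonical superquadric parameters have discontinuities: a tall box at an
angle slightly below +pi/4 renders almost identically to a wide box just
above -pi/4, yet their parameters differ greatly.  An Isomap embedding
of the depth-derivative features avoids this by placing shapes so that
graph-geodesic distances in feature space are preserved: similar depth
maps land close together regardless of how their superquadric
parameters read.

The pipeline is the classical one: a k-nearest-neighbor graph on
Euclidean feature distances, all-pairs shortest-path geodesics
(Dijkstra on the sparse graph), then classical MDS of the geodesic
distance matrix.  The feature space is the four derivative channels of
the depth maps (first and second, horizontal and vertical; 1024 values
per shape on the 16 x 16 grid), used in native units.

An out-of-sample transform (a Nystrom/landmark-style extension) gives
coordinates for held-out shapes, which the paper-scale pipeline needs
to produce network targets for validation shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist, pdist
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "IsomapEmbedding", "isomap_fit", "isomap_transform",
    "derivative_features", "distance_histograms",
]

DERIVATIVE_CHANNELS = slice(1, 5)  # dz/dx, dz/dy, d2z/dx2, d2z/dy2


def derivative_features(depth_values: np.ndarray) -> np.ndarray:
    """First+second derivative channels (horizontal and vertical) of a
    (N, n, n) depth-map stack, flattened to (N, n*n*4)."""
    from .features import derivative_stack

    rows = []
    for d in depth_values:
        ch = derivative_stack(d).channels[DERIVATIVE_CHANNELS]
        rows.append(np.transpose(ch, (1, 2, 0)).ravel())
    return np.stack(rows)


class DisconnectedGraphError(ValueError):
    """Raised when the k-NN graph splits into several components."""


@dataclass
class IsomapEmbedding:
    """A fitted Isomap: coordinates plus the graph/geodesic metadata
    needed for diagnostics and out-of-sample extension."""

    coordinates: np.ndarray      # (n, d), centered
    eigenvalues: np.ndarray      # (d,)
    eigenvectors: np.ndarray     # (n, d)
    geodesics: np.ndarray        # (n, n) training geodesic distances
    features: np.ndarray         # (n, p) training features
    k: int
    d: int
    residual_variance: float
    feature_space: str = "first+second derivatives, horizontal and vertical"
    nn_distances: np.ndarray = None  # training nearest-neighbor distances

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("coordinates", data=self.coordinates)
            f.create_dataset("eigenvalues", data=self.eigenvalues)
            f.attrs["k"] = self.k
            f.attrs["d"] = self.d
            f.attrs["residual_variance"] = self.residual_variance


def _residual_variance(D_geo: np.ndarray, coords: np.ndarray) -> float:
    dg = D_geo[np.triu_indices_from(D_geo, k=1)]
    de = pdist(coords)
    r = np.corrcoef(dg, de)[0, 1]
    return float(1.0 - r**2)


def isomap_fit(features: np.ndarray, k: int = 10, d: int = 8) -> IsomapEmbedding:
    """Fit an Isomap: k-NN graph -> geodesics -> classical MDS.

    Deterministic given the input order; the eigenvector sign convention
    (largest-magnitude entry positive) removes the reflection ambiguity.
    A disconnected neighborhood graph raises
    :class:`DisconnectedGraphError` naming the component sizes rather
    than silently growing k, so geodesics stay interpretable.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, idx = nbrs.kneighbors(X)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    W = csr_matrix((vals, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)

    ncomp, labels = connected_components(W, directed=False)
    if ncomp > 1:
        sizes = np.bincount(labels).tolist()
        raise DisconnectedGraphError(
            f"k-NN graph has {ncomp} components with sizes {sizes}; "
            "increase k explicitly if a coarser graph is acceptable"
        )

    D = shortest_path(W, method="D", directed=False)

    D2 = D**2
    mu_row = D2.mean(axis=1)
    B = -0.5 * (D2 - mu_row[:, None] - mu_row[None, :] + D2.mean())
    vals, vecs = eigh(B, subset_by_index=[n - d, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.maximum(vals, 0.0)
    # fix each eigenvector's sign: largest-magnitude entry positive
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(vals)[None, :]

    return IsomapEmbedding(
        coordinates=coords,
        eigenvalues=vals,
        eigenvectors=vecs,
        geodesics=D,
        features=X,
        k=k,
        d=d,
        residual_variance=_residual_variance(D, coords),
        nn_distances=dist[:, 1],
    )


def isomap_transform(emb: IsomapEmbedding, new_features: np.ndarray):
    """Out-of-sample coordinates via geodesic-distance interpolation.

    Geodesics from each new point are approximated through its k nearest
    training points (Euclidean hop to the neighbor, then the training
    geodesic onward); coordinates follow from the Nystrom/landmark-MDS
    formula, which reproduces training points exactly.  Returns
    (coords, far_flag) where far_flag marks queries whose nearest
    training neighbor is beyond the 95th percentile of training
    nearest-neighbor distances.
    """
    Xn = np.atleast_2d(np.asarray(new_features, dtype=float))
    e = cdist(Xn, emb.features)  # (m, n)
    m, n = e.shape
    k = emb.k
    near = np.argpartition(e, kth=min(k, n - 1), axis=1)[:, :k]
    g = np.full((m, n), np.inf)
    for i in range(m):
        # geodesic through any of the k nearest anchors
        g[i] = np.min(e[i, near[i], None] + emb.geodesics[near[i], :], axis=0)
    g2 = g**2
    mu = (emb.geodesics**2).mean(axis=0)
    lam = emb.eigenvalues.copy()
    safe = lam > 0
    coords = np.zeros((m, emb.d))
    scale = np.zeros(emb.d)
    scale[safe] = 0.5 / np.sqrt(lam[safe])
    coords = (mu[None, :] - g2) @ emb.eigenvectors * scale[None, :]

    thresh = np.quantile(emb.nn_distances, 0.95)
    far = e.min(axis=1) > thresh
    if np.ndim(new_features) == 1:
        return coords[0], bool(far[0])
    return coords, far


def distance_histograms(coordinates: np.ndarray, prediction_errors: np.ndarray,
                        bins: int = 50):
    """Histogram all pairwise embedding distances against per-shape
    root-sum-square prediction errors on a shared binning.

    Returns a dict with the two histograms, the shared bin edges, and
    the medians of both distributions (the headline comparison: typical
    errors should sit far below typical inter-shape distances).
    """
    dists = pdist(np.asarray(coordinates, dtype=float))
    errs = np.asarray(prediction_errors, dtype=float)
    hi = max(dists.max(), errs.max())
    edges = np.linspace(0.0, hi, bins + 1)
    h_d, _ = np.histogram(dists, bins=edges)
    h_e, _ = np.histogram(errs, bins=edges)
    return {
        "distance_hist": h_d,
        "error_hist": h_e,
        "edges": edges,
        "median_distance": float(np.median(dists)),
        "median_error": float(np.median(errs)),
    }
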