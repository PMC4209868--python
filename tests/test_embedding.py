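import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

import shapecode.shapes as sh
from shapecode.embedding import (
    DisconnectedGraphError,
    derivative_features,
    distance_histograms,
    isomap_fit,
    isomap_transform,
)
from shapecode.render import render_many
from shapecode.shapes import Superquadric


@pytest.fixture(scope="module")
def plane_data():
    rng = np.random.default_rng(0)
    latent = rng.standard_normal((400, 2))
    return latent, latent @ rng.standard_normal((2, 100))


@pytest.fixture(scope="module")
def sphere_family(grid):
    radii = np.linspace(0.01, 0.06, 300)
    shapes = [Superquadric(r, r, r, 1, 1, 1, label=sh.SPHERE_LIKE) for r in radii]
    return radii, render_many(shapes, grid)


class TestIsomapFit:
    def test_linear_manifold_matches_pca_distances(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        r = np.corrcoef(pdist(emb.coordinates), pdist(X))[0, 1]
        assert r**2 > 0.999
        assert emb.residual_variance < 0.001

    def test_sphere_radius_family_orders_by_radius(self, sphere_family):
        """A 1-parameter shape family embeds as a 1-D curve ordered by
        the parameter.  Depth features carry discrete jumps where new
        rays begin to hit, so the neighborhood must be wide enough to
        bridge them."""
        radii, depth = sphere_family
        emb = isomap_fit(depth.reshape(len(radii), -1), k=40, d=1)
        rho = spearmanr(emb.coordinates[:, 0], radii).statistic
        assert abs(rho) > 0.99

    def test_residual_variance_nonincreasing_in_d(self, sphere_family):
        radii, depth = sphere_family
        X = depth.reshape(len(radii), -1)
        rv = [isomap_fit(X, k=40, d=d).residual_variance for d in (1, 2, 4)]
        assert rv[0] >= rv[1] >= rv[2]
        assert all(0 <= v <= 1 for v in rv)

    def test_matches_reference_isomap_implementation(self, plane_data):
        """Cross-check against scikit-learn's Isomap: same k and d give
        the same embedding geometry (pairwise distances agree)."""
        from sklearn.manifold import Isomap as SkIsomap

        _, X = plane_data
        ours = isomap_fit(X[:200], k=12, d=2)
        ref = SkIsomap(n_neighbors=12, n_components=2).fit_transform(X[:200])
        r = np.corrcoef(pdist(ours.coordinates), pdist(ref))[0, 1]
        assert r > 0.999

    def test_coordinates_centered(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        assert np.abs(emb.coordinates.mean(axis=0)).max() < 1e-8

    def test_disconnected_graph_reports_components(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (20, 3)),
                       np.random.default_rng(1).normal(100, 0.1, (20, 3))])
        with pytest.raises(DisconnectedGraphError, match="sizes"):
            isomap_fit(X, k=3, d=2)

    def test_derivative_features_shape(self, sphere_family):
        _, depth = sphere_family
        F = derivative_features(depth[:5])
        assert F.shape == (5, 16 * 16 * 4)


class TestIsomapTransform:
    def test_training_points_reproduced(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        Y, far = isomap_transform(emb, X[:10])
        assert np.abs(Y - emb.coordinates[:10]).max() < 1e-8
        assert not far.any()

    def test_midpoint_stays_near_segment(self, plane_data):
        latent, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        d = np.linalg.norm(latent - latent[0], axis=1)
        j = np.argsort(d)[1]  # nearest neighbor of point 0
        mid = 0.5 * (X[0] + X[j])
        y, _ = isomap_transform(emb, mid)
        lo = np.minimum(emb.coordinates[0], emb.coordinates[j])
        hi = np.maximum(emb.coordinates[0], emb.coordinates[j])
        pad = 0.1 * (np.linalg.norm(emb.coordinates[0] - emb.coordinates[j]) + 1e-9)
        assert np.all(y >= lo - pad) and np.all(y <= hi + pad)

    def test_far_query_flagged(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        y, far = isomap_transform(emb, X[0] + 1e3)
        assert far

    def test_invariant_to_training_order(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        q = X[:5] + 0.01
        Y1, _ = isomap_transform(emb, q)
        # refit on a permuted copy of the same training set
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(X))
        emb2 = isomap_fit(X[perm], k=25, d=2)
        Y2, _ = isomap_transform(emb2, q)
        # coordinates agree up to per-axis sign (eigen-sign convention
        # applies to different orderings of the same points)
        for j in range(2):
            assert (np.allclose(Y1[:, j], Y2[:, j], atol=1e-6)
                    or np.allclose(Y1[:, j], -Y2[:, j], atol=1e-6))


class TestShapeManifoldGeometry:
    def test_embedding_continuous_under_small_perturbations(self, midscale_pipeline, grid):
        """Small parameter perturbations move a shape only slightly in
        the embedding: perturbation-pair distances stay below the 5th
        percentile of all pairwise distances."""
        import dataclasses

        emb = midscale_pipeline["embedding"]
        db = midscale_pipeline["db"]
        p5 = np.quantile(pdist(emb.coordinates), 0.05)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(db), 30, replace=False):
            s = db.shapes[i]
            ds = dataclasses.replace(
                s, A1=min(max(s.A1 * 1.01, 0.01), 0.06), theta1=s.theta1 + 0.01)
            f2 = derivative_features(render_many([ds], grid))
            y2, _ = isomap_transform(emb, f2[0])
            assert np.linalg.norm(y2 - emb.coordinates[i]) < p5

    def test_superquadric_discontinuity_absent_in_embedding(self, midscale_pipeline, grid):
        """A tall box tilted just below +pi/4 and a wide box just above
        -pi/4 render nearly identically; their canonical parameters
        differ greatly but their embedding coordinates do not."""
        import shapecode.shapes as sh

        emb = midscale_pipeline["embedding"]
        delta = 0.02
        tall = Superquadric(0.02, 0.02, 0.05, 0.1, 0.1, 0.1, np.pi / 4 - delta, 0, 0)
        wide = Superquadric(0.02, 0.05, 0.02, 0.1, 0.1, 0.1, -np.pi / 4 + delta, 0, 0)
        pair = derivative_features(render_many([tall, wide], grid))
        ya, _ = isomap_transform(emb, pair[0])
        yb, _ = isomap_transform(emb, pair[1])
        emb_dist = np.linalg.norm(ya - yb)
        p5 = np.quantile(pdist(emb.coordinates), 0.05)
        param_dist = np.linalg.norm(
            sh.canonicalize(tall).params - sh.canonicalize(wide).params)
        assert emb_dist < p5          # close in the shape space
        assert param_dist > 1.0       # far apart in canonical parameters


class TestDistanceHistograms:
    def test_zero_errors_concentrate_first_bin(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X, k=25, d=2)
        h = distance_histograms(emb.coordinates, np.zeros(len(X)))
        assert h["error_hist"][0] == len(X)
        assert h["error_hist"][1:].sum() == 0

    def test_errors_equal_to_distances_coincide(self, plane_data):
        _, X = plane_data
        emb = isomap_fit(X[:50], k=10, d=2)
        dists = pdist(emb.coordinates)
        h = distance_histograms(emb.coordinates, dists)
        assert np.array_equal(h["distance_hist"], h["error_hist"])
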