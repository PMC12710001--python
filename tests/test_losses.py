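"""Reconstruction loss terms: exact identities, brute-force oracles, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from leafgen import losses as L


def brute_chamfer(a, b, squared=True):
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    d = d2 if squared else np.sqrt(d2)
    return d.min(axis=1).sum() + d.min(axis=0).sum()


def brute_neighbor_sets(points, k, d_max):
    out = []
    for u in range(len(points)):
        d = np.linalg.norm(points - points[u], axis=1)
        order = [v for v in np.argsort(d, kind="stable") if v != u and d[v] < d_max]
        out.append(set(order[:k]))
    return out


class TestSkeletonLoss:
    def test_zero_offsets(self):
        assert L.skeleton_loss(np.zeros((10, 3)), np.ones(10, bool)) == 0.0

    def test_l1_of_single_vector(self):
        off = np.zeros((5, 3))
        off[2] = [1.0, -2.0, 0.0]
        mask = np.zeros(5, bool)
        mask[2] = True
        assert L.skeleton_loss(off, mask) == 3.0

    def test_indicator_gates_non_skeleton_offsets(self, rng):
        off = rng.normal(size=(8, 3))
        mask = np.zeros(8, bool)
        mask[:3] = True
        off[:3] = 0.0
        assert L.skeleton_loss(off, mask) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            L.skeleton_loss(np.zeros((3, 3)), np.ones(4, bool))


class TestChamfer:
    def test_identical_sets_zero(self, rng):
        a = rng.normal(size=(12, 3))
        assert L.chamfer_distance(a, a.copy()) == 0.0

    def test_two_singletons(self):
        a, b = np.array([[0.0, 0, 0]]), np.array([[1.0, 0, 0]])
        assert L.chamfer_distance(a, b, squared=True) == 2.0

    @pytest.mark.parametrize("squared", [True, False])
    def test_matches_brute_force(self, rng, squared):
        a, b = rng.normal(size=(30, 3)), rng.normal(size=(25, 3))
        assert L.chamfer_distance(a, b, squared=squared) == pytest.approx(
            brute_chamfer(a, b, squared), abs=1e-12)

    def test_symmetric_and_translation_invariant(self, rng):
        a, b = rng.normal(size=(15, 3)), rng.normal(size=(18, 3))
        t = np.array([3.0, -2.0, 1.0])
        assert L.chamfer_distance(a, b) == pytest.approx(L.chamfer_distance(b, a))
        assert L.chamfer_distance(a + t, b + t) == pytest.approx(
            L.chamfer_distance(a, b), rel=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(arrays(float, (8, 3), elements=st.floats(-5, 5)))
    def test_permutation_invariant(self, a):
        b = a[::-1] + 0.1
        perm = np.arange(8)[::-1]
        assert L.chamfer_distance(a, b) == pytest.approx(
            L.chamfer_distance(a[perm], b), rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            L.chamfer_distance(np.empty((0, 3)), np.zeros((3, 3)))


class TestKNNGraph:
    def test_collinear_chain(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        g = L.build_knn_graph(pts, k=2, d_max=1.5)
        assert list(g.degrees) == [1, 2, 1]

    def test_zero_dmax_isolates_everything(self, rng):
        g = L.build_knn_graph(rng.normal(size=(10, 3)), k=3, d_max=0.0)
        assert g.degrees.sum() == 0

    def test_matches_brute_force(self, rng):
        pts = rng.normal(size=(40, 3))
        g = L.build_knn_graph(pts, k=5, d_max=1.0)
        brute = brute_neighbor_sets(pts, 5, 1.0)
        assert all(set(s) == b for s, b in zip(g.neighbor_sets, brute))

    def test_strict_threshold(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        g = L.build_knn_graph(pts, k=1, d_max=1.0)
        assert g.degrees.sum() == 0  # distance exactly d_max is excluded


class TestEdgeLoss:
    def chain(self, n=6, s=1.0):
        return np.column_stack([np.arange(n) * s, np.zeros(n), np.zeros(n)])

    def test_zero_at_target_spacing(self):
        pts = self.chain()
        g = L.build_knn_graph(pts, k=2, d_max=1.5)
        assert L.edge_loss(g, pts, l_bar=1.0) == 0.0

    def test_uniform_offset(self):
        pts = self.chain()
        g = L.build_knn_graph(pts, k=2, d_max=1.5)
        assert L.edge_loss(g, pts, l_bar=2.0) == pytest.approx(1.0)

    def test_matches_direct_accumulation(self, rng):
        pts = rng.normal(size=(30, 3))
        g = L.build_knn_graph(pts, k=4, d_max=2.0)
        _, _, lengths = g.edges(pts)
        assert L.edge_loss(g, pts, 0.7) == pytest.approx(
            np.abs(lengths - 0.7).mean(), abs=1e-12)

    def test_empty_graph_is_zero(self, rng):
        g = L.build_knn_graph(rng.normal(size=(5, 3)), k=2, d_max=0.0)
        assert L.edge_loss(g, rng.normal(size=(5, 3)), 1.0) == 0.0


class TestSmoothness:
    def test_interior_rows_vanish_on_uniform_chain(self):
        pts = np.column_stack([np.arange(7.0), np.zeros(7), np.zeros(7)])
        g = L.build_knn_graph(pts, k=2, d_max=1.5)
        from leafgen.losses import _laplacian_rows

        q, keep = _laplacian_rows(pts, g)
        interior = np.isin(keep, np.arange(1, 6))
        assert np.allclose(q[interior], 0.0, atol=1e-12)

    def test_matches_dense_laplacian_oracle(self, rng):
        pts = rng.normal(size=(25, 3))
        g = L.build_knn_graph(pts, k=4, d_max=3.0)
        n = len(pts)
        lap = np.zeros((n, n))
        np.fill_diagonal(lap, -1.0)
        for u, nbrs in enumerate(g.neighbor_sets):
            for v in nbrs:
                lap[u, v] = 1.0 / len(nbrs)
        q = lap @ pts
        keep = g.degrees > 0
        expected = (q[keep] ** 2).sum()
        assert L.smoothness_loss(pts, g) == pytest.approx(expected, abs=1e-12)
        expected_norm = np.linalg.norm(q[keep], axis=1).sum()
        assert L.smoothness_loss(pts, g, squared=False) == pytest.approx(
            expected_norm, abs=1e-12)

    def test_centroid_property_gives_zero(self):
        # each point exactly at its neighbors' centroid
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        g = L.build_knn_graph(pts, k=2, d_max=1.5)
        from leafgen.losses import _laplacian_rows

        q, keep = _laplacian_rows(pts, g)
        assert np.allclose(q[np.isin(keep, [1, 2, 3])], 0.0)


class TestGradients:
    """Analytic gradients match central differences on random inputs."""

    @pytest.mark.parametrize("term", ["chamfer", "edges", "smooth", "smooth_norm"])
    def test_finite_differences(self, rng, term):
        pts = rng.normal(size=(20, 3))
        real = rng.normal(size=(22, 3))
        graph = L.build_knn_graph(pts, 4, d_max=10.0)
        if term == "chamfer":
            f = lambda x: L.chamfer_distance(real, x, squared=True)
            grad = L.chamfer_grad(pts, real)
        elif term == "edges":
            f = lambda x: L.edge_loss(graph, x, 0.5)
            grad = L.edge_loss_grad(graph, pts, 0.5)
        elif term == "smooth":
            f = lambda x: L.smoothness_loss(x, graph)
            grad = L.smoothness_loss_grad(pts, graph)
        else:
            f = lambda x: L.smoothness_loss(x, graph, squared=False)
            grad = L.smoothness_loss_grad(pts, graph, squared=False)
        eps = 1e-6
        for i, j in [(0, 0), (5, 1), (11, 2), (19, 0)]:
            xp, xm = pts.copy(), pts.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            num = (f(xp) - f(xm)) / (2 * eps)
            assert num == pytest.approx(grad[i, j], rel=1e-4, abs=1e-7)

    def test_skeleton_grad_is_masked_sign(self, rng):
        off = rng.normal(size=(10, 3))
        mask = rng.random(10) > 0.5
        g = L.skeleton_loss_grad(off, mask)
        assert np.array_equal(g[mask], np.sign(off[mask]))
        assert np.all(g[~mask] == 0)


class TestTotalLoss:
    def test_unit_parts_unit_weights(self):
        parts = dict(skeleton=1, chamfer=1, edges=1, smooth=1, cmmd=1, fid=1, pr=1)
        w = L.LossWeights(1, 1, 1, 1, 1)
        assert L.total_loss(parts, w) == 7.0

    def test_reference_weights(self):
        parts = dict(skeleton=1, chamfer=1, edges=1, smooth=1, cmmd=1, fid=1, pr=1)
        assert L.total_loss(parts, L.LossWeights()) == pytest.approx(11.23)

    def test_zero_distribution_weight(self):
        parts = dict(skeleton=2, chamfer=3, edges=0, smooth=0, cmmd=99, fid=99, pr=99)
        w = L.LossWeights(1, 1, 1, 1, 0)
        assert L.total_loss(parts, w) == 5.0

    def test_non_finite_part_names_term(self):
        with pytest.raises(ValueError, match="chamfer"):
            L.total_loss({"chamfer": np.inf}, L.LossWeights())

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(w_chamfer=-1.0)
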