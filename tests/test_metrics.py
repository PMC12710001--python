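"""Distribution metrics: identities, brute-force oracles, closed forms."""

import itertools

import numpy as np
import pytest

import leafgen as lg
from leafgen import metrics as M


def brute_cmmd_linear(x, y):
    n, m = len(x), len(y)
    sx = sum(x[i] @ x[j] for i in range(n) for j in range(n) if i != j)
    sy = sum(y[i] @ y[j] for i in range(m) for j in range(m) if i != j)
    sxy = sum(x[i] @ y[j] for i in range(n) for j in range(m))
    return sx / (n * (n - 1)) + sy / (m * (m - 1)) - 2 * sxy / (n * m)


def brute_coverage(v, phi, k):
    for vp in phi:
        radius = sorted(np.sum((phi - vp) ** 2, axis=1))[k]
        if np.sum((v - vp) ** 2) < radius:
            return 1
    return 0


def brute_realism(vg, phi, k):
    best = 0.0
    for vp in phi:
        radius = np.sqrt(sorted(np.sum((phi - vp) ** 2, axis=1))[k])
        d = np.linalg.norm(vg - vp)
        best = max(best, np.inf if d == 0 else radius / d)
    return best


class TestEmbedding:
    def test_identical_and_permuted_clouds_match(self, rng):
        cloud = rng.normal(size=(200, 3))
        e1 = M.geometric_embedding(cloud)
        e2 = M.geometric_embedding(cloud[rng.permutation(200)])
        assert np.array_equal(e1, M.geometric_embedding(cloud.copy()))
        assert np.allclose(e1, e2)

    def test_species_separation_on_seeded_fixtures(self):
        def embed(profile, seed):
            r = np.random.default_rng(seed)
            p = lg.sample_skeleton_params(profile, r)
            cloud, _ = lg.generate_pseudo_real_leaf(p, lg.NoiseConfig(), r)
            return M.geometric_embedding(cloud)

        beet = [embed(lg.SUGAR_BEET, s) for s in range(1, 7)]
        maize = [embed(lg.MAIZE, s) for s in range(11, 17)]
        same = [np.linalg.norm(a - b) for a, b in itertools.combinations(beet, 2)]
        cross = [np.linalg.norm(a - b) for a in beet for b in maize]
        assert np.mean(cross) > np.mean(same)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            M.geometric_embedding(np.zeros((3, 3)))


class TestCMMD:
    def test_matches_triple_sum_oracle(self, rng):
        x, y = rng.normal(size=(9, 4)), rng.normal(size=(7, 4))
        val = M.cmmd(M.EmbeddingSet(x), M.EmbeddingSet(y), kernel="linear")
        assert val == pytest.approx(brute_cmmd_linear(x, y), abs=1e-12)

    def test_null_distribution_near_zero(self):
        vals = []
        for s in range(8):
            r = np.random.default_rng(s)
            vals.append(M.cmmd(M.EmbeddingSet(r.normal(size=(400, 3))),
                               M.EmbeddingSet(r.normal(size=(400, 3)))))
        # unbiased estimator: O(1/n) fluctuations around 0
        assert max(abs(v) for v in vals) < 0.1

    def test_identical_sets_at_most_tolerance_above_zero(self, rng):
        x = rng.normal(size=(30, 5))
        assert M.cmmd(M.EmbeddingSet(x), M.EmbeddingSet(x.copy())) <= 1e-9

    def test_rbf_kernel_separates_shifted_sets(self, rng):
        x = rng.normal(size=(60, 3))
        y = rng.normal(size=(60, 3)) + 5.0
        near = M.cmmd(M.EmbeddingSet(x), M.EmbeddingSet(x + 1e-3), kernel="rbf")
        far = M.cmmd(M.EmbeddingSet(x), M.EmbeddingSet(y), kernel="rbf")
        assert far > near

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            M.cmmd(M.EmbeddingSet(rng.normal(size=(5, 3))),
                   M.EmbeddingSet(rng.normal(size=(5, 4))))


class TestFID:
    def test_identical_sets_zero(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(50, 4)))
        assert M.fid(x, x) < 1e-8

    def test_one_dimensional_closed_form(self):
        r = np.random.default_rng(0)
        x = M.EmbeddingSet(r.normal(0, 1, (10_000, 1)))
        y = M.EmbeddingSet(r.normal(1, 1, (10_000, 1)))
        # closed form (mu_r-mu_f)^2 + (sigma_r-sigma_f)^2 = 1
        assert M.fid(x, y) == pytest.approx(1.0, abs=0.1)

    def test_matches_eigendecomposition_oracle(self, rng):
        x, y = rng.normal(size=(40, 5)), rng.normal(size=(40, 5)) + 0.5
        mu_r, mu_f = x.mean(0), y.mean(0)
        cr, cf = np.cov(x, rowvar=False), np.cov(y, rowvar=False)
        # independent sqrt: whiten cr, symmetrize, eigendecompose
        w, v = np.linalg.eigh(cr)
        sr = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
        mid = sr @ cf @ sr
        w2, v2 = np.linalg.eigh(mid)
        tr_sqrt = np.sqrt(np.clip(w2, 0, None)).sum()
        expected = ((mu_r - mu_f) ** 2).sum() + np.trace(cr + cf) - 2 * tr_sqrt
        got = M.fid(M.EmbeddingSet(x), M.EmbeddingSet(y))
        assert got == pytest.approx(expected, abs=1e-8)

    def test_small_sets_use_shrinkage(self, rng):
        # fewer vectors than dimensions: still finite and >= 0
        x = M.EmbeddingSet(rng.normal(size=(6, 10)))
        y = M.EmbeddingSet(rng.normal(size=(6, 10)))
        assert np.isfinite(M.fid(x, y))


class TestCoverageAndPR:
    def test_member_vector_is_covered(self, rng):
        phi = M.EmbeddingSet(rng.normal(size=(10, 3)))
        assert M.coverage_indicator(phi.vectors[4], phi, k=2) == 1

    def test_far_vector_not_covered(self, rng):
        phi = M.EmbeddingSet(rng.normal(size=(10, 3)))
        assert M.coverage_indicator(np.full(3, 100.0), phi, k=2) == 0

    def test_matches_exhaustive_oracle(self, rng):
        phi = rng.normal(size=(20, 4))
        for _ in range(20):
            v = rng.normal(size=4) * 1.5
            assert M.coverage_indicator(v, M.EmbeddingSet(phi), 3) == brute_coverage(v, phi, 3)

    def test_identical_sets_perfect_pr(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(25, 4)))
        for k in (2, 4, 8):
            pr = M.precision_recall(x, M.EmbeddingSet(x.vectors.copy()), k)
            assert pr.precision == 1.0 and pr.recall == 1.0 and pr.f_score == 1.0

    def test_distant_sets_zero_pr(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(15, 3)))
        y = M.EmbeddingSet(rng.normal(size=(15, 3)) + 1000.0)
        pr = M.precision_recall(x, y, 3)
        assert pr.precision == 0.0 and pr.recall == 0.0 and pr.f_score == 0.0

    def test_pr_matches_brute_force(self, rng):
        x, y = rng.normal(size=(18, 3)), rng.normal(size=(16, 3)) * 1.2
        pr = M.precision_recall(M.EmbeddingSet(x), M.EmbeddingSet(y), 3)
        prec = np.mean([brute_coverage(v, x, 3) for v in y])
        rec = np.mean([brute_coverage(v, y, 3) for v in x])
        assert pr.precision == pytest.approx(prec)
        assert pr.recall == pytest.approx(rec)

    def test_too_few_vectors_rejected(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            M.precision_recall(x, x, k=5)


class TestPRLoss:
    def test_perfect_pr_near_zero(self):
        val = M.pr_loss(M.PRResult(1.0, 1.0, 1.0, 3), epsilon=1e-8)
        assert val == pytest.approx(0.0, abs=1e-7)

    def test_zero_pr_with_epsilon(self):
        assert M.pr_loss(M.PRResult(0.0, 0.0, 0.0, 3), epsilon=0.01) == pytest.approx(4.0)

    def test_monotone_in_precision(self):
        vals = [M.pr_loss(M.PRResult(p, 0.5, 0, 3), 1e-6) for p in (0.9, 0.6, 0.3, 0.1)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            M.pr_loss(M.PRResult(1, 1, 1, 3), epsilon=0.0)


class TestRealism:
    def test_coinciding_vector_is_infinite(self):
        grid = np.array([[i * 0.1, 0.0, 0.0] for i in range(10)])
        scores = M.realism_scores(M.EmbeddingSet(grid[:1]), M.EmbeddingSet(grid), k=2)
        assert np.isinf(scores[0])

    def test_far_vector_scores_radius_over_distance(self):
        grid = np.array([[i * 0.1, 0.0, 0.0] for i in range(10)])
        far = M.EmbeddingSet(np.array([[100.0, 0.0, 0.0]]))
        score = M.realism_scores(far, M.EmbeddingSet(grid), k=2)[0]
        assert score < 1.0
        # max over members: the nearest member (0.9,0,0) has k=2 radius 0.2
        assert score == pytest.approx(0.2 / 99.1, rel=1e-6)

    def test_matches_brute_force(self, rng):
        phi = rng.normal(size=(15, 3))
        gen = rng.normal(size=(6, 3))
        scores = M.realism_scores(M.EmbeddingSet(gen), M.EmbeddingSet(phi), k=3)
        for s, v in zip(scores, gen):
            assert s == pytest.approx(brute_realism(v, phi, 3), rel=1e-10)


class TestMeanFscoreAndFiltering:
    def test_identical_sets_mean_one(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(120, 5)))
        assert M.mean_fscore(x, M.EmbeddingSet(x.vectors.copy())) == 1.0

    def test_disjoint_sets_zero(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(40, 3)))
        y = M.EmbeddingSet(rng.normal(size=(40, 3)) + 500)
        assert M.mean_fscore(x, y, k_set=(2, 4, 8)) == 0.0

    def test_mean_of_individual_fscores(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(30, 3)))
        y = M.EmbeddingSet(rng.normal(size=(30, 3)) * 1.3)
        ks = (2, 4, 8)
        expected = np.mean([M.precision_recall(x, y, k).f_score for k in ks])
        assert M.mean_fscore(x, y, ks) == pytest.approx(expected)

    def test_infeasible_k_skipped(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(10, 3)))
        val = M.mean_fscore(x, M.EmbeddingSet(x.vectors.copy()), k_set=(2, 4, 96))
        assert val == 1.0  # 96 skipped, the rest perfect

    def test_zero_threshold_equals_unfiltered(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(30, 4)))
        y = M.EmbeddingSet(rng.normal(size=(30, 4)) * 1.1)
        pr, frac = M.realism_filtered_fscore(x, y, k=3, min_realism=0.0)
        assert frac == 1.0
        assert pr.f_score == pytest.approx(M.precision_recall(x, y, 3).f_score)

    def test_infinite_threshold_invalid(self, rng):
        x = M.EmbeddingSet(rng.normal(size=(20, 4)))
        y = M.EmbeddingSet(rng.normal(size=(20, 4)) + 50)
        pr, frac = M.realism_filtered_fscore(x, y, k=3, min_realism=np.inf)
        assert not pr.valid
        assert frac == 0.0

    def test_fscore_non_decreasing_on_outlier_mixture(self):
        """Filtering off-manifold generated samples raises the F-score."""
        r = np.random.default_rng(2)
        on = r.normal(0, 1, (40, 4))
        outliers = r.normal(8, 0.5, (10, 4))
        real = M.EmbeddingSet(r.normal(0, 1, (50, 4)))
        gen = M.EmbeddingSet(np.vstack([on, outliers]))
        scores, fracs = [], []
        for thr in (0.0, 0.5, 1.0):
            pr, frac = M.realism_filtered_fscore(real, gen, k=3, min_realism=thr)
            assert pr.valid and frac > 0.5
            scores.append(pr.f_score)
            fracs.append(frac)
        assert np.all(np.diff(scores) >= 0)
        assert np.all(np.diff(fracs) <= 0)


class TestPointToMesh:
    def planar_patch(self, n, z, seed):
        r = np.random.default_rng(seed)
        xy = r.uniform(0, 1, (n, 2))
        return np.column_stack([xy, np.full(n, z)])

    def test_identical_leaves_zero(self):
        a = self.planar_patch(300, 0.0, 0)
        v = M.point_to_mesh_distance(a, a.copy(), n_probe=64,
                                     rng=np.random.default_rng(1))
        assert v == pytest.approx(0.0, abs=1e-9)

    def test_parallel_slabs_bounded_by_offset(self):
        h = 0.3
        a = self.planar_patch(300, 0.0, 0)
        b = self.planar_patch(300, h, 1)
        v = M.point_to_mesh_distance(a, b, n_probe=256, rng=np.random.default_rng(2))
        assert 0.0 < v <= h + 1e-6

    def test_seeded_run_reproducible(self):
        a = self.planar_patch(200, 0.0, 3)
        b = self.planar_patch(200, 0.2, 4)
        v1 = M.point_to_mesh_distance(a, b, 128, np.random.default_rng(9))
        v2 = M.point_to_mesh_distance(a, b, 128, np.random.default_rng(9))
        assert v1 == v2


class TestDiversityReport:
    def test_identical_leaves(self):
        r = np.random.default_rng(0)
        leaf = np.column_stack([r.uniform(0, 1, (100, 2)), np.zeros(100)])
        rep = M.diversity_report([leaf, leaf.copy(), leaf.copy()], n_trials=2,
                                 rng=np.random.default_rng(1), n_probe=32)
        assert rep.chamfer_mean == 0.0 and rep.chamfer_std == 0.0
        assert rep.p2m_mean == pytest.approx(0.0, abs=1e-9)

    def test_translated_pair_matches_closed_form(self):
        r = np.random.default_rng(1)
        a = np.column_stack([r.uniform(0, 1, (150, 2)), np.zeros(150)])
        t = np.array([0.0, 0.0, 0.05])
        rep = M.diversity_report([a, a + t], n_trials=1,
                                 rng=np.random.default_rng(2), n_probe=32)
        # every nearest-neighbor distance is at most |t| (the translated copy
        # of the same point is available): symmetric mean chamfer <= |t|
        assert 0 < rep.chamfer_mean <= np.linalg.norm(t) + 1e-12

    def test_reproducible(self):
        r = np.random.default_rng(3)
        leaves = [np.column_stack([r.uniform(0, 1, (80, 2)), np.zeros(80)])
                  for _ in range(3)]
        r1 = M.diversity_report(leaves, 2, np.random.default_rng(5), n_probe=32)
        r2 = M.diversity_report(leaves, 2, np.random.default_rng(5), n_probe=32)
        assert r1 == r2

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            M.diversity_report([np.zeros((10, 3))])


class TestOrderInvariance:
    def test_metrics_invariant_to_vector_order(self, rng):
        x = rng.normal(size=(20, 4))
        y = rng.normal(size=(18, 4))
        perm_x = x[rng.permutation(20)]
        perm_y = y[rng.permutation(18)]
        ex, ey = M.EmbeddingSet(x), M.EmbeddingSet(y)
        px, py = M.EmbeddingSet(perm_x), M.EmbeddingSet(perm_y)
        assert M.fid(ex, ey) == pytest.approx(M.fid(px, py), abs=1e-9)
        assert M.cmmd(ex, ey) == pytest.approx(M.cmmd(px, py), abs=1e-9)
        a, b = M.precision_recall(ex, ey, 3), M.precision_recall(px, py, 3)
        assert (a.precision, a.recall) == (b.precision, b.recall)
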