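"""Density-peak clustering, quality indices, embeddings, ablation clusterers."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from edgeclust import cluster as cl


def brute_force_rho_delta(D, dc):
    n = len(D)
    rho = np.array([sum(np.exp(-((D[i, k] / dc) ** 2)) for k in range(n) if k != i) for i in range(n)])
    delta = np.empty(n)
    nneigh = np.full(n, -1)
    for i in range(n):
        higher = [j for j in range(n) if (rho[j] > rho[i]) or (rho[j] == rho[i] and j < i)]
        if not higher:
            delta[i] = D.max()
        else:
            j = min(higher, key=lambda j: D[i, j])
            delta[i], nneigh[i] = D[i, j], j
    return rho, delta, nneigh


def blob_distances(rng, centers, n_each, spread=0.1):
    pts = np.vstack([rng.normal(c, spread, size=(n_each, 2)) for c in centers])
    return pts, squareform(pdist(pts))


class TestDensityPeak:
    def test_two_point_closed_form(self):
        d = 3.0
        D = np.array([[0.0, d], [d, 0.0]])
        res = cl.density_peak(D, dc=2.0)
        expected_rho = np.exp(-((d / 2.0) ** 2))
        np.testing.assert_allclose(res.rho, [expected_rho, expected_rho])
        np.testing.assert_allclose(res.delta, [d, d])
        assert res.nneigh[0] == -1 and res.nneigh[1] == 0  # rho tie broken by index

    def test_identical_points_have_rho_n_minus_one(self):
        D = np.zeros((5, 5))
        res = cl.density_peak(D, dc=1.0)
        np.testing.assert_allclose(res.rho, 4.0)

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(20, 3))
        D = squareform(pdist(pts))
        res = cl.density_peak(D, dc=0.8)
        rho, delta, nneigh = brute_force_rho_delta(D, 0.8)
        np.testing.assert_allclose(res.rho, rho, atol=1e-10)
        np.testing.assert_allclose(res.delta, delta, atol=1e-10)
        np.testing.assert_array_equal(res.nneigh, nneigh)

    def test_invalid_dc_rejected(self):
        with pytest.raises(ValueError):
            cl.density_peak(np.zeros((3, 3)), dc=0.0)


class TestChooseDc:
    def test_presets_return_published_radii(self):
        assert cl.choose_dc(np.zeros((2, 2)), preset="cyd") == 0.71
        assert cl.choose_dc(np.zeros((2, 2)), preset="ck") == 0.46

    def test_scale_equivariance(self, rng):
        pts = rng.normal(size=(40, 2))
        D = squareform(pdist(pts))
        dc1 = cl.choose_dc(D, 0.05)
        dc2 = cl.choose_dc(3.0 * D, 0.05)
        assert dc2 == pytest.approx(3.0 * dc1, rel=1e-6)

    def test_quality_search_scale_equivariance(self, rng):
        _, D = blob_distances(rng, [(0, 0), (5, 5), (10, 0)], 10)
        dc1, k1 = cl.choose_dc_by_quality(D, k=3)
        dc2, k2 = cl.choose_dc_by_quality(2.0 * D, k=3)
        assert k1 == k2 == 3
        assert dc2 == pytest.approx(2.0 * dc1, rel=1e-9)

    def test_all_zero_distances_rejected(self):
        with pytest.raises(ValueError):
            cl.choose_dc(np.zeros((4, 4)))


class TestCentersAndLabels:
    def test_three_blob_centers_land_one_per_blob(self, rng):
        _, D = blob_distances(rng, [(0, 0), (5, 5), (10, 0)], 15)
        res = cl.density_peak(D, dc=0.5)
        centers = cl.select_centers(res, k=3)
        assert sorted(c // 15 for c in centers) == [0, 1, 2]

    def test_k_equals_n_makes_every_sample_a_center(self, rng):
        pts = rng.normal(size=(6, 2))
        D = squareform(pdist(pts))
        res = cl.density_peak(D, dc=0.5)
        cl.select_centers(res, k=6)
        labels = cl.assign_labels(res)
        assert len(np.unique(labels)) == 6

    def test_duplicate_manual_centers_rejected(self, rng):
        D = squareform(pdist(rng.normal(size=(5, 2))))
        res = cl.density_peak(D, dc=0.5)
        with pytest.raises(ValueError):
            cl.select_centers(res, manual=[1, 1])

    def test_gamma_ranking_invariant_to_monotone_rho_rescale(self, rng):
        _, D = blob_distances(rng, [(0, 0), (6, 6)], 10)
        res = cl.density_peak(D, dc=0.5)
        cen1 = cl.select_centers(res, k=2)
        res2 = cl.DensityPeakResult(
            rho=res.rho * 10 + 3, delta=res.delta, nneigh=res.nneigh, dc=res.dc, dist=res.dist
        )
        cen2 = cl.select_centers(res2, k=2)
        np.testing.assert_array_equal(cen1, cen2)

    def test_separated_pairs_labeled_together(self):
        D = np.array(
            [
                [0.0, 0.1, 5.0, 5.0],
                [0.1, 0.0, 5.0, 5.0],
                [5.0, 5.0, 0.0, 0.1],
                [5.0, 5.0, 0.1, 0.0],
            ]
        )
        res = cl.density_peak(D, dc=0.5)
        cl.select_centers(res, k=2)
        labels = cl.assign_labels(res)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_single_center_labels_everything(self, rng):
        D = squareform(pdist(rng.normal(size=(8, 2))))
        res = cl.density_peak(D, dc=1.0)
        cl.select_centers(res, k=1)
        assert (cl.assign_labels(res) == 1).all()

    def test_labels_stable_under_permutation(self, rng):
        pts, D = blob_distances(rng, [(0, 0), (6, 6), (12, 0)], 12)
        res = cl.density_peak(D, dc=0.6)
        cl.select_centers(res, k=3)
        lab = cl.assign_labels(res)
        perm = rng.permutation(len(pts))
        D2 = D[np.ix_(perm, perm)]
        res2 = cl.density_peak(D2, dc=0.6)
        cl.select_centers(res2, k=3)
        lab2 = cl.assign_labels(res2)
        assert adjusted_rand_score(lab[perm], lab2) == pytest.approx(1.0)


class TestClusterQuality:
    def test_silhouette_matches_hand_computation(self):
        x = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = squareform(pdist(x))
        labels = np.array([1, 1, 2, 2])
        q = cl.cluster_quality(labels, dist=D, features=x)
        from sklearn.metrics import silhouette_samples

        s0 = silhouette_samples(D, labels, metric="precomputed")[0]
        # a(0)=0.1, b(0)=mean(10,10.1)=10.05 -> s=(10.05-0.1)/10.05
        assert s0 == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-12)
        assert -1 <= q.silhouette_avg <= 1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            cl.cluster_quality(np.ones(5), dist=np.zeros((5, 5)))

    def test_quality_indices_invariant_to_label_permutation(self, rng):
        X, D = blob_distances(rng, [(0, 0), (4, 4)], 10)
        labels = np.repeat([1, 2], 10)
        remap = {1: 7, 2: 3}
        relabeled = np.vectorize(remap.get)(labels)
        q1 = cl.cluster_quality(labels, dist=D, features=X)
        q2 = cl.cluster_quality(relabeled, dist=D, features=X)
        assert q1.silhouette_avg == pytest.approx(q2.silhouette_avg)
        assert q1.dbi == pytest.approx(q2.dbi)
        assert q1.ch_pseudo_f == pytest.approx(q2.ch_pseudo_f)


class TestValidationViews:
    def test_block_diagonal_odm(self, rng):
        _, D = blob_distances(rng, [(0, 0), (8, 8)], 10)
        labels = np.repeat([1, 2], 10)
        views = cl.validation_views(D, labels)
        odm = views["ordered_dissimilarity_map"]
        in_block = np.concatenate([odm[:10, :10].ravel(), odm[10:, 10:].ravel()])
        off_block = odm[:10, 10:].ravel()
        assert off_block.mean() > in_block.mean()

    def test_classical_mds_exact_for_euclidean_input(self, rng):
        pts = rng.normal(size=(15, 2))
        D = squareform(pdist(pts))
        emb = cl.classical_mds(D, 2)
        # Procrustes alignment against the generating coordinates
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, emb)
        assert disparity < 1e-12

    def test_tsne_presets_match_published_parameters(self):
        assert cl.TSNE_PRESETS["velocity"] == (30, 50)
        assert cl.TSNE_PRESETS["acf"] == (10, 20)

    def test_tsne_perplexity_guard(self, rng):
        _, D = blob_distances(rng, [(0, 0), (5, 5)], 5)
        with pytest.raises(ValueError, match="perplexity"):
            cl.validation_views(D, np.repeat([1, 2], 5), features=rng.normal(size=(10, 15)))


class TestAblationClusterers:
    def test_two_far_blobs_give_two_communities(self, rng):
        # neighbourhood size comparable to the blob size, as in the published
        # runs where the neighbour count was a sizable fraction of the samples
        _, D = blob_distances(rng, [(0, 0), (20, 20)], 20)
        labels = cl.community_detect(D, n_neighbors=12, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:20])) == 1 and len(np.unique(labels[20:])) == 1

    def test_identical_points_single_community(self):
        D = np.zeros((8, 8))
        labels = cl.community_detect(D, n_neighbors=3, seed=0)
        assert len(np.unique(labels)) == 1

    def test_community_determinism_under_seed(self, rng):
        _, D = blob_distances(rng, [(0, 0), (3, 3), (6, 0)], 10, spread=0.5)
        a = cl.community_detect(D, 6, seed=42)
        b = cl.community_detect(D, 6, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_kmeans_recovers_separated_templates(self, small_velocity_set):
        vel, truth = small_velocity_set
        labels = cl.kmeans_baseline(vel.matrix, k=5, seed=0)
        assert adjusted_rand_score(truth.labels, labels) >= 0.95

    def test_kmeans_parameter_guards(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            cl.kmeans_baseline(X, k=1)
        with pytest.raises(ValueError):
            cl.kmeans_baseline(X, k=6)
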