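"""PCA shape basis, weight clustering, bundle segmentation and
descriptors — including brute-force oracle comparisons."""

import numpy as np
import pytest

from cnvtract.evaluation import segmentation_study
from cnvtract.shape import (ClusterModel, assign_clusters, cluster_weights,
                            fit_shape_pca, membership_histogram, project,
                            segment_bundles, shape_descriptors,
                            train_bundle_map)
from cnvtract.simulate import SimulationDesign, simulate_bundle
from cnvtract.streamlines import streamlines_to_features
from tests.conftest import make_cohort


class TestShapePca:
    def test_rank_two_data_yields_two_components(self, rng):
        basis = rng.normal(0, 1, (2, 90))
        X = rng.normal(0, 1, (40, 2)) @ basis + rng.normal(0, 1, 90)
        model = fit_shape_pca(X, variance_target=0.95)
        assert model.n_components == 2
        full = fit_shape_pca(X, variance_target=1.0)
        assert np.sum(full.eigenvalues > 1e-10) == 2

    def test_eigenvalues_match_dense_eigendecomposition(self, rng):
        X = rng.normal(0, 2, (5, 6))
        model = fit_shape_pca(X, variance_target=1.0)
        cov = np.cov(X, rowvar=False, ddof=1)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.eigenvalues, ev[:model.n_components],
                           atol=1e-8)

    def test_full_basis_reconstructs_exactly(self, rng):
        X = rng.normal(0, 1, (12, 8))
        model = fit_shape_pca(X, variance_target=1.0)
        W = project(model, X)
        recon = W @ model.basis + model.mean_vector
        assert np.allclose(recon, X, atol=1e-8)

    def test_sign_convention_largest_element_positive(self, rng):
        X = rng.normal(0, 1, (30, 10))
        model = fit_shape_pca(X, variance_target=1.0)
        for row in model.basis:
            assert row[np.argmax(np.abs(row))] > 0

    def test_identical_vectors_rejected(self):
        X = np.ones((5, 9))
        with pytest.raises(ValueError, match="zero variance"):
            fit_shape_pca(X)

    def test_explicit_component_count(self, rng):
        X = rng.normal(0, 1, (40, 20))
        assert fit_shape_pca(X, n_components=7).n_components == 7


class TestProjection:
    def test_mean_vector_projects_to_zero(self, rng):
        model = fit_shape_pca(rng.normal(0, 1, (20, 12)), variance_target=0.9)
        assert np.allclose(project(model, model.mean_vector), 0.0, atol=1e-10)

    def test_eigenvector_displacement_recovers_weight(self, rng):
        model = fit_shape_pca(rng.normal(0, 1, (20, 12)), variance_target=0.9)
        v = model.mean_vector + 2.0 * model.basis[0]
        w = project(model, v)
        expected = np.zeros(model.n_components)
        expected[0] = 2.0
        assert np.allclose(w, expected, atol=1e-10)

    def test_reconstruction_error_bounded_by_discarded_eigenvalue_mass(self, rng):
        X = rng.normal(0, 1, (60, 15)) * np.linspace(3, 0.1, 15)
        model = fit_shape_pca(X, variance_target=0.9)
        W = project(model, X)
        recon = W @ model.basis + model.mean_vector
        mse = np.mean(np.sum((X - recon) ** 2, axis=1))
        tail = model.total_variance - model.eigenvalues.sum()
        # mean squared residual equals the discarded eigenvalue mass
        # (up to the n/(n-1) sample-covariance factor)
        assert mse == pytest.approx(tail * (len(X) - 1) / len(X), rel=1e-6)

    def test_length_mismatch_rejected(self, rng):
        model = fit_shape_pca(rng.normal(0, 1, (20, 12)))
        with pytest.raises(ValueError):
            project(model, np.zeros(13))


def _lloyd(X, centroids, iters=300):
    """Exhaustive reference Lloyd iteration from a fixed init."""
    C = centroids.copy()
    for _ in range(iters):
        d = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
        lab = d.argmin(1)
        new = np.array([X[lab == k].mean(0) if np.any(lab == k) else C[k]
                        for k in range(len(C))])
        if np.allclose(new, C, atol=1e-12):
            break
        C = new
    return C


class TestClustering:
    def test_k_equals_n_distinct_points_gives_zero_inertia(self, rng):
        X = rng.normal(0, 5, (12, 3))
        cm = cluster_weights(X, K=12, seed=0)
        d = ((X[:, None, :] - cm.centroids[None]) ** 2).sum(-1).min(1)
        assert d.max() < 1e-12

    def test_two_separated_blobs_recovered_exactly(self, rng):
        a = rng.normal(0, 1, (40, 4))
        b = rng.normal(0, 1, (40, 4)) + 20.0
        X = np.vstack([a, b])
        cm = cluster_weights(X, K=2, seed=0)
        lab = assign_clusters(cm, X)
        assert len(set(lab[:40])) == 1 and len(set(lab[40:])) == 1
        assert lab[0] != lab[40]

    def test_same_seed_reproduces_centroids(self, rng):
        X = rng.normal(0, 1, (100, 5))
        c1 = cluster_weights(X, K=8, seed=3).centroids
        c2 = cluster_weights(X, K=8, seed=3).centroids
        assert np.array_equal(c1, c2)

    def test_matches_exhaustive_lloyd_from_identical_init(self, rng):
        X = rng.normal(0, 1, (50, 3))
        init = X[rng.choice(50, 5, replace=False)]
        ours = cluster_weights(X, K=5, init=init).centroids
        ref = _lloyd(X, init)
        # same fixed point, possibly permuted
        d = ((ours[:, None, :] - ref[None]) ** 2).sum(-1)
        assert np.max(d.min(axis=1)) < 1e-8

    def test_fewer_points_than_clusters_suggests_smaller_k(self, rng):
        with pytest.raises(ValueError, match="smaller K"):
            cluster_weights(rng.normal(0, 1, (5, 2)), K=10)


class TestMembershipHistogram:
    def test_counts_sum_to_streamline_count(self):
        h = membership_histogram([3] * 10, K=5)
        assert np.array_equal(h, [0, 0, 0, 10, 0])

    def test_empty_subject_gives_zero_vector(self):
        h = membership_histogram([], K=4)
        assert h.sum() == 0 and len(h) == 4

    def test_normalised_histogram_sums_to_one(self, rng):
        h = membership_histogram(rng.integers(0, 7, 50), K=7, normalise=True)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_id_rejected(self):
        with pytest.raises(ValueError):
            membership_histogram([5], K=5)


class TestSegmentation:
    def test_held_out_accuracy_on_three_bundle_fixture(self):
        res = segmentation_study(seed=0)
        assert res["accuracy"] >= 0.95

    def test_unlabelled_cluster_maps_to_unassigned(self, rng):
        X = rng.normal(0, 1, (30, 3))
        cm = ClusterModel(centroids=np.array([[0., 0., 0.], [50., 50., 50.]]),
                          cluster_to_bundle={0: "cc_body"})
        lab = assign_clusters(cm, np.array([[49., 50., 51.]]))
        assert cm.cluster_to_bundle.get(int(lab[0]), "unassigned") == "unassigned"

    def test_empty_bundle_map_rejected(self, rng):
        from cnvtract.streamlines import Streamline, Tractogram
        model = fit_shape_pca(rng.normal(0, 1, (20, 90)))
        cm = ClusterModel(centroids=np.zeros((1, model.n_components)))
        tg = Tractogram([Streamline(np.column_stack(
            [np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)]))])
        with pytest.raises(ValueError, match="empty"):
            segment_bundles(tg, model, cm)

    def test_bad_labels_rejected_in_training(self, rng):
        W = rng.normal(0, 1, (10, 2))
        cm = ClusterModel(centroids=W[:2])
        with pytest.raises(ValueError, match="vocabulary"):
            train_bundle_map(cm, W, ["not_a_bundle"] * 10)


class TestShapeDescriptors:
    def test_streamlines_at_model_mean_give_zero_descriptors(self, rng):
        model = fit_shape_pca(rng.normal(0, 1, (20, 12)))
        W = np.zeros((8, model.n_components))
        d = shape_descriptors(W, model, "cc_body")
        assert np.allclose(d.values, 0.0) and not d.missing

    def test_below_minimum_count_marked_missing(self, rng):
        model = fit_shape_pca(rng.normal(0, 1, (20, 12)))
        d = shape_descriptors(np.zeros((3, model.n_components)), model,
                              "fornix_L", min_streamlines=5)
        assert d.missing and np.all(np.isnan(d.values))

    def test_eigenvector_sign_flip_negates_one_descriptor(self, rng):
        X = rng.normal(0, 1, (40, 12))
        model = fit_shape_pca(X, variance_target=1.0)
        W = project(model, X[:10])
        d0 = shape_descriptors(W, model, "cc_body").values
        flipped = fit_shape_pca(X, variance_target=1.0)
        flipped.basis[1] = -flipped.basis[1]
        W1 = project(flipped, X[:10])
        d1 = shape_descriptors(W1, flipped, "cc_body").values
        assert d1[1] == pytest.approx(-d0[1], abs=1e-10)
        keep = np.arange(len(d0)) != 1
        assert np.allclose(d1[keep], d0[keep], atol=1e-10)

    def test_descriptor_monotone_in_arc_amplitude(self):
        # cingulum-like arcs with amplitudes 2..10 mm: the most
        # amplitude-correlated descriptor must be monotone up to sign
        cohort = make_cohort(seed=5)
        amps = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        feats, groups = [], []
        for g, a in enumerate(amps):
            design = SimulationDesign(
                seed=11, amplitude_base=a, curvature_effect=0.0,
                amplitude_subject_sd=0.0, point_jitter_sd=0.5,
                n_streamlines=20)
            sls = simulate_bundle("cingulum_dorsal_L", cohort.iloc[0], design,
                                  subject_id=f"amp{g}")
            feats.append(streamlines_to_features(sls))
            groups += [g] * len(sls)
        X = np.vstack(feats)
        model = fit_shape_pca(X, n_components=5)
        W = project(model, X)
        groups = np.array(groups)
        means = np.array([[W[groups == g, j].mean() for j in range(5)]
                          for g in range(len(amps))])
        cors = [abs(np.corrcoef(amps, means[:, j])[0, 1]) for j in range(5)]
        j = int(np.argmax(cors))
        assert cors[j] > 0.95
        diffs = np.diff(means[:, j])
        assert np.all(diffs > 0) or np.all(diffs < 0)
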