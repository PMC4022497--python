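"""Standardized PCA, K-means(k=2) and the two-round classifier."""

import itertools

import numpy as np
import pytest

from ecr import classify
from ecr.classify import (
    CLASSIFIER_FEATURES,
    FLIP,
    FUNC,
    FeatureMatrix,
    assign_flip_cluster,
    kmeans2,
    load_model,
    project,
    save_model,
    select_features,
    standardize_and_pca,
    train_two_round,
)
from ecr.exceptions import DegenerateDataError, FeatureMismatchError
from ecr.features import FEATURE_NAMES


def random_matrix(n_rows, feature_names, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    return FeatureMatrix(
        interface_ids=[f"i{i}" for i in range(n_rows)],
        values=rng.normal(size=(n_rows, len(feature_names))),
        feature_names=list(feature_names),
        labels=labels,
    )


class TestStandardizeAndPca:
    def test_two_perfectly_correlated_features(self):
        x = np.arange(10, dtype=float)
        m = FeatureMatrix(
            [f"i{i}" for i in range(10)],
            np.column_stack([x, 2 * x + 1]),
            ["f1", "f2"],
        )
        model, scores = standardize_and_pca(m)
        np.testing.assert_allclose(model.eigenvalues, [2.0, 0.0], atol=1e-12)
        assert model.variance_fraction[0] == pytest.approx(1.0)

    def test_exactly_uncorrelated_features(self):
        # orthogonal contrast columns have sample correlation exactly 0
        m = FeatureMatrix(
            ["a", "b", "c", "d"],
            np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float),
            ["f1", "f2"],
        )
        model, _ = standardize_and_pca(m)
        np.testing.assert_allclose(model.eigenvalues, [1.0, 1.0], atol=1e-12)

    def test_matches_eigendecomposition_oracle(self):
        m = random_matrix(12, [f"f{k}" for k in range(7)], seed=3)
        model, scores = standardize_and_pca(m)
        corr = np.corrcoef(m.values, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
        # each reported eigenpair satisfies corr @ v = λ v
        for k in range(7):
            v = model.eigenvectors[:, k]
            np.testing.assert_allclose(corr @ v, model.eigenvalues[k] * v, atol=1e-8)

    def test_orthonormality_trace_and_reconstruction(self):
        m = random_matrix(30, [f"f{k}" for k in range(7)], seed=9)
        model, scores = standardize_and_pca(m)
        e = model.eigenvectors
        np.testing.assert_allclose(e.T @ e, np.eye(7), atol=1e-8)
        assert model.eigenvalues.sum() == pytest.approx(7.0, abs=1e-8)
        z = (m.values - model.means) / model.sds
        np.testing.assert_allclose(scores @ e.T, z, atol=1e-8)

    def test_zero_variance_feature_named_in_error(self):
        m = random_matrix(10, ["f1", "f2"], seed=1)
        m.values[:, 1] = 5.0
        with pytest.raises(DegenerateDataError, match="f2"):
            standardize_and_pca(m)


class TestSelectFeatures:
    def test_drops_r2_and_is_idempotent(self):
        m = random_matrix(10, FEATURE_NAMES, seed=2)
        out = select_features(m)
        assert out.feature_names == CLASSIFIER_FEATURES
        again = select_features(out)
        assert again.feature_names == CLASSIFIER_FEATURES
        np.testing.assert_array_equal(again.values, out.values)

    def test_synthetic_training_variance_concentrates(self, trained_synthetic):
        matrix7, _, _ = trained_synthetic
        model, _ = standardize_and_pca(matrix7)
        assert float(model.variance_fraction[:2].sum()) > 0.80


class TestKmeans2:
    def test_separated_clouds_split_exactly(self):
        rng = np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal([-10, 0], 0.1, size=(20, 2)), rng.normal([10, 0], 0.1, size=(20, 2))]
        )
        result = kmeans2(pts, seed=1)
        left = set(result.assignments[:20])
        right = set(result.assignments[20:])
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_matches_exhaustive_global_optimum(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            pts = rng.normal(size=(6, 2)) * 3
            result = kmeans2(pts, seed=1, restarts=50)

            best = np.inf
            for mask_bits in range(1, 2**6 - 1):
                mask = np.array([(mask_bits >> i) & 1 for i in range(6)], dtype=bool)
                inertia = sum(
                    ((pts[g] - pts[g].mean(axis=0)) ** 2).sum()
                    for g in (mask, ~mask)
                )
                best = min(best, inertia)
            assert result.inertia == pytest.approx(best, abs=1e-9)

    def test_identical_points_flagged_degenerate(self):
        pts = np.ones((5, 2))
        result = kmeans2(pts, seed=1)
        assert result.degenerate

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 2))
        a = kmeans2(pts, seed=7)
        b = kmeans2(pts, seed=7)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        np.testing.assert_array_equal(a.centroids, b.centroids)


class TestAssignFlipCluster:
    def _clustered(self, values, labels=None, seed=1):
        m = FeatureMatrix(
            [f"i{i}" for i in range(len(values))],
            values,
            CLASSIFIER_FEATURES,
            labels=labels,
        )
        pca, scores = standardize_and_pca(m)
        clustering = kmeans2(scores[:, :2], seed=seed)
        return m, pca, clustering

    def _two_population_values(self, rng, negate=False):
        # hot population: large sum/n_hot/avg; cold population: small
        hot = rng.normal([0.1, 2.5, 30.0, 1.5, 25.0, 12.0, 0.5], 0.2, size=(15, 7))
        cold = rng.normal([-0.01, 0.3, 4.0, 0.25, 15.0, 1.0, 0.07], 0.2, size=(15, 7))
        values = np.vstack([hot, cold])
        return -values if negate else values

    def test_hot_high_sum_cloud_designated_flip(self):
        rng = np.random.default_rng(3)
        m, pca, clustering = self._clustered(self._two_population_values(rng))
        flip = assign_flip_cluster(pca, clustering)
        # the first 15 rows are the hot population
        hot_cluster = np.bincount(clustering.assignments[:15]).argmax()
        assert flip == hot_cluster

    def test_negated_data_flips_designation(self):
        rng = np.random.default_rng(3)
        values = self._two_population_values(rng)
        m, pca, cl = self._clustered(values)
        flip = assign_flip_cluster(pca, cl)
        m2, pca2, cl2 = self._clustered(self._two_population_values(
            np.random.default_rng(3), negate=True))
        flip2 = assign_flip_cluster(pca2, cl2)
        hot1 = np.bincount(cl.assignments[:15]).argmax()
        hot2 = np.bincount(cl2.assignments[:15]).argmax()
        assert flip == hot1
        assert flip2 != hot2  # negated "hot" rows are now the low-sum cloud

    def test_label_majority_mapping(self):
        rng = np.random.default_rng(3)
        labels = [FLIP] * 15 + [FUNC] * 15
        m, pca, clustering = self._clustered(self._two_population_values(rng), labels)
        flip = assign_flip_cluster(pca, clustering, labels=labels)
        assert flip == np.bincount(clustering.assignments[:15]).argmax()


class TestTwoRoundTraining:
    def test_bookkeeping_partition(self, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        r1 = set(model.round1_member_idx.tolist())
        r2 = set(model.round2_input_idx.tolist())
        assert r1 | r2 == set(range(matrix7.n))
        assert r1 & r2 == set()

    def test_round2_input_reconstruction(self, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        expected = [i for i in range(matrix7.n) if i not in set(model.round1_member_idx)]
        np.testing.assert_array_equal(model.round2_input_idx, expected)

    def test_too_few_rows_raises(self):
        m = random_matrix(5, CLASSIFIER_FEATURES, seed=0)
        with pytest.raises(DegenerateDataError):
            train_two_round(m)

    def test_wrong_feature_set_raises(self):
        m = random_matrix(10, FEATURE_NAMES, seed=0)  # 8 features, r2 included
        with pytest.raises(FeatureMismatchError):
            train_two_round(m)


class TestProjection:
    def test_training_matrix_reproduces_round1_assignments(self, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        _, detail = project(model, matrix7)
        np.testing.assert_array_equal(
            detail["round1_assignments"], model.round1.clustering.assignments
        )

    def test_row_at_centroid_preimage_assigned_to_it(self, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        pca = model.round1.pca
        for k in (0, 1):
            # invert: scores (c1, c2, 0, ..., 0) -> standardized -> raw features
            s = np.zeros(len(pca.feature_names))
            s[:2] = model.round1.clustering.centroids[k]
            raw = (pca.eigenvectors @ s) * pca.sds + pca.means
            m = FeatureMatrix(["x"], raw[None, :], pca.feature_names)
            _, detail = project(model, m)
            assert detail["round1_assignments"][0] == k

    def test_feature_name_mismatch_raises(self, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        renamed = FeatureMatrix(
            matrix7.interface_ids,
            matrix7.values,
            ["bogus"] + matrix7.feature_names[1:],
        )
        with pytest.raises(FeatureMismatchError):
            project(model, renamed)

    def test_eigenvector_negation_leaves_assignments_unchanged(self, trained_synthetic):
        import copy

        matrix7, model, _ = trained_synthetic
        pred_before, _ = project(model, matrix7)
        flipped = copy.deepcopy(model)
        for rm in (flipped.round1, flipped.round2):
            rm.pca.eigenvectors[:, 0] *= -1  # PC1 sign is arbitrary
            rm.clustering.centroids[:, 0] *= -1
        pred_after, _ = project(flipped, matrix7)
        assert pred_before == pred_after

    def test_heldout_synthetic_accuracy(self, trained_synthetic):
        from ecr import generate_dataset
        from ecr.metrics import accuracy, confusion_from_labels

        _, model, _ = trained_synthetic
        held, _ = generate_dataset(40, 24, seed=99)
        held7 = select_features(held)
        pred, _ = project(model, held7)
        c = confusion_from_labels(held7.labels, pred)
        assert accuracy(c) >= 0.85


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, trained_synthetic):
        matrix7, model, _ = trained_synthetic
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for a, b in ((model.round1, loaded.round1), (model.round2, loaded.round2)):
            np.testing.assert_array_equal(a.pca.means, b.pca.means)
            np.testing.assert_array_equal(a.pca.sds, b.pca.sds)
            np.testing.assert_array_equal(a.pca.eigenvectors, b.pca.eigenvectors)
            np.testing.assert_array_equal(a.pca.eigenvalues, b.pca.eigenvalues)
            np.testing.assert_array_equal(
                a.clustering.centroids, b.clustering.centroids
            )
            assert a.flip_cluster == b.flip_cluster
        assert loaded.predictions == model.predictions
        pred_orig, _ = project(model, matrix7)
        pred_loaded, _ = project(loaded, matrix7)
        assert pred_orig == pred_loaded

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"hello": 1}')
        from ecr.exceptions import InputError

        with pytest.raises(InputError):
            load_model(p)
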