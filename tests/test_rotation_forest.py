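"""Rotation Forest: partitions, PCA blocks, assembly, ensemble behaviour."""

import numpy as np
import pytest

from lpqppi.rotation_forest import (
    RFConfig,
    assemble_rotation,
    canonicalize_signs,
    fit_block,
    label_from_proba,
    load_model,
    partition_features,
    predict,
    predict_proba,
    save_model,
    train,
)


def blobs(n=200, n_features=4, seed=0, sep=6.0):
    """Two well-separated Gaussian blobs with +/-1 labels."""
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(half, n_features)),
            rng.normal(sep, 1.0, size=(n - half, n_features)),
        ]
    )
    y = np.concatenate([np.full(half, -1), np.full(n - half, 1)])
    perm = rng.permutation(n)
    return x[perm], y[perm]


class TestPartition:
    def test_even_split(self, rng):
        part = partition_features(10, 5, rng)
        assert [len(s) for s in part.subsets] == [2] * 5
        assert part.n_padded == 0

    def test_uneven_split_pads_the_last_subset(self, rng):
        part = partition_features(7, 3, rng)
        assert part.subset_size == 3
        assert [len(s) for s in part.subsets] == [3, 3, 1]
        assert part.n_padded == 2

    def test_every_feature_in_exactly_one_subset(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            part = partition_features(512, 55, rng)
            all_idx = np.concatenate(part.subsets)
            assert sorted(all_idx.tolist()) == list(range(512))

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_features(4, 5, rng)


class TestFitBlock:
    def test_one_dimensional_block_is_unit(self, rng):
        x = rng.normal(size=(50, 1))
        np.testing.assert_allclose(fit_block(x, None, 0.6, rng), [[1.0]])

    def test_columns_are_orthonormal(self, rng):
        x = rng.normal(size=(80, 6))
        c = fit_block(x, None, 0.6, rng)
        np.testing.assert_allclose(c.T @ c, np.eye(6), atol=1e-8)

    def test_matches_eigendecomposition_of_drawn_covariance(self):
        # fraction 1.0 draws every row, so the oracle covariance is just
        # the full-sample covariance regardless of the draw order
        rng = np.random.default_rng(3)
        x = np.random.default_rng(11).normal(size=(60, 5))
        c = fit_block(x, None, 1.0, rng)
        centered = x - x.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(centered.T @ centered / 59)
        oracle = canonicalize_signs(eigvecs[:, np.argsort(eigvals)[::-1]])
        np.testing.assert_allclose(c, oracle, atol=1e-8)

    def test_identical_rows_fall_back_to_identity(self, rng, caplog):
        x = np.ones((30, 4))
        with caplog.at_level("WARNING"):
            c = fit_block(x, None, 0.6, rng)
        np.testing.assert_array_equal(c, np.eye(4))
        assert "identity" in caplog.text


class TestAssembly:
    def test_single_block_reorders_to_original_feature_order(self, rng):
        part = partition_features(5, 1, rng)
        block = np.linalg.qr(rng.normal(size=(5, 5)))[0]
        spec = assemble_rotation([block], part)
        x = rng.normal(size=(10, 5))
        idx = part.subsets[0]
        expected = np.empty_like(x)
        expected[:, idx] = x[:, idx] @ block
        np.testing.assert_allclose(spec.apply(x), expected)
        np.testing.assert_allclose(spec.apply(x), x @ spec.matrix())

    def test_identity_blocks_leave_data_unchanged(self, rng):
        part = partition_features(12, 3, rng)
        spec = assemble_rotation([np.eye(len(s)) for s in part.subsets], part)
        x = rng.normal(size=(7, 12))
        np.testing.assert_array_equal(spec.apply(x), x)

    def test_blockwise_application_oracle(self, rng):
        part = partition_features(12, 3, rng)
        blocks = [np.linalg.qr(rng.normal(size=(4, 4)))[0] for _ in range(3)]
        spec = assemble_rotation(blocks, part)
        x = rng.normal(size=(20, 12))
        out = spec.apply(x)
        for idx, block in zip(part.subsets, blocks):
            np.testing.assert_allclose(out[:, idx], x[:, idx] @ block)

    def test_rotation_preserves_frobenius_norm_without_padding(self, rng):
        x, y = blobs(n=60, n_features=12, seed=5)
        model = train(x, y, RFConfig(n_subsets=3, n_trees=2, seed=1))
        for spec in model.rotations:
            assert abs(
                np.linalg.norm(spec.apply(x)) - np.linalg.norm(x)
            ) <= 1e-8 * np.linalg.norm(x)

    def test_dimension_mismatch_rejected(self, rng):
        part = partition_features(6, 2, rng)
        with pytest.raises(ValueError):
            assemble_rotation([np.eye(3)], part)
        with pytest.raises(ValueError):
            assemble_rotation([np.eye(2), np.eye(2)], part)


class TestTraining:
    def test_same_seed_reproduces_predictions(self):
        x, y = blobs(seed=2)
        x_new, _ = blobs(seed=9)
        config = RFConfig(n_subsets=2, n_trees=5, seed=77)
        p1 = predict_proba(train(x, y, config), x_new)
        p2 = predict_proba(train(x, y, config), x_new)
        np.testing.assert_array_equal(p1, p2)

    def test_separable_blobs_are_fit_almost_perfectly(self):
        x, y = blobs(n=200, n_features=4, seed=0)
        model = train(x, y, RFConfig(n_subsets=1, n_trees=1, seed=0))
        assert np.mean(predict(model, x) == y) >= 0.99

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            train(x, np.ones(10), RFConfig(n_subsets=1, n_trees=1))

    def test_non_pm1_labels_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match=r"\+1/-1"):
            train(x, y, RFConfig(n_subsets=1, n_trees=1))

    def test_growing_the_ensemble_keeps_earlier_trees(self):
        x, y = blobs(seed=4)
        small = train(x, y, RFConfig(n_subsets=2, n_trees=3, seed=5))
        large = train(x, y, RFConfig(n_subsets=2, n_trees=6, seed=5))
        for spec_s, spec_l in zip(small.rotations, large.rotations):
            for b_s, b_l in zip(spec_s.blocks, spec_l.blocks):
                np.testing.assert_array_equal(b_s, b_l)


class TestPrediction:
    def test_probabilities_form_a_simplex(self):
        x, y = blobs(seed=1)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=4, seed=3))
        proba = predict_proba(model, x)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_ensemble_mean_matches_manual_average_of_three_trees(self):
        x, y = blobs(seed=6)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=3, seed=8))
        manual = np.mean(
            [
                tree.predict_proba(spec.apply(x))
                for spec, tree in zip(model.rotations, model.trees)
            ],
            axis=0,
        )
        np.testing.assert_allclose(predict_proba(model, x), manual, atol=1e-12)

    def test_single_tree_ensemble_equals_its_tree(self):
        x, y = blobs(seed=7)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=1, seed=2))
        np.testing.assert_array_equal(
            predict_proba(model, x),
            model.trees[0].predict_proba(model.rotations[0].apply(x)),
        )

    def test_tree_storage_order_is_irrelevant(self):
        x, y = blobs(seed=3)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=5, seed=4))
        before = predict_proba(model, x)
        order = np.random.default_rng(0).permutation(5)
        model.rotations = [model.rotations[i] for i in order]
        model.trees = [model.trees[i] for i in order]
        np.testing.assert_allclose(predict_proba(model, x), before, atol=1e-12)

    def test_identity_rotation_reduces_to_a_raw_feature_tree(self):
        x, y = blobs(seed=8)
        model = train(
            x, y, RFConfig(n_subsets=2, n_trees=1, identity_rotation=True, seed=0)
        )
        np.testing.assert_array_equal(model.rotations[0].apply(x), x)
        np.testing.assert_array_equal(
            predict_proba(model, x), model.trees[0].predict_proba(x)
        )

    @pytest.mark.parametrize(
        "p_pos,expected", [(0.9, 1), (0.1, -1), (0.5, 1)]
    )
    def test_decision_rule_with_tie_to_positive(self, p_pos, expected):
        assert label_from_proba(p_pos) == expected

    def test_feature_length_mismatch_rejected(self):
        x, y = blobs(seed=0)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=1))
        with pytest.raises(ValueError, match="features"):
            predict(model, np.zeros(7))


class TestEnsembleSize:
    def test_auc_grows_with_ensemble_size_on_planted_data(self):
        """Averaged over 5 seeds, CV AUC is non-decreasing (within noise)
        as the ensemble grows through L = 1, 5, 20."""
        from lpqppi.evaluation import cross_validate
        from lpqppi.pipeline import RunConfig, featurize_pairs
        from lpqppi.synthetic import SyntheticSpec, generate_dataset

        run = RunConfig()
        mean_auc = {}
        datasets = []
        for seed in range(5):
            spec = SyntheticSpec(n_pairs=300, seed=200 + seed)
            records, pairs = generate_dataset(spec)
            datasets.append(featurize_pairs(records, pairs, run)[:2])
        for n_trees in (1, 5, 20):
            aucs = []
            for seed, (features, labels) in enumerate(datasets):
                config = RFConfig(n_subsets=8, n_trees=n_trees, seed=seed)
                report = cross_validate(features, labels, config=config,
                                        k=5, seed=seed)
                aucs.append(report.mean("auc"))
            mean_auc[n_trees] = float(np.mean(aucs))
        assert mean_auc[5] >= mean_auc[1] - 0.02
        assert mean_auc[20] >= mean_auc[5] - 0.02


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path):
        x, y = blobs(seed=10)
        model = train(x, y, RFConfig(n_subsets=2, n_trees=4, seed=6))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_proba(model, x), predict_proba(loaded, x)
        )
        assert loaded.config == model.config
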