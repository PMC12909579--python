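"""Two-tier pipeline: CNN training/truncation, the 70/30 embedding split,
booster configuration from genotypes, and end-to-end behavior on easy data."""

import numpy as np
import pytest

from stageopt._nn import SmallCNN
from stageopt.dual_layer import (
    BoosterClassifier,
    CNNClassifier,
    DualLayerClassifier,
    EmbeddingSet,
    build_booster,
    split_70_30,
    truncate_and_embed,
)
from stageopt.synthetic_data import generate_tabular


@pytest.fixture(scope="module")
def fitted_cnn(tiny_images):
    X, y = tiny_images
    clf = CNNClassifier(
        learning_rate=0.002, dropout=0.1, epochs=12,
        conv_widths=(32,), dense_widths=(48,), seed=0,
    )
    return clf.fit(X, y)


class TestCNNGradients:
    def test_numeric_gradient_check(self):
        rng = np.random.default_rng(0)
        net = SmallCNN([4, 5], [5, 6], dropout=0.0, n_classes=3,
                       input_shape=(8, 8, 3), seed=1)
        X = rng.random((6, 8, 8, 3)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 6)]
        _, probs, caches = net.loss_and_probs(X, y, train=True)
        grads = net._backward(
            (probs - y).astype(np.float32) / np.float32(len(X)), caches
        )
        for li, layer in enumerate(net.layers):
            if layer.w is None:
                continue
            idx = tuple(s - 1 for s in layer.w.shape)
            eps, orig = 1e-3, layer.w[idx]
            layer.w[idx] = orig + eps
            l1, _, _ = net.loss_and_probs(X, y)
            layer.w[idx] = orig - eps
            l2, _, _ = net.loss_and_probs(X, y)
            layer.w[idx] = orig
            numeric = (l1 - l2) / (2 * eps)
            assert grads[li][0][idx] == pytest.approx(numeric, abs=2e-3)


class TestCNNArchitecture:
    def test_genotype_decoding_single_layers(self):
        g = [0.0001, 0.05, 10, 1, 1, 32, 64, 32, 64]
        clf = CNNClassifier.from_genotype(g)
        assert clf.learning_rate == 0.0001
        assert clf.dropout == 0.05
        assert tuple(clf.conv_widths) == (32,)
        assert tuple(clf.dense_widths) == (32,)

    def test_two_conv_blocks_give_8x8_map(self):
        net = SmallCNN([32, 32], [40], dropout=0.1, seed=0)
        # 32 -> 16 -> 8 spatial, so flatten feeds 8*8*32 into the dense layer
        dense = next(l for l in net.layers if l.kind == "dense")
        assert dense.w.shape[0] == 8 * 8 * 32

    def test_parameter_count_positive_finite(self):
        net = SmallCNN([32], [32], dropout=0.05, seed=0)
        assert 0 < net.n_parameters() < np.inf

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SmallCNN([], [32], dropout=0.1)
        with pytest.raises(ValueError):
            SmallCNN([32], [32], dropout=1.0)


class TestCNNTraining:
    def test_learns_separable_data(self, easy_images):
        """High-separability data (200/class, 15 epochs) is learned well."""
        X, y = easy_images
        clf = CNNClassifier(
            learning_rate=0.002, dropout=0.1, epochs=15,
            conv_widths=(32,), dense_widths=(48,), seed=0,
        ).fit(X, y)
        assert clf.validation_mcc_ >= 0.8

    def test_structural_fixture_learns_above_chance(self, fitted_cnn):
        assert fitted_cnn.validation_mcc_ >= 0.3

    def test_seed_reproducibility(self, tiny_images):
        X, y = tiny_images
        kw = dict(learning_rate=0.002, dropout=0.1, epochs=5,
                  conv_widths=(32,), dense_widths=(32,), seed=4)
        r1 = CNNClassifier(**kw).fit(X, y)
        r2 = CNNClassifier(**kw).fit(X, y)
        assert np.array_equal(r1.predict_proba(X[:16]), r2.predict_proba(X[:16]))
        assert r1.validation_mcc_ == r2.validation_mcc_

    def test_empty_training_set_rejected(self):
        clf = CNNClassifier()
        with pytest.raises(ValueError):
            clf.fit(np.empty((0, 32, 32, 3)), np.empty(0, dtype=int))

    def test_shuffled_labels_stay_near_chance(self, easy_images):
        X, y = easy_images
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        clf = CNNClassifier(learning_rate=0.002, dropout=0.1, epochs=8,
                            conv_widths=(32,), dense_widths=(32,), seed=1)
        clf.fit(X, y_shuf)
        assert abs(clf.validation_mcc_) <= 0.15


class TestTrainEvalCNN:
    def test_reports_on_eval_split(self, tiny_images):
        from stageopt.dual_layer import train_eval_cnn

        X, y = tiny_images
        model = CNNClassifier(learning_rate=0.002, dropout=0.1, epochs=6,
                              conv_widths=(32,), dense_widths=(32,), seed=2)
        fitted, report = train_eval_cnn(
            model, (X[:96], y[:96]), (X[96:], y[96:])
        )
        assert fitted is model and hasattr(fitted, "model_")
        assert report.support.sum() == len(X) - 96
        assert -1 <= report.mcc <= 1

    def test_empty_split_rejected(self, tiny_images):
        from stageopt.dual_layer import train_eval_cnn

        X, y = tiny_images
        with pytest.raises(ValueError):
            train_eval_cnn(CNNClassifier(), (X, y),
                           (np.empty((0, 32, 32, 3)), np.empty(0, int)))


class TestEmbeddings:
    def test_width_matches_last_dense(self, fitted_cnn, tiny_images):
        X, y = tiny_images
        emb = truncate_and_embed(fitted_cnn, X, y)
        assert emb.width == 48
        assert len(emb) == len(X)

    def test_inference_determinism(self, fitted_cnn, tiny_images):
        X, _ = tiny_images
        e1 = fitted_cnn.transform(X[:20])
        e2 = fitted_cnn.transform(X[:20])
        assert np.array_equal(e1, e2)  # dropout inactive at inference

    def test_unfitted_transform_rejected(self):
        with pytest.raises(RuntimeError):
            CNNClassifier().transform(np.zeros((1, 32, 32, 3)))

    def test_csv_roundtrip(self, tmp_path):
        X, y = generate_tabular((5, 5, 5, 5), 7, 1.0, seed=0)
        emb = EmbeddingSet(X.astype(np.float32), y)
        path = tmp_path / "emb.csv"
        emb.to_csv(path)
        loaded = EmbeddingSet.from_csv(path)
        assert np.allclose(loaded.features, emb.features, atol=1e-6)
        assert np.array_equal(loaded.labels, emb.labels)


class TestSplit7030:
    def test_sizes_and_stratification(self):
        X, y = generate_tabular((384, 336, 300, 300), 4, 1.0, seed=0)
        emb = EmbeddingSet(X, y)
        tr, te = split_70_30(emb, seed=0)
        assert len(tr) == 924 and len(te) == 396
        for k in range(4):
            n_total = (y == k).sum()
            n_test = (te.labels == k).sum()
            assert abs(n_test - 0.3 * n_total) <= 1

    def test_disjoint_exhaustive(self):
        X, y = generate_tabular((20, 20, 20, 20), 3, 1.0, seed=1)
        emb = EmbeddingSet(X, y)
        tr, te = split_70_30(emb, seed=5)
        joined = np.vstack([tr.features, te.features])
        assert joined.shape[0] == len(emb)
        # every original row appears exactly once
        order = np.lexsort(joined.T)
        orig_order = np.lexsort(X.T)
        assert np.allclose(joined[order], X[orig_order])

    def test_small_class_rejected(self):
        X, y = generate_tabular((5, 20, 20, 20), 3, 1.0, seed=1)
        with pytest.raises(ValueError):
            split_70_30(EmbeddingSet(X, y), seed=0)


class TestBoosters:
    def test_xgb_upper_bound_genotype(self):
        b = build_booster("xgb", [0.9, 5, 1, 1, 5, 0.8])
        model = b._make_model()
        assert model.get_params()["max_depth"] == 5
        assert model.get_params()["learning_rate"] == 0.9

    def test_lgbm_rounds_exactly_trained(self):
        X, y = generate_tabular((30, 30, 30, 30), 6, 3.0, seed=0)
        g = [5, 5, 8, 2, 0.8, 0.9, 0.01, 0.1, 0.1, 0.3]
        b = BoosterClassifier("lgbm", g, seed=0).fit(X, y)
        assert b.model_.booster_.num_trees() == 5 * 4  # rounds x classes

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_booster("catboost", [0.5] * 6)

    def test_wrong_genotype_length(self):
        with pytest.raises(ValueError):
            build_booster("xgb", [0.5] * 10)

    @pytest.mark.parametrize("kind,dim", [("xgb", 6), ("lgbm", 10)])
    def test_learns_separated_clusters(self, kind, dim, rng):
        from stageopt.search_space import builtin_space, sample_uniform

        sp = builtin_space("L2_XGB" if kind == "xgb" else "L2_LGBM")
        X, y = generate_tabular((80,) * 4, 8, 4.0, seed=0, direction_seed=0)
        Xt, yt = generate_tabular((40,) * 4, 8, 4.0, seed=99, direction_seed=0)
        g = sample_uniform(sp, rng)
        b = BoosterClassifier(kind, g, seed=0).fit(X, y)
        assert b.score(Xt, yt) > 0.5


class TestDualLayerPipeline:
    def test_end_to_end_reports(self, tiny_images):
        X, y = tiny_images
        clf = DualLayerClassifier(
            cnn_genotype=[0.002, 0.1, 10, 1, 1, 32, 32, 48, 48],
            booster_kind="lgbm",
            booster_genotype=[15, 6, 8, 2, 0.8, 0.9, 0.01, 0.1, 0.1, 0.3],
            seed=0,
        ).fit(X, y)
        assert clf.embeddings_.width == 48
        assert len(clf.embeddings_) == len(X)
        assert clf.l2_report_.mcc >= clf.l1_report_.mcc - 0.2
        assert 0 <= clf.l2_report_.accuracy <= 1

    def test_predict_chain(self, tiny_images):
        X, y = tiny_images
        clf = DualLayerClassifier(
            cnn_genotype=[0.002, 0.1, 8, 1, 1, 32, 32, 32, 32],
            booster_kind="xgb",
            booster_genotype=[0.5, 2, 0.9, 0.9, 3, 0.1],
            seed=1,
        ).fit(X, y)
        preds = clf.predict(X[:10])
        assert preds.shape == (10,)
        assert set(preds) <= {0, 1, 2, 3}
        assert clf.predict_proba(X[:10]).shape == (10, 4)

    def test_sklearn_param_interface(self):
        clf = DualLayerClassifier(seed=3)
        params = clf.get_params()
        assert params["seed"] == 3
        clf.set_params(booster_kind="xgb")
        assert clf.booster_kind == "xgb"
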