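"""CNN architecture, training loop behavior, HOG and SVM baselines."""

import numpy as np
import pytest

import pelagiscan as p
from pelagiscan import nn
from pelagiscan.classifiers import HOGParams, hog_features, train_svm

from conftest import make_toy_dataset


class TestArchitecture:
    def test_flatten_lengths_read_from_layer_shapes(self):
        cfg = p.CNNConfig()
        model = p.build_cnn(cfg, "fused", seed=0)
        lengths = model.flatten_lengths()
        assert lengths["spatial"] == 65_536  # 64 x 64 x 16 after two 2x pools
        assert lengths["spectral"] == 100  # 50 x 2 after two 2x pools
        assert model.feature_length == 65_636

    def test_channel_shape_flow(self):
        cfg = p.CNNConfig()
        shapes = p.build_cnn(cfg, "fused", seed=0).channel_output_shapes()
        assert shapes["spatial"][0] == (8, 256, 256)  # conv1
        assert shapes["spatial"][3] == (8, 128, 128)  # pool1
        assert shapes["spatial"][8] == (16, 64, 64)  # pool2
        assert shapes["spectral"][3] == (4, 100)
        assert shapes["spectral"][8] == (2, 50)

    def test_signature_length_must_survive_two_pools(self):
        with pytest.raises(ValueError, match="survive two pools"):
            p.CNNConfig(input_signature_length=201)

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        probs = nn.softmax(rng.normal(size=(100, 5)) * 10)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_probabilities_tie_break_to_first_class(self):
        cfg = p.CNNConfig(classes=("a", "b"), image_size=8,
                          input_signature_length=8)
        model = p.build_cnn(cfg, "spectral", seed=0)
        for layer in model._all_layer_lists():
            for k in layer.params:
                layer.params[k] = np.zeros_like(layer.params[k])
        ds = make_toy_dataset(4, classes=("a", "b"), image_size=8, sig_len=8)
        labels, probs = p.predict(model, ds)
        np.testing.assert_allclose(probs, 0.5)
        assert (labels == "a").all()


class TestGradients:
    def numerical_grad(self, f, param, eps=1e-6):
        grad = np.zeros_like(param)
        it = np.nditer(param, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = param[idx]
            param[idx] = orig + eps
            hi = f()
            param[idx] = orig - eps
            lo = f()
            param[idx] = orig
            grad[idx] = (hi - lo) / (2 * eps)
            it.iternext()
        return grad

    def test_backprop_matches_numerical_gradients(self):
        """End-to-end gradient check of the fused network (dropout off)."""
        cfg = p.CNNConfig(classes=("a", "b", "c"), image_size=8,
                          input_signature_length=8, dropout=0.0,
                          hidden_units=6)
        model = p.build_cnn(cfg, "fused", seed=1)
        rng = np.random.default_rng(2)
        xi = rng.random((4, 3, 8, 8))
        xs = rng.random((4, 1, 8))
        y = np.eye(3)[rng.integers(0, 3, 4)]

        def loss_fn():
            logits = model.forward(xi, xs, train=True)
            loss, _ = nn.softmax_cross_entropy(logits, y)
            return loss

        logits = model.forward(xi, xs, train=True)
        _, dlogits = nn.softmax_cross_entropy(logits, y)
        model.backward(dlogits)

        checked = 0
        rng_pick = np.random.default_rng(3)
        for layer in model._all_layer_lists():
            for key, param in layer.params.items():
                analytic = layer.grads[key]
                # spot-check a handful of coordinates per parameter tensor
                flat_idx = rng_pick.choice(param.size,
                                           size=min(4, param.size),
                                           replace=False)
                for fi in flat_idx:
                    idx = np.unravel_index(fi, param.shape)
                    orig = param[idx]
                    eps = 1e-6
                    param[idx] = orig + eps
                    hi = loss_fn()
                    param[idx] = orig - eps
                    lo = loss_fn()
                    param[idx] = orig
                    num = (hi - lo) / (2 * eps)
                    assert analytic[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)
                    checked += 1
        assert checked > 30


class TestTraining:
    def separable_dataset(self, n=12):
        return make_toy_dataset(
            n, classes=("lo", "hi"), image_size=8, sig_len=8,
            sig_offsets={"lo": 0.2, "hi": 0.8},
        )

    def test_separable_toy_reaches_zero_training_error(self):
        ds = self.separable_dataset()
        cfg = p.CNNConfig(classes=("lo", "hi"), image_size=8,
                          input_signature_length=8)
        model = p.build_cnn(cfg, "spectral", seed=0)
        model, history = p.train_cnn(
            model, ds, p.TrainConfig(max_epochs=60, patience=60, seed=0)
        )
        yhat, _ = p.predict(model, ds)
        assert (yhat == ds.labels()).mean() == 1.0
        assert history.stopped_epoch <= 60

    def test_early_stopping_waits_exactly_patience_epochs(self):
        # random labels: validation loss plateaus almost immediately
        rng = np.random.default_rng(0)
        ds = make_toy_dataset(20, classes=("a", "b"), image_size=8, sig_len=8)
        cfg = p.CNNConfig(classes=("a", "b"), image_size=8,
                          input_signature_length=8)
        model = p.build_cnn(cfg, "spectral", seed=0)
        model, history = p.train_cnn(
            model, ds, p.TrainConfig(max_epochs=200, patience=4, seed=0)
        )
        assert history.stopped_epoch < 200
        assert history.stopped_epoch - history.best_epoch == 4

    def test_same_seed_gives_identical_history(self):
        ds = self.separable_dataset()
        cfg = p.CNNConfig(classes=("lo", "hi"), image_size=8,
                          input_signature_length=8)
        histories = []
        for _ in range(2):
            model = p.build_cnn(cfg, "spectral", seed=7)
            _, h = p.train_cnn(model, ds,
                               p.TrainConfig(max_epochs=10, patience=10, seed=7))
            histories.append(h)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_single_class_rejected(self):
        ds = make_toy_dataset(6, classes=("only",), image_size=8, sig_len=8)
        cfg = p.CNNConfig(classes=("only", "other"), image_size=8,
                          input_signature_length=8)
        model = p.build_cnn(cfg, "spectral", seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            p.train_cnn(model, ds, p.TrainConfig(seed=0))

    def test_prediction_is_deterministic(self):
        ds = self.separable_dataset(6)
        cfg = p.CNNConfig(classes=("lo", "hi"), image_size=8,
                          input_signature_length=8)
        model = p.build_cnn(cfg, "fused", seed=0)
        a = p.predict(model, ds)[1]
        b = p.predict(model, ds)[1]
        np.testing.assert_array_equal(a, b)


class TestHOG:
    def test_default_descriptor_length(self):
        img = p.RGBImage(
            np.random.default_rng(0).integers(0, 256, (256, 256, 3), dtype=np.uint8)
        )
        feats = hog_features(img)
        # (16 - 4 + 1)^2 blocks x 4*4 cells x 8 bins
        assert feats.shape == (13 * 13 * 4 * 4 * 8,)
        assert feats.shape == (21_632,)

    def test_constant_image_gives_zero_descriptor(self):
        img = p.RGBImage(np.full((256, 256, 3), 77, dtype=np.uint8))
        assert (hog_features(img) == 0).all()

    def test_horizontal_ramp_concentrates_in_one_orientation_bin(self):
        ramp = np.tile(np.arange(64, dtype=np.uint8) * 4, (64, 1))
        img = p.RGBImage(np.stack([ramp] * 3, axis=2))
        feats = hog_features(img, HOGParams(pixels_per_cell=(16, 16),
                                            cells_per_block=(2, 2)))
        bins = feats.reshape(-1, 8)
        nonzero_bins = {int(np.argmax(row)) for row in bins if row.any()}
        assert len(nonzero_bins) == 1

    def test_incompatible_size_rejected(self):
        img = p.RGBImage(np.zeros((100, 100, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="incompatible"):
            hog_features(img)


class TestSVM:
    def test_separable_points_classified_perfectly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = train_svm(x, y)
        assert (clf.predict(x) == y).mean() == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(np.ones((4, 2)), np.array(["a"] * 4))

    def test_pixel_feature_width(self):
        ds = make_toy_dataset(3, classes=("a", "b"), image_size=256, sig_len=8)
        feats = p.SVMBaseline("pixels").features(ds)
        assert feats.shape[1] == 256 * 256 * 3 == 196_608

    def test_concatenated_widths_are_additive(self):
        ds = make_toy_dataset(3, classes=("a", "b"), image_size=64, sig_len=40)
        hog_w = p.SVMBaseline("hog").features(ds).shape[1]
        spec_w = p.SVMBaseline("spectral").features(ds).shape[1]
        both = p.SVMBaseline("hog+spectral").features(ds).shape[1]
        assert spec_w == 40 and both == hog_w + spec_w

    def test_baseline_fit_predict_on_separable_signatures(self):
        ds = make_toy_dataset(10, classes=("lo", "hi"), image_size=8, sig_len=8,
                              sig_offsets={"lo": 0.2, "hi": 0.8})
        baseline = p.SVMBaseline("spectral").fit(ds)
        assert (baseline.predict(ds) == ds.labels()).mean() == 1.0
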