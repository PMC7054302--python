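"""The pixel-wise and slice-wise CNNs: contracts, gradients, training."""

import numpy as np
import pytest

from hyse import (
    CnnArchitecture,
    TrainingConfig,
    build_pixel_cnn,
    build_slice_cnn,
    cross_validate,
    make_folds,
    make_reference_library,
    make_training_pool,
)
from hyse import nn as hnn
from hyse.cnn import load_model


@pytest.fixture(scope="module")
def separable_set():
    """400 patches from 4 well-separated spectral prototypes."""
    rng = np.random.default_rng(0)
    protos = rng.random((4, 121))
    y = rng.integers(4, size=400)
    x = protos[y] + rng.normal(0, 0.02, (400, 121))
    return x.reshape(-1, 11, 11), y


@pytest.fixture(scope="module")
def trained_on_separable(separable_set):
    patches, y = separable_set
    model = build_pixel_cnn(seed=0)
    log = model.fit(patches, y, TrainingConfig(max_epochs=40, seed=0))
    return model, log


class TestPixelCnnContracts:
    def test_forward_is_19_way_softmax(self, rng):
        model = build_pixel_cnn(seed=1)
        probs = model.forward_probs(rng.random((5, 11, 11)))
        assert probs.shape == (5, 19)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_seed_determines_initialization(self):
        a = build_pixel_cnn(seed=3)
        b = build_pixel_cnn(seed=3)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)
        c = build_pixel_cnn(seed=4)
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.net.params(), c.net.params())
        )

    def test_inference_is_deterministic_dropout_off(self, rng):
        model = build_pixel_cnn(seed=0)
        x = rng.random((3, 11, 11))
        np.testing.assert_array_equal(model.forward_probs(x), model.forward_probs(x))

    def test_dropout_active_in_training_mode(self, rng):
        model = build_pixel_cnn(seed=0)
        x = rng.random((8, 11, 11))
        a = model.forward_probs(x, train=True)
        b = model.forward_probs(x, train=True)
        assert not np.array_equal(a, b)

    def test_bad_architecture_rejected(self):
        with pytest.raises(ValueError, match="2 conv"):
            build_pixel_cnn(CnnArchitecture(conv_layers=[(8, 3)], fc_layers=[32, 19]))

    def test_untrained_classification_rejected(self, rng):
        with pytest.raises(RuntimeError, match="trained"):
            build_pixel_cnn(seed=0).classify_slice(rng.random((4, 11, 11)))

    def test_label_out_of_range_rejected(self, rng):
        model = build_pixel_cnn(seed=0)
        with pytest.raises(ValueError, match="labels"):
            model.fit(rng.random((4, 11, 11)), np.array([0, 1, 2, 19]))


class TestTrainingDynamics:
    def test_zero_learning_rate_is_identity(self, separable_set):
        patches, y = separable_set
        model = build_pixel_cnn(seed=5)
        before = [p.value.copy() for p in model.net.params()]
        model.fit(patches[:100], y[:100], TrainingConfig(
            max_epochs=3, learning_rate=0.0, seed=0))
        for p, b in zip(model.net.params(), before):
            np.testing.assert_array_equal(p.value, b)

    def test_first_sgd_step_is_minus_lr_times_gradient(self):
        """With momentum starting from rest, step 1 moves by exactly -lr*g."""
        rng = np.random.default_rng(0)
        conv = hnn.Conv2D(1, 2, (1, 1), rng)
        net = hnn.Sequential([conv])
        x = rng.random((4, 1, 1, 1))
        y = np.array([0, 1, 0, 1])[:, None, None]
        net.zero_grad()
        logits = net.forward(x, train=True)
        _, dlogits = hnn.softmax_cross_entropy(logits, y)
        net.backward(dlogits)
        grads = [p.grad.copy() for p in net.params()]
        before = [p.value.copy() for p in net.params()]
        opt = hnn.MomentumSGD(net.params(), lr=0.01, momentum=0.9, weight_decay=0.0)
        opt.step()
        for p, g, b in zip(net.params(), grads, before):
            np.testing.assert_allclose(p.value, b - 0.01 * g, atol=1e-12)

    def test_gradients_match_finite_differences(self):
        """Backprop agrees with central finite differences to 1e-4."""
        rng = np.random.default_rng(1)
        net = hnn.Sequential([
            hnn.Conv2D(1, 2, (2, 2), rng),
            hnn.ReLU(),
            hnn.Conv2D(2, 3, (2, 2), rng),
        ])
        x = rng.random((3, 1, 3, 3))
        y = rng.integers(3, size=(3, 1, 1))

        def loss_value():
            logits = net.forward(x, train=False)
            return hnn.softmax_cross_entropy(logits, y)[0]

        net.zero_grad()
        logits = net.forward(x, train=False)
        _, dlogits = hnn.softmax_cross_entropy(logits, y)
        net.backward(dlogits)
        eps = 1e-6
        for p in net.params():
            flat = p.value.ravel()
            gflat = p.grad.ravel()
            for idx in range(0, flat.size, max(flat.size // 10, 1)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_value()
                flat[idx] = orig - eps
                down = loss_value()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, abs=1e-4)

    def test_overfits_separable_set(self, trained_on_separable, separable_set):
        patches, y = separable_set
        model, log = trained_on_separable
        assert (model.predict(patches) == y).mean() >= 0.99
        assert log.stopped_epoch <= 200

    def test_loss_descends_after_smoothing(self, trained_on_separable):
        _, log = trained_on_separable
        losses = np.array(log.losses)
        smoothed = np.convolve(losses, np.ones(10) / 10, mode="valid")
        assert (np.diff(smoothed) <= 1e-3).all()

    def test_early_stopping_fires_on_plateau(self, separable_set):
        patches, y = separable_set
        model = build_pixel_cnn(seed=2)
        log = model.fit(
            patches[:200], y[:200],
            TrainingConfig(max_epochs=120, patience=5, seed=0),
            val_patches=patches[200:], val_labels=y[200:],
        )
        assert log.early_stopped
        assert log.stopped_epoch < 120


class TestModelPersistence:
    def test_roundtrip(self, tmp_path, trained_on_separable, separable_set):
        patches, _ = separable_set
        model, _ = trained_on_separable
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict(patches), model.predict(patches))
        assert back.trained


class TestSliceCnn:
    _small_arch = CnnArchitecture(
        conv_layers=[(8, 3), (8, 3), (16, 3), (16, 3)], fc_layers=[32, 19]
    )

    def test_per_pixel_output_shape(self, rng):
        model = build_slice_cnn(self._small_arch, seed=0, n_bins=121)
        probs = model.forward_probs(rng.random((2, 9, 121)))
        assert probs.shape == (2, 19, 9)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_seed_determines_initialization(self):
        a = build_slice_cnn(self._small_arch, seed=3)
        b = build_slice_cnn(self._small_arch, seed=3)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_bad_architecture_rejected(self):
        with pytest.raises(ValueError, match="4 conv"):
            build_slice_cnn(CnnArchitecture(), seed=0)

    def test_head_to_head_with_pixel_cnn(self):
        """On a tiny separable slice task the two variants land within a few
        points of each other (the slice-wise one was the weaker performer)."""
        rng = np.random.default_rng(0)
        protos = rng.random((4, 121))
        ny = 6
        n_slices = 40
        block_labels = rng.integers(4, size=(n_slices, 2))
        labels = np.repeat(block_labels, ny // 2, axis=1)  # (n, ny)
        slices = protos[labels] + rng.normal(0, 0.02, (n_slices, ny, 121))
        cfg = TrainingConfig(max_epochs=120, batch_size=8, learning_rate=0.003, seed=0)

        slice_model = build_slice_cnn(self._small_arch, seed=0, n_bins=121)
        slice_model.fit(slices[:32], labels[:32], cfg)
        slice_acc = (slice_model.predict(slices[32:]) == labels[32:]).mean()

        pixel_model = build_pixel_cnn(seed=0)
        patches = slices.reshape(-1, 121).reshape(-1, 11, 11)
        flat = labels.reshape(-1)
        split = 32 * ny
        pixel_model.fit(patches[:split], flat[:split], cfg)
        pixel_acc = (pixel_model.predict(patches[split:]) == flat[split:]).mean()

        assert abs(pixel_acc - slice_acc) <= 0.05


class TestCrossValidation:
    def test_fold_partition_properties(self):
        base_ids = np.repeat(np.arange(12), 3)  # 12 groups of 3 pool cubes
        folds = make_folds(base_ids, k=5, seed=0)
        assert len(folds) == 5
        merged = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(merged, np.arange(len(base_ids)))
        group_counts = [len(np.unique(base_ids[f])) for f in folds]
        assert max(group_counts) - min(group_counts) <= 1

    def test_no_base_cube_straddles_folds(self):
        rng = np.random.default_rng(0)
        base_ids = rng.integers(0, 12, size=60)
        folds = make_folds(base_ids, k=5, seed=1)
        fold_groups = [set(base_ids[f].tolist()) for f in folds]
        for i in range(5):
            for j in range(i + 1, 5):
                assert fold_groups[i].isdisjoint(fold_groups[j])

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            make_folds(np.arange(3), k=5)

    def test_cross_validate_reports_per_fold(self):
        library = make_reference_library(seed=0, n_wavelengths=242)
        pool = make_training_pool(
            library, n_replicates=2, n_augmented=8, seed=0, shape=(2, 16, 242)
        )
        cfg = TrainingConfig(max_epochs=2, batch_size=32, seed=0)
        reports = cross_validate(
            pool, k=5, config=cfg, n_per_cube=12, n_val_per_cube=8,
            n_slices_per_cube=2,
        )
        assert len(reports) == 5
        for report in reports:
            assert 0.0 <= report.acc_av <= 100.0
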