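import numpy as np
import pytest

from tissuediff import (
    AEClassifierConfig,
    CNNConfig,
    RFConfig,
    combined_loss,
    make_windows,
    predict_recording_proba,
    smoke_train_config,
    train_ae_nn,
    train_cnn,
    train_rf,
)
from tissuediff.classifiers import AENet, ResNet1d
from tissuediff.evaluation import make_group_folds

from conftest import fold_tables


class TestCombinedLoss:
    def test_alpha_zero_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, 20)
        recon = rng.normal(size=(20, 9))
        target = rng.normal(size=(20, 9))
        from tissuediff._nn import cross_entropy

        ce, _ = cross_entropy(logits, labels)
        assert combined_loss(logits, labels, recon, target, 0.0) == pytest.approx(ce)

    def test_perfect_reconstruction_reduces_to_cross_entropy(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(20, 2))
        labels = rng.integers(0, 2, 20)
        x = rng.normal(size=(20, 9))
        from tissuediff._nn import cross_entropy

        ce, _ = cross_entropy(logits, labels)
        for alpha in (0.3, 1.0, 7.5):
            assert combined_loss(logits, labels, x, x, alpha) == pytest.approx(ce)

    def test_hand_computed_single_sample_case(self):
        # uniform 2-class softmax gives CE = ln 2; one unit error over nine
        # features gives MSE = 1/9; alpha = 0.3
        logits = np.array([[0.0, 0.0]])
        recon = np.zeros((1, 9))
        recon[0, 0] = 1.0
        target = np.zeros((1, 9))
        value = combined_loss(logits, np.array([0]), recon, target, 0.3)
        assert value == pytest.approx(np.log(2) + 0.3 * (1 / 9), abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((3, 2)), np.zeros(2, dtype=int),
                          np.zeros((3, 9)), np.zeros((3, 9)), 0.3)


def test_ae_parameter_count_matches_closed_form():
    cfg = AEClassifierConfig()
    net = AENet(cfg, np.random.default_rng(0))
    d, e, z, c, k, n = 9, 32, 9, 32, 4, 2
    expected = (d * e + e) + (e * z + z) + (z * c + c) + (c * d + d) \
        + (z * k + k) + (k * n + n)
    assert cfg.n_parameters == expected
    assert net.n_parameters == expected


class TestMakeWindows:
    def test_thousand_samples_yield_937_windows(self):
        x = np.random.default_rng(0).normal(size=(9, 1000))
        windows, targets = make_windows(x, 64)
        assert windows.shape == (937, 9, 64)
        assert targets[0] == 63 and targets[-1] == 999
        # each window ends exactly at its target sample
        assert np.array_equal(windows[0], x[:, 0:64])
        assert np.array_equal(windows[-1], x[:, 936:1000])

    def test_exact_window_length_yields_one(self):
        windows, targets = make_windows(np.zeros((9, 64)), 64)
        assert windows.shape[0] == 1
        assert targets.tolist() == [63]

    def test_one_short_yields_none(self):
        windows, targets = make_windows(np.zeros((9, 63)), 64)
        assert windows.shape[0] == 0
        assert targets.size == 0


class TestCNNArchitecture:
    def test_temporal_trace_halves_at_each_block(self):
        net = ResNet1d(CNNConfig(), np.random.default_rng(0))
        assert net.temporal_trace() == [64, 32, 16, 8]

    def test_seven_convolutional_layers(self):
        assert CNNConfig().n_conv_layers == 7

    def test_forward_shape_and_probability_rows(self):
        rng = np.random.default_rng(1)
        net = ResNet1d(CNNConfig(), rng)
        logits = net.forward(rng.normal(size=(5, 9, 64)))
        assert logits.shape == (5, 2)

    def test_window_shorter_than_downsampling_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(window=4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(kernel=6)


class TestRandomForest:
    def test_separable_clouds_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (100, 9)), rng.normal(10, 1, (100, 9))])
        y = np.array(["soft"] * 100 + ["very_soft"] * 100)
        model = train_rf(X, y, RFConfig(seed=0))
        assert (model.predict(X) == y).mean() == 1.0
        probs = model.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_identical_feature_distributions_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(3000, 9))
        y = np.where(rng.random(3000) < 0.5, "soft", "very_soft")
        model = train_rf(X[:2000], y[:2000], RFConfig(seed=1))
        acc = (model.predict(X[2000:]) == y[2000:]).mean()
        assert acc == pytest.approx(0.5, abs=0.1)

    def test_same_seed_gives_identical_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 9))
        y = np.where(X[:, 0] + rng.normal(0, 2, 300) > 0, "soft", "very_soft")
        a = train_rf(X, y, RFConfig(seed=5)).predict_proba(X)
        b = train_rf(X, y, RFConfig(seed=5)).predict_proba(X)
        assert np.array_equal(a, b)

    def test_single_class_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_rf(np.zeros((10, 9)), np.repeat("soft", 10))


@pytest.fixture(scope="module")
def fold_data(separable_dataset):
    fold = make_group_folds(separable_dataset, k=5, seed=7)[0]
    return fold_tables(separable_dataset, fold)


class TestAETraining:
    def test_recovers_separable_classes(self, fold_data):
        Xtr, ytr = fold_data["train"]
        Xva, yva = fold_data["val"]
        Xte, yte = fold_data["test"]
        model = train_ae_nn(Xtr, ytr, Xva, yva, train_cfg=smoke_train_config(seed=1))
        from sklearn.metrics import f1_score

        f1 = f1_score(yte, model.predict(Xte), average="macro")
        assert f1 >= 0.95

    def test_training_loss_descends(self, fold_data):
        Xtr, ytr = fold_data["train"]
        Xva, yva = fold_data["val"]
        model = train_ae_nn(Xtr, ytr, Xva, yva, train_cfg=smoke_train_config(seed=2))
        hist = model.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

    def test_same_seed_gives_identical_predictions(self, fold_data):
        Xtr, ytr = fold_data["train"]
        Xva, yva = fold_data["val"]
        cfg = smoke_train_config(seed=3, max_epochs=5)
        a = train_ae_nn(Xtr, ytr, Xva, yva, train_cfg=cfg).predict_proba(Xva)
        b = train_ae_nn(Xtr, ytr, Xva, yva, train_cfg=cfg).predict_proba(Xva)
        assert np.array_equal(a, b)

    def test_probability_rows_sum_to_one(self, fold_data):
        Xtr, ytr = fold_data["train"]
        Xva, yva = fold_data["val"]
        model = train_ae_nn(Xtr, ytr, Xva, yva,
                            train_cfg=smoke_train_config(seed=4, max_epochs=3))
        probs = model.predict_proba(Xva)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_empty_validation_set_rejected(self, fold_data):
        Xtr, ytr = fold_data["train"]
        with pytest.raises(ValueError):
            train_ae_nn(Xtr, ytr, np.empty((0, 9)), np.empty(0),
                        train_cfg=smoke_train_config())


class TestCNNTraining:
    def test_tiny_training_descends_and_aligns_predictions(self, separable_dataset):
        """Short CNN run on two recordings per class: loss goes down and a
        1000-sample recording receives exactly 937 aligned predictions."""
        fold = make_group_folds(separable_dataset, k=5, seed=7)[0]
        data = fold_tables(separable_dataset, fold)
        norm, windows, labels = data["normalizer"], data["windows"], data["labels"]

        def recs(ids):
            return [(norm.transform(windows[r].T).T, labels[r], r) for r in ids]

        # two recordings from each class (train_ids is sorted by class prefix)
        train_sub = fold.train_ids[:2] + fold.train_ids[-2:]
        cfg = smoke_train_config(seed=5, max_epochs=3)
        model = train_cnn(recs(train_sub), recs(fold.val_ids), train_cfg=cfg)
        hist = model.history
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]

        samples = norm.transform(windows[fold.test_ids[0]].T).T
        probs, targets = predict_recording_proba(model, samples)
        assert probs.shape == (937, 2)
        assert targets[0] == 63 and targets[-1] == 999
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
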