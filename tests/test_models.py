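import numpy as np
import pytest

from swisc import errors
from swisc.dataset import encode_onehot, make_sequences
from swisc.io import FeatureMatrix, StateLabels
from swisc.models import (ModelConfig, build_model, load_model, save_model,
                          swisc_config, train, train_svm)
from swisc.nn import Nadam
from swisc.states import STATES


def blobs(rng, n_per_class, n_features=8, classes=("wake", "NREM"), sep=4.0):
    """Well-separated Gaussian clusters, one per state."""
    xs, ys = [], []
    for k, state in enumerate(classes):
        center = np.zeros(n_features)
        center[k % n_features] = sep * (k + 1)
        xs.append(rng.standard_normal((n_per_class, n_features)) + center)
        ys.extend([state] * n_per_class)
    x = np.vstack(xs)
    manifest = [f"f{i}" for i in range(n_features)]
    fm = FeatureMatrix(values=x, feature_set="full", manifest=manifest,
                       epoch_len_s=20.0)
    return fm, StateLabels(labels=np.array(ys, dtype=object))


class TestBuildModel:
    @pytest.mark.parametrize("family,l_out", [
        ("dense", 50), ("lstm", 50), ("bilstm", 100), ("stacked_bilstm", 13)])
    def test_output_is_probability_simplex(self, rng, family, l_out):
        cfg = ModelConfig(family=family, seq_len=3, layer_size=50, seed=0)
        net = build_model(cfg, n_features=12)
        probs = net.predict_proba(rng.standard_normal((6, 3, 12)))
        assert probs.shape == (6, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_bilstm_width_is_twice_layer_size(self):
        cfg = ModelConfig(family="bilstm", seq_len=7, layer_size=200)
        net = build_model(cfg, n_features=100)
        h = net.layers[0].forward(np.zeros((2, 7, 100)), train=False)
        assert h.shape == (2, 7, 400)  # 200 units per direction

    def test_stacked_layers_halve(self):
        cfg = ModelConfig(family="stacked_bilstm", seq_len=3, layer_size=200)
        net = build_model(cfg, n_features=10)
        widths = [layer.units for layer in net.layers[:4]]
        assert widths == [200, 100, 50, 25]

    def test_even_seq_len_rejected(self):
        with pytest.raises(errors.ConfigError):
            ModelConfig(family="bilstm", seq_len=4)

    def test_swisc_reference_config(self):
        cfg = swisc_config()
        assert (cfg.family, cfg.seq_len, cfg.layer_size) == ("bilstm", 7, 200)
        assert cfg.l1_activity == pytest.approx(1e-4)
        assert cfg.dropout == pytest.approx(0.4)


class TestTraining:
    def test_separable_classes_learned(self, rng):
        fm, labels = blobs(rng, 100)
        cfg = ModelConfig(family="bilstm", seq_len=1, layer_size=16,
                          max_train_epochs=20, seed=0)
        model = train(cfg, fm, labels, epochs_per_file=32)
        _, pred = model.predict(fm)
        assert (pred.labels == labels.labels).mean() > 0.95
        assert set(model.history) >= {"loss", "accuracy", "precision", "recall"}

    def test_early_stop_fires_on_plateau(self, rng):
        fm, labels = blobs(rng, 30)
        # zero learning rate -> loss never improves -> patience (5) exhausts
        cfg = ModelConfig(family="dense", seq_len=1, layer_size=4,
                          max_train_epochs=30, learning_rate=0.0, seed=0)
        model = train(cfg, fm, labels)
        # the first plateau epoch sets the baseline; patience exhausts after
        # five further non-improving epochs, i.e. at epoch 6 of the plateau
        assert len(model.history["loss"]) == 6

    def test_seeded_training_is_reproducible(self, rng):
        fm, labels = blobs(rng, 40)
        cfg = ModelConfig(family="lstm", seq_len=3, layer_size=8,
                          max_train_epochs=5, seed=42)
        h1 = train(cfg, fm, labels).history["loss"]
        h2 = train(cfg, fm, labels).history["loss"]
        assert h1 == h2

    def test_dropout_only_during_training(self, rng):
        cfg = ModelConfig(family="bilstm", seq_len=3, layer_size=8,
                          dropout=0.4, seed=0)
        net = build_model(cfg, n_features=6)
        x = rng.standard_normal((4, 3, 6))
        a = net.predict_proba(x)
        b = net.predict_proba(x)
        np.testing.assert_array_equal(a, b)  # inference deterministic
        c = net.predict_proba(x, train=True)
        assert not np.allclose(a, c)  # dropout perturbs the training pass

    def test_misaligned_inputs_rejected(self, rng):
        fm, labels = blobs(rng, 10)
        short = StateLabels(labels=labels.labels[:-1])
        with pytest.raises(errors.ConfigError):
            train(ModelConfig(family="dense", seq_len=1, layer_size=4), fm, short)


class TestSvm:
    def test_separable_blobs(self, rng):
        fm, labels = blobs(rng, 150)
        cfg = ModelConfig(family="svm", seq_len=1, seed=0)
        model = train(cfg, fm, labels)  # dispatches to train_svm
        _, pred = model.predict(fm)
        assert (pred.labels == labels.labels).mean() > 0.95

    def test_five_class_labels_in_alphabet(self, rng):
        fm, labels = blobs(rng, 40, classes=STATES)
        model = train_svm(ModelConfig(family="svm", seq_len=1, seed=0),
                          fm, labels)
        probs, pred = model.predict(fm)
        assert set(pred.labels) <= set(STATES)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self, rng):
        fm, labels = blobs(rng, 20, classes=("wake",))
        with pytest.raises(errors.SwiscError):
            train_svm(ModelConfig(family="svm", seq_len=1), fm, labels)


class TestPredictContracts:
    def test_manifest_mismatch_rejected(self, rng):
        fm, labels = blobs(rng, 30)
        cfg = ModelConfig(family="dense", seq_len=1, layer_size=4,
                          max_train_epochs=2, seed=0)
        model = train(cfg, fm, labels)
        other = FeatureMatrix(values=fm.values,
                              manifest=[f"g{i}" for i in range(fm.n_features)],
                              feature_set="full", epoch_len_s=20.0)
        with pytest.raises(errors.CompatibilityError):
            model.predict(other)

    def test_serialization_roundtrip(self, rng, tmp_path):
        fm, labels = blobs(rng, 30, classes=("wake", "NREM", "REM"))
        cfg = ModelConfig(family="bilstm", seq_len=3, layer_size=8,
                          max_train_epochs=3, seed=1)
        model = train(cfg, fm, labels)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        p1, _ = model.predict(fm)
        p2, _ = back.predict(fm)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_svm_serialization_roundtrip(self, rng, tmp_path):
        fm, labels = blobs(rng, 30)
        model = train_svm(ModelConfig(family="svm", seq_len=1, seed=0), fm, labels)
        save_model(model, tmp_path / "svm")
        back = load_model(tmp_path / "svm")
        _, a = model.predict(fm)
        _, b = back.predict(fm)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestNadam:
    def test_descends_simple_quadratic(self):
        params = {"w": np.array([5.0])}
        opt = Nadam(lr=0.1)
        for _ in range(200):
            opt.step(params, {"w": 2 * params["w"]})
        assert abs(params["w"][0]) < 0.1
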