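"""The five classifier families and their training schedule.

Families: a linear SVM baseline (hinge loss, L2, stochastic gradient descent,
1,000 iterations) and four sequence networks — dense, LSTM, BiLSTM and a
four-layer Stacked-BiLSTM whose layers halve in width. The networks end in a
five-way softmax, train under Nadam on class-weighted categorical
cross-entropy, and stop early when the monitored loss improves by less than
0.001 for five consecutive training epochs.

The reference configuration (seq-7 input windows over the full 100-feature
vectors, a 200-unit-per-direction BiLSTM with 40% dropout and an L1 activity
penalty of 1e-4) is exposed as :func:`swisc_config`.

A trained model remembers the feature manifest it was fitted on (as a hash)
and refuses to score feature matrices with a different layout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
from sklearn.linear_model import SGDClassifier

from . import nn
from .dataset import compute_class_weights, encode_onehot, make_sequences
from .errors import CompatibilityError, ConfigError, SwiscError
from .io import FeatureMatrix, StateLabels
from .states import N_STATES, STATES, as_names

FAMILIES = ("svm", "dense", "lstm", "bilstm", "stacked_bilstm")


@dataclasses.dataclass
class ModelConfig:
    """Architecture and training hyperparameters for one classifier."""

    family: str = "bilstm"
    feature_set: str = "full"
    seq_len: int = 7
    layer_size: int = 200
    dropout: float = 0.4
    l1_activity: float = 0.0
    n_classes: int = N_STATES
    batch_size: int | None = None  # None -> epochs-per-file of the data
    max_train_epochs: int = 20
    early_stop_delta: float = 1e-3
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    standardize: bool = True
    mask: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.seq_len % 2 == 0 or self.seq_len < 1:
            raise ConfigError("sequence length must be odd and >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["mask"] is not None:
            d["mask"] = list(d["mask"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("mask") is not None:
            d["mask"] = tuple(d["mask"])
        return cls(**d)


def swisc_config(**overrides) -> ModelConfig:
    """The reference sleep/seizure classifier configuration."""
    cfg = dict(family="bilstm", feature_set="full", seq_len=7, layer_size=200,
               dropout=0.4, l1_activity=1e-4, max_train_epochs=60)
    cfg.update(overrides)
    return ModelConfig(**cfg)


def manifest_hash(manifest: list[str], epoch_len_s: float | None = None) -> str:
    payload = json.dumps({"manifest": list(manifest)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_model(config: ModelConfig, n_features: int) -> nn.SequenceClassifier:
    """Assemble the layer stack of a neural family (SVMs are fit directly)."""
    L = config.layer_size
    if config.family == "dense":
        layers = [nn.TimeDense(L), nn.Flatten(), nn.Dense(config.n_classes)]
    elif config.family == "lstm":
        layers = [nn.LSTM(L), nn.Dropout(config.dropout), nn.Flatten(),
                  nn.Dense(config.n_classes)]
    elif config.family == "bilstm":
        layers = [nn.BiLSTM(L, activity_l1=config.l1_activity),
                  nn.Dropout(config.dropout), nn.Flatten(),
                  nn.Dense(config.n_classes)]
    elif config.family == "stacked_bilstm":
        layers = [nn.BiLSTM(L), nn.BiLSTM(L // 2), nn.BiLSTM(L // 4),
                  nn.BiLSTM(L // 8), nn.Dropout(config.dropout), nn.Flatten(),
                  nn.Dense(config.n_classes)]
    else:
        raise ConfigError(f"build_model does not handle family {config.family!r}")
    return nn.SequenceClassifier(layers, n_features=n_features,
                                 seq_len=config.seq_len, seed=config.seed)


@dataclasses.dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it safely."""

    config: ModelConfig
    manifest: list[str]
    network: nn.SequenceClassifier | None = None
    svm: SGDClassifier | None = None
    svm_classes: list[str] | None = None
    history: dict = dataclasses.field(default_factory=dict)
    feature_mu: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    @property
    def manifest_hash(self) -> str:
        return manifest_hash(self.manifest)

    def _prepare(self, features: FeatureMatrix | np.ndarray) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            if manifest_hash(features.manifest) != self.manifest_hash:
                raise CompatibilityError(
                    "feature manifest differs from the one the model was trained on")
            x = features.values
        else:
            x = np.asarray(features)
            if x.shape[-1] != len(self.manifest):
                raise CompatibilityError(
                    f"expected {len(self.manifest)} features, got {x.shape[-1]}")
        if self.feature_mu is not None:
            x = (x - self.feature_mu) / self.feature_sd
        return x

    def predict(self, features: FeatureMatrix | np.ndarray,
                epoch_len_s: float | None = None) -> tuple[np.ndarray, StateLabels]:
        """Score a feature matrix; returns (probabilities, decoded labels)."""
        x = self._prepare(features)
        if epoch_len_s is None:
            epoch_len_s = (features.epoch_len_s
                           if isinstance(features, FeatureMatrix) else 20.0)
        if self.svm is not None:
            scores = self.svm.decision_function(x)
            if scores.ndim == 1:
                scores = np.stack([-scores, scores], axis=1)
            pred_local = scores.argmax(axis=1)
            probs = np.zeros((len(x), N_STATES))
            # pseudo-probabilities: softmax over the margin scores of the
            # classes seen in training
            sm = nn.softmax(scores)
            for j, cls in enumerate(self.svm_classes):
                probs[:, STATES.index(cls)] = sm[:, j]
            labels = np.array([self.svm_classes[i] for i in pred_local], dtype=object)
        else:
            seqs = make_sequences(x, self.config.seq_len)
            probs = self.network.predict_proba(seqs)
            labels = as_names(probs.argmax(axis=1))
        return probs, StateLabels(labels=labels, epoch_len_s=epoch_len_s)


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _weight_vector(weights: dict[str, float] | None) -> np.ndarray:
    vec = np.ones(N_STATES)
    if weights:
        for s, w in weights.items():
            vec[STATES.index(s)] = w
    return vec


def train(config: ModelConfig, features: FeatureMatrix, labels: StateLabels,
          weights: dict[str, float] | None = None,
          validation: tuple[FeatureMatrix, StateLabels] | None = None,
          epochs_per_file: int | list[int] | None = None,
          verbose: bool = False) -> TrainedModel:
    """Train one classifier under the standard schedule.

    ``weights`` defaults to the smoothed balanced class weights of the
    training labels. ``epochs_per_file`` gives the per-file epoch counts of a
    concatenated training matrix: it sets the mini-batch size (one full
    recording per batch) and keeps sequence windows from crossing file
    boundaries. When omitted the matrix is treated as a single file.
    """
    if features.n_epochs != len(labels):
        raise ConfigError("features and labels are misaligned")
    if weights is None:
        weights = compute_class_weights(labels, floor=0.01)
    if config.family == "svm":
        return train_svm(config, features, labels, weights)

    x = features.values
    mu = sd = None
    if config.standardize:
        mu, sd = _standardize_fit(x)
        x = (x - mu) / sd
    if isinstance(epochs_per_file, (list, tuple)):
        if sum(epochs_per_file) != len(x):
            raise ConfigError("epochs_per_file does not sum to the epoch count")
        bounds = np.cumsum([0, *epochs_per_file])
        seqs = np.concatenate([make_sequences(x[a:b], config.seq_len)
                               for a, b in zip(bounds[:-1], bounds[1:])])
        epochs_per_file = int(epochs_per_file[0])
    else:
        seqs = make_sequences(x, config.seq_len)
    y = encode_onehot(labels).astype(np.float64)

    net = build_model(config, n_features=features.n_features)
    val = None
    if validation is not None:
        vx = validation[0].values
        if mu is not None:
            vx = (vx - mu) / sd
        val = (make_sequences(vx, config.seq_len),
               encode_onehot(validation[1]).astype(np.float64))

    batch = config.batch_size or epochs_per_file or len(seqs)

    def _mean_aucpr(y_true, probs):
        from .metrics import aucpr
        vals = list(aucpr(y_true, np.clip(probs, 0, 1)).values())
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else 0.0

    net.fit(seqs, y, class_weight_vec=_weight_vector(weights),
            batch_size=batch, max_epochs=config.max_train_epochs,
            early_stop_delta=config.early_stop_delta,
            early_stop_patience=config.early_stop_patience,
            validation=val, optimizer=nn.Nadam(lr=config.learning_rate),
            metrics_fn=_mean_aucpr, verbose=verbose)
    return TrainedModel(config=config, manifest=list(features.manifest),
                        network=net, history=net.history,
                        feature_mu=mu, feature_sd=sd)


def train_svm(config: ModelConfig, features: FeatureMatrix, labels: StateLabels,
              weights: dict[str, float] | None = None) -> TrainedModel:
    """Linear one-vs-all hinge-loss classifier via SGD, 1,000 iterations max.

    The SVM sees the plain per-epoch feature vector (no sequence windowing).
    """
    uniq = sorted(set(labels.labels))
    if len(uniq) < 2:
        raise SwiscError("SVM training needs at least two classes present")
    if weights is None:
        weights = compute_class_weights(labels, floor=0.01)
    x = features.values
    mu = sd = None
    if config.standardize:
        mu, sd = _standardize_fit(x)
        x = (x - mu) / sd
    clf = SGDClassifier(loss="hinge", penalty="l2", max_iter=1000,
                        class_weight={s: w for s, w in weights.items()},
                        random_state=config.seed)
    clf.fit(x, np.asarray(labels.labels, dtype=object))
    return TrainedModel(config=config, manifest=list(features.manifest),
                        svm=clf, svm_classes=[str(c) for c in clf.classes_],
                        feature_mu=mu, feature_sd=sd)


def predict(model: TrainedModel, features: FeatureMatrix | np.ndarray,
            epoch_len_s: float | None = None) -> tuple[np.ndarray, StateLabels]:
    """Functional alias for :meth:`TrainedModel.predict`."""
    return model.predict(features, epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# serialization: config + manifest as JSON, weights as arrays
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.config.to_dict(),
        "manifest": model.manifest,
        "manifest_hash": model.manifest_hash,
        "kind": "svm" if model.svm is not None else "network",
        "svm_classes": model.svm_classes,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))
    (out / "history.json").write_text(json.dumps(model.history, indent=1))
    arrays: dict[str, np.ndarray] = {}
    if model.feature_mu is not None:
        arrays["feature_mu"] = model.feature_mu
        arrays["feature_sd"] = model.feature_sd
    if model.svm is not None:
        arrays["svm_coef"] = model.svm.coef_
        arrays["svm_intercept"] = model.svm.intercept_
    else:
        for k, v in model.network.get_weights().items():
            arrays["w:" + k] = v
    np.savez(out / "weights.npz", **arrays)
    return out


def load_model(model_dir) -> TrainedModel:
    out = Path(model_dir)
    meta = json.loads((out / "model.json").read_text())
    config = ModelConfig.from_dict(meta["config"])
    with np.load(out / "weights.npz") as z:
        arrays = {k: z[k] for k in z.files}
    history = json.loads((out / "history.json").read_text())
    mu = arrays.get("feature_mu")
    sd = arrays.get("feature_sd")
    if meta["kind"] == "svm":
        clf = SGDClassifier(loss="hinge", penalty="l2", max_iter=1000)
        clf.coef_ = arrays["svm_coef"]
        clf.intercept_ = arrays["svm_intercept"]
        clf.classes_ = np.array(meta["svm_classes"], dtype=object)
        return TrainedModel(config=config, manifest=meta["manifest"], svm=clf,
                            svm_classes=meta["svm_classes"], history=history,
                            feature_mu=mu, feature_sd=sd)
    net = build_model(config, n_features=len(meta["manifest"]))
    net.set_weights({k[2:]: v for k, v in arrays.items() if k.startswith("w:")})
    return TrainedModel(config=config, manifest=meta["manifest"], network=net,
                        history=history, feature_mu=mu, feature_sd=sd)
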