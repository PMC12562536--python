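"""A small numpy engine for the sequence classifiers.

Implements exactly the layer vocabulary the classifier families need — a
time-distributed linear dense layer, LSTM and bidirectional LSTM layers that
return full sequences, dropout, flatten, and a softmax output head — together
with Nadam optimization of a class-weighted categorical cross-entropy and
plateau-based early stopping. Gradients are computed by hand-written
backpropagation (through time for the recurrent layers).

All randomness (initialization, batch shuffling, dropout masks) flows from a
single integer seed, so training is reproducible bit-for-bit on one device.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DivergenceError


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng, n, m):
    a = rng.standard_normal((max(n, m), max(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:n, :m]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params, self.grads = {}, {}

    def build(self, rng, input_shape):  # -> output_shape
        raise NotImplementedError

    def forward(self, x, train: bool):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def regularization_loss(self) -> float:
        return 0.0


class TimeDense(Layer):
    """Linear fully connected layer applied to every timestep."""

    def __init__(self, units: int):
        super().__init__()
        self.units = units

    def build(self, rng, input_shape):
        seq, fin = input_shape
        self.params = {"W": _glorot(rng, fin, self.units),
                       "b": np.zeros(self.units)}
        return (seq, self.units)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        x = self._x
        self.grads = {"W": np.tensordot(x, dout, axes=([0, 1], [0, 1])),
                      "b": dout.sum(axis=(0, 1))}
        return dout @ self.params["W"].T


class LSTM(Layer):
    """Single-direction LSTM returning the full hidden-state sequence.

    Gate order in the packed weight matrices is (input, forget, cell, output);
    the forget-gate bias is initialized to 1.
    """

    def __init__(self, units: int, backwards: bool = False):
        super().__init__()
        self.units = units
        self.backwards = backwards

    def build(self, rng, input_shape):
        seq, fin = input_shape
        u = self.units
        w = _glorot(rng, fin, 4 * u)
        rec = np.concatenate([_orthogonal(rng, u, u) for _ in range(4)], axis=1)
        b = np.zeros(4 * u)
        b[u:2 * u] = 1.0
        self.params = {"W": w, "U": rec, "b": b}
        return (seq, u)

    def forward(self, x, train):
        if self.backwards:
            x = x[:, ::-1, :]
        n, seq, _ = x.shape
        u = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        cache = []
        hs = np.empty((n, seq, u))
        for t in range(seq):
            z = x[:, t, :] @ W + h @ U + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            cache.append((x[:, t, :], h_prev, c_prev, i, f, g, o, tc))
        self._cache = cache
        self._in_shape = x.shape
        return hs[:, ::-1, :] if self.backwards else hs

    def backward(self, dout):
        if self.backwards:
            dout = dout[:, ::-1, :]
        n, seq, u = dout.shape
        W, U = self.params["W"], self.params["U"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params["b"])
        dx = np.empty(self._in_shape)
        dh_next = np.zeros((n, u))
        dc_next = np.zeros((n, u))
        for t in range(seq - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            dh = dout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc ** 2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dW += xt.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_next = dz @ U.T
        self.grads = {"W": dW, "U": dU, "b": db}
        return dx[:, ::-1, :] if self.backwards else dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and backward passes concatenated.

    ``units`` is the size of each direction, so the output width is 2*units.
    Optional L1 activity regularization penalizes the layer's output.
    """

    def __init__(self, units: int, activity_l1: float = 0.0):
        super().__init__()
        self.units = units
        self.activity_l1 = activity_l1
        self.fwd = LSTM(units, backwards=False)
        self.bwd = LSTM(units, backwards=True)

    def build(self, rng, input_shape):
        seq, _ = input_shape
        self.fwd.build(rng, input_shape)
        self.bwd.build(rng, input_shape)
        self.params = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        self.params.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        return (seq, 2 * self.units)

    def forward(self, x, train):
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x, train)
        self._out = np.concatenate([hf, hb], axis=-1)
        return self._out

    def backward(self, dout):
        if self.activity_l1:
            dout = dout + self.activity_l1 * np.sign(self._out)
        dxf = self.fwd.backward(dout[..., :self.units])
        dxb = self.bwd.backward(dout[..., self.units:])
        self.grads = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        self.grads.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return dxf + dxb

    def regularization_loss(self) -> float:
        if not self.activity_l1:
            return 0.0
        return float(self.activity_l1 * np.abs(self._out).sum() / self._out.shape[0])


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = None  # set by the network

    def build(self, rng, input_shape):
        return input_shape

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def build(self, rng, input_shape):
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Output projection on flattened input (softmax applied by the network)."""

    def __init__(self, units: int):
        super().__init__()
        self.units = units

    def build(self, rng, input_shape):
        (fin,) = input_shape
        self.params = {"W": _glorot(rng, fin, self.units),
                       "b": np.zeros(self.units)}
        return (self.units,)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Nadam:
    """Nesterov-accelerated Adam with the canonical default hyperparameters."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1 ** (self.t + 1))
            v_hat = v / (1 - b2 ** self.t)
            update = (b1 * m_hat + (1 - b1) * g / (1 - b1 ** self.t))
            params[key] -= self.lr * update / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class SequenceClassifier:
    """A feed-forward stack over (batch, seq, features) inputs ending in a
    five-way softmax."""

    def __init__(self, layers: list[Layer], n_features: int, seq_len: int,
                 seed: int = 0):
        self.layers = layers
        self.seq_len = seq_len
        self.n_features = n_features
        self.rng = np.random.default_rng(seed)
        shape = (seq_len, n_features)
        for layer in layers:
            if isinstance(layer, Dropout):
                layer.rng = self.rng
            shape = layer.build(self.rng, shape)
        self.n_classes = shape[0]
        self.history: dict[str, list] = {}

    # -- inference ---------------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return softmax(self.logits(x, train))

    # -- training ----------------------------------------------------------
    def _loss_and_grad(self, x, y, sample_weight, train=True):
        logits = self.logits(x, train=train)
        probs = softmax(logits)
        eps = 1e-12
        ce = -(y * np.log(probs + eps)).sum(axis=1)
        loss = float((sample_weight * ce).mean())
        loss += sum(layer.regularization_loss() for layer in self.layers)
        dlogits = (probs - y) * sample_weight[:, None] / x.shape[0]
        return loss, probs, dlogits

    def evaluate_loss(self, x, y, sample_weight=None, batch_size=4096) -> float:
        if sample_weight is None:
            sample_weight = np.ones(len(x))
        total, n = 0.0, len(x)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            loss, _, _ = self._loss_and_grad(x[sl], y[sl], sample_weight[sl],
                                             train=False)
            total += loss * (sl.stop - sl.start)
        return total / n

    def fit(self, x, y_onehot, class_weight_vec=None, batch_size=None,
            max_epochs: int = 20, early_stop_delta: float = 1e-3,
            early_stop_patience: int = 5, validation=None,
            optimizer: Nadam | None = None, shuffle: bool = True,
            metrics_fn=None, verbose: bool = False) -> dict:
        """Minimize class-weighted categorical cross-entropy with Nadam.

        ``class_weight_vec`` is a length-n_classes weight array; each sample
        is weighted by the weight of its true class. Early stopping fires
        after ``early_stop_patience`` consecutive epochs whose monitored loss
        (validation if given, else training) improves by less than
        ``early_stop_delta``.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y_onehot, dtype=np.float64)
        n = len(x)
        if batch_size is None:
            batch_size = n
        if class_weight_vec is None:
            class_weight_vec = np.ones(self.n_classes)
        sample_weight = np.asarray(class_weight_vec)[y.argmax(axis=1)]

        opt = optimizer or Nadam()
        history: dict[str, list] = {k: [] for k in
                                    ("loss", "accuracy", "precision", "recall",
                                     "aucpr", "val_loss")}
        best = np.inf
        stall = 0
        for ep in range(max_epochs):
            order = self.rng.permutation(n) if shuffle else np.arange(n)
            ep_loss = 0.0
            correct = 0
            all_probs = np.empty((n, self.n_classes))
            for start in range(0, n, batch_size):
                sel = order[start:start + batch_size]
                loss, probs, dlogits = self._loss_and_grad(
                    x[sel], y[sel], sample_weight[sel], train=True)
                if not np.isfinite(loss):
                    raise DivergenceError(
                        f"non-finite loss at training epoch {ep}; history={history}")
                dout = dlogits
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                params, grads = {}, {}
                for li, layer in enumerate(self.layers):
                    for k, v in layer.params.items():
                        params[f"{li}:{k}"] = v
                        grads[f"{li}:{k}"] = layer.grads[k]
                opt.step(params, grads)
                ep_loss += loss * len(sel)
                correct += int((probs.argmax(1) == y[sel].argmax(1)).sum())
                all_probs[sel] = probs
            ep_loss /= n
            history["loss"].append(ep_loss)
            history["accuracy"].append(correct / n)
            pred_hot = all_probs >= 0.5
            tp = float((pred_hot & (y > 0.5)).sum())
            fp = float((pred_hot & ~(y > 0.5)).sum())
            fn = float((~pred_hot & (y > 0.5)).sum())
            history["precision"].append(tp / (tp + fp) if tp + fp else 0.0)
            history["recall"].append(tp / (tp + fn) if tp + fn else 0.0)
            if metrics_fn is not None:
                history["aucpr"].append(metrics_fn(y, all_probs))
            monitored = ep_loss
            if validation is not None:
                xv, yv = validation
                val_loss = self.evaluate_loss(xv, yv)
                history["val_loss"].append(val_loss)
                monitored = val_loss
            if verbose:
                print(f"epoch {ep + 1}: loss={ep_loss:.4f} "
                      f"acc={history['accuracy'][-1]:.4f}")
            if best - monitored < early_stop_delta:
                stall += 1
            else:
                stall = 0
            best = min(best, monitored)
            if stall >= early_stop_patience:
                break
        self.history = history
        return history

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{li}:{k}"] = v
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for k in layer.params:
                key = f"{li}:{k}"
                if key not in weights:
                    raise ConfigError(f"missing weight {key}")
                if weights[key].shape != layer.params[k].shape:
                    raise ConfigError(f"weight {key} has wrong shape")
                layer.params[k] = np.asarray(weights[key], dtype=np.float64)
                if isinstance(layer, BiLSTM):
                    sub, kk = k.split("_", 1)
                    (layer.fwd if sub == "fwd" else layer.bwd).params[kk] = layer.params[k]
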