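"""LSTM horizon classifier: 10 monthly feature vectors in, a probability
distribution over the next 50 months out.

The network is a stacked two-layer LSTM (50 tanh units per layer by
default; 100/200-unit variants exist for keyword models) followed by a
dense projection of the *final* time step's hidden state onto the
50-month horizon and a softmax. The argmax of the softmax is the
predicted life expectancy in months; its maximum is the prediction's
certainty. Training minimizes cross-entropy against the one-hot
months-to-death label with the Adam update rule, mini-batches of 5, a
learning rate of 1e-5 and 10 epochs by default, weights drawn from a
seeded truncated normal and biases initialized at 0.1.

The whole stack is plain numpy: forward pass, full backpropagation
through time, and Adam are implemented here, single-threaded and fully
seeded, so build + train + predict is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .feature_engineering import WindowSample

__all__ = ["ModelConfig", "Prognosis", "LSTMClassifier", "build_model", "train", "predict"]


@dataclass
class ModelConfig:
    window: int = 10
    horizon: int = 50
    hidden_layers: int = 2
    hidden_units: int = 50
    batch_size: int = 5
    learning_rate: float = 1e-5
    epochs: int = 10
    init_sd: float = 0.1
    bias_init: float = 0.1
    #: loss on the final step only by default; all-steps variant available
    loss_all_steps: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window", "horizon", "hidden_layers", "hidden_units", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class Prognosis:
    """Softmax horizon distribution with its argmax interpretation."""

    probabilities: np.ndarray  # length horizon, sums to 1
    predicted_months: int  # argmax + 1, ties toward the earlier month
    certainty: float  # max probability


def _truncated_normal(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    # two-sided truncation at 2 sd, as conventional for network init
    return stats.truncnorm.rvs(-2, 2, scale=sd, size=shape, random_state=rng)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class LSTMClassifier:
    """Stacked LSTM + dense softmax head over the months-to-death horizon."""

    def __init__(self, config: ModelConfig, input_dim: int):
        if input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        self.config = config
        self.input_dim = input_dim
        rng = np.random.default_rng(config.seed)
        H, sd, b0 = config.hidden_units, config.init_sd, config.bias_init
        self.params: dict[str, np.ndarray] = {}
        dim = input_dim
        for layer in range(config.hidden_layers):
            self.params[f"Wx{layer}"] = _truncated_normal(rng, (dim, 4 * H), sd)
            self.params[f"Wh{layer}"] = _truncated_normal(rng, (H, 4 * H), sd)
            self.params[f"b{layer}"] = np.full(4 * H, b0)
            dim = H
        self.params["Wo"] = _truncated_normal(rng, (H, config.horizon), sd)
        self.params["bo"] = np.full(config.horizon, b0)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._train_rng = np.random.default_rng(config.seed + 1)

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, want_cache: bool):
        """X: (B, T, input_dim) -> logits (B, horizon) [+ cache for BPTT]."""
        B, T, _ = X.shape
        H = self.config.hidden_units
        caches = []
        inputs = X
        for layer in range(self.config.hidden_layers):
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            b = self.params[f"b{layer}"]
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            hs = np.empty((T, B, H))
            steps = []
            for t in range(T):
                x_t = inputs[:, t, :]
                z = x_t @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_new = f * c + i * g
                h_new = o * np.tanh(c_new)
                if want_cache:
                    steps.append((x_t, h, c, i, f, g, o, c_new))
                h, c = h_new, c_new
                hs[t] = h
            caches.append(steps)
            inputs = hs.transpose(1, 0, 2)
        logits = inputs[:, -1, :] @ self.params["Wo"] + self.params["bo"]
        if want_cache:
            return logits, inputs, caches
        return logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[2] != self.input_dim:
            raise ValueError(f"input dim {X.shape[2]} != model dim {self.input_dim}")
        return _softmax(self._forward(X, want_cache=False))

    # -- backward ----------------------------------------------------------

    def _backward_layer(self, layer: int, steps, dh_out: np.ndarray, grads) -> np.ndarray:
        """BPTT for one layer. dh_out: (T, B, H) gradients w.r.t. outputs.

        Returns (T, B, in_dim) gradients w.r.t. the layer inputs."""
        H = self.config.hidden_units
        Wx = self.params[f"Wx{layer}"]
        Wh = self.params[f"Wh{layer}"]
        T = len(steps)
        B = dh_out.shape[1]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params[f"b{layer}"])
        dx_all = np.empty((T, B, Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new = steps[t]
            tanh_c = np.tanh(c_new)
            dh = dh_out[t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_all[t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        grads[f"Wx{layer}"] = dWx
        grads[f"Wh{layer}"] = dWh
        grads[f"b{layer}"] = db
        return dx_all

    def _batch_step(self, X: np.ndarray, y: np.ndarray) -> float:
        """One forward/backward/Adam step; returns the batch mean loss."""
        B, T, _ = X.shape
        logits, top_h, caches = self._forward(X, want_cache=True)
        grads: dict[str, np.ndarray] = {}
        dh_out = np.zeros((T, B, self.config.hidden_units))
        if self.config.loss_all_steps:
            # intermediate predictions contribute to the loss as well
            logits_all = top_h @ self.params["Wo"] + self.params["bo"]
            probs_all = _softmax(logits_all)
            sel = probs_all[np.arange(B), :, y - 1]
            loss = float(-np.log(sel + 1e-12).mean())
            onehot = np.zeros((B, self.config.horizon))
            onehot[np.arange(B), y - 1] = 1.0
            dlog_all = (probs_all - onehot[:, None, :]) / (B * T)
            grads["Wo"] = np.einsum("bth,btk->hk", top_h, dlog_all)
            grads["bo"] = dlog_all.sum(axis=(0, 1))
            dh_out += (dlog_all @ self.params["Wo"].T).transpose(1, 0, 2)
        else:
            probs = _softmax(logits)
            onehot = np.zeros_like(probs)
            onehot[np.arange(B), y - 1] = 1.0
            loss = float(-np.log(probs[np.arange(B), y - 1] + 1e-12).mean())
            dlogits = (probs - onehot) / B
            grads["Wo"] = top_h[:, -1, :].T @ dlogits
            grads["bo"] = dlogits.sum(axis=0)
            dh_out[-1] = dlogits @ self.params["Wo"].T
        for layer in range(self.config.hidden_layers - 1, -1, -1):
            dx = self._backward_layer(layer, caches[layer], dh_out, grads)
            dh_out = dx
        self._adam_update(grads)
        return loss

    def _adam_update(self, grads, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        lr = self.config.learning_rate
        for key, g in grads.items():
            m = self._adam_m[key]
            v = self._adam_v[key]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Train for ``config.epochs`` epochs; returns per-epoch mean loss.

        Samples are reshuffled each epoch under the model seed;
        mini-batches of ``batch_size`` with the final short batch kept.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.size == 0:
            raise ValueError("empty training set")
        if X.shape[2] != self.input_dim:
            raise ValueError(f"input dim {X.shape[2]} != model dim {self.input_dim}")
        n = X.shape[0]
        bs = self.config.batch_size
        history = []
        for _ in range(self.config.epochs):
            order = self._train_rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                losses.append(self._batch_step(X[idx], y[idx]))
            history.append(float(np.mean(losses)))
        return history

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        """Single text file: JSON metadata header, then one array per line."""
        meta = {"config": asdict(self.config), "input_dim": self.input_dim}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(json.dumps(meta, sort_keys=True) + "\n")
            for key in sorted(self.params):
                flat = " ".join(repr(float(x)) for x in self.params[key].ravel())
                shape = ",".join(map(str, self.params[key].shape))
                fh.write(f"{key}\t{shape}\t{flat}\n")

    @classmethod
    def load(cls, path) -> "LSTMClassifier":
        with open(path, encoding="utf-8") as fh:
            meta = json.loads(fh.readline())
            model = cls(ModelConfig(**meta["config"]), meta["input_dim"])
            for line in fh:
                key, shape, flat = line.rstrip("\n").split("\t")
                arr = np.array([float(x) for x in flat.split()])
                model.params[key] = arr.reshape([int(s) for s in shape.split(",")])
        return model


# ---------------------------------------------------------------------------
# Functional surface


def build_model(config: ModelConfig, input_dim: int) -> LSTMClassifier:
    return LSTMClassifier(config, input_dim)


def _stack(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.vectors for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


def train(
    model: LSTMClassifier, samples: list[WindowSample], config: ModelConfig | None = None
) -> list[float]:
    """Train on windowed samples; returns per-epoch mean cross-entropy."""
    if not samples:
        raise ValueError("empty sample list")
    X, y = _stack(samples)
    return model.fit(X, y)


def predict(model: LSTMClassifier, window: WindowSample | np.ndarray) -> Prognosis:
    vectors = window.vectors if isinstance(window, WindowSample) else window
    probs = model.predict_proba(vectors)[0]
    predicted = int(np.argmax(probs)) + 1  # ties resolve to the earlier month
    return Prognosis(
        probabilities=probs,
        predicted_months=predicted,
        certainty=float(probs[predicted - 1]),
    )
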