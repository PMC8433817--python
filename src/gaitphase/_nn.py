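"""Minimal NumPy recurrent network: stacked LSTM, batch-norm, dropout, Adam.

Implements exactly the layer kinds the per-phase sequence models need,
with explicit backpropagation through time.  Conventions follow the common
deep-learning defaults: LSTM gate order (input, forget, cell, output) with
unit forget-gate bias, Glorot-uniform input kernels, orthogonal recurrent
kernels; batch normalization over the batch (and time) axes per feature
with moving statistics for inference; inverted dropout.  Everything is
float64 — model sizes here are small enough that numerical transparency
beats throughput.

Gradient correctness is enforced by a finite-difference check in the test
suite; keep any change to the backward passes under that test.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


class Layer:
    """Base: trainable arrays live in self.params with matching self.grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
        """``mode``: 'train' (batch stats, dropout on), 'infer' (moving
        stats, dropout off) or 'calibrate' (batch stats, dropout off,
        batch-norm accumulating exact dataset statistics)."""
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features) input.

    ``return_sequences`` controls whether the output is the full hidden
    sequence (B, T, H) or only the final hidden state (B, H).
    """

    def __init__(self, input_dim: int, units: int, return_sequences: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        H = units
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.params = {
            "Wx": glorot_uniform(rng, input_dim, H, (input_dim, 4 * H)),
            "Wh": np.concatenate([orthogonal(rng, H) for _ in range(4)], axis=1),
            "b": b,
        }
        self.zero_grads()

    def forward(self, x, mode, rng):
        B, T, D = x.shape
        H = self.units
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xz = x @ Wx + b  # (B, T, 4H), input contribution precomputed
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = cache = {
            "x": x, "i": np.empty((B, T, H)), "f": np.empty((B, T, H)),
            "g": np.empty((B, T, H)), "o": np.empty((B, T, H)),
            "c": np.empty((B, T, H)), "tc": np.empty((B, T, H)),
            "h_prev": np.empty((B, T, H)), "c_prev": np.empty((B, T, H)),
        }
        hs = np.empty((B, T, H))
        for t in range(T):
            z = xz[:, t] + h @ Wh
            s = sigmoid(z[:, :3 * H])  # gate layout: [input, forget, output | cell]
            i, f, o = s[:, :H], s[:, H:2 * H], s[:, 2 * H:]
            g = np.tanh(z[:, 3 * H:])
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            cache["i"][:, t], cache["f"][:, t] = i, f
            cache["g"][:, t], cache["o"][:, t] = g, o
            cache["c"][:, t], cache["tc"][:, t] = c, tc
            hs[:, t] = h
        return hs if self.return_sequences else h

    def backward(self, dout):
        cache = self._cache
        x = cache["x"]
        B, T, D = x.shape
        H = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh = np.zeros((B, H))
        dc = np.zeros((B, H))
        dz = np.empty((B, 4 * H))
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dout[:, t]
            elif t == T - 1:
                dh = dh + dout
            i, f = cache["i"][:, t], cache["f"][:, t]
            g, o = cache["g"][:, t], cache["o"][:, t]
            tc = cache["tc"][:, t]
            dc = dc + dh * o * (1.0 - tc * tc)
            dz[:, :H] = dc * g
            dz[:, H:2 * H] = dc * cache["c_prev"][:, t]
            dz[:, 2 * H:3 * H] = dh * tc
            s = np.concatenate((i, f, o), axis=1)
            dz[:, :3 * H] *= s * (1.0 - s)
            dz[:, 3 * H:] = dc * i * (1.0 - g * g)
            dWx += x[:, t].T @ dz
            dWh += cache["h_prev"][:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"] += dWx
        self.grads["Wh"] += dWh
        self.grads["b"] += db
        return dx


class BatchNorm(Layer):
    """Per-feature normalization over the batch (and, for sequences, time) axes."""

    def __init__(self, dim: int, momentum: float = 0.99, epsilon: float = 0.001) -> None:
        super().__init__()
        self.momentum = momentum
        self.epsilon = epsilon
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.moving_mean = np.zeros(dim)
        self.moving_var = np.ones(dim)
        self.zero_grads()

    def forward(self, x, mode, rng):
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        if mode == "infer":
            mean, var = self.moving_mean, self.moving_var
        else:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            if mode == "train":
                self.moving_mean = self.momentum * self.moving_mean + (1 - self.momentum) * mean
                self.moving_var = self.momentum * self.moving_var + (1 - self.momentum) * var
            else:  # calibrate: accumulate exact dataset statistics
                n = flat.shape[0]
                self._acc_n += n
                self._acc_sum += flat.sum(axis=0)
                self._acc_sumsq += np.square(flat).sum(axis=0)
        inv_std = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (flat - mean) * inv_std
        if mode == "train":
            self._cache = (xhat, inv_std, shape)
        out = self.params["gamma"] * xhat + self.params["beta"]
        return out.reshape(shape)

    def start_calibration(self) -> None:
        dim = self.moving_mean.shape[0]
        self._acc_n = 0
        self._acc_sum = np.zeros(dim)
        self._acc_sumsq = np.zeros(dim)

    def finish_calibration(self) -> None:
        if self._acc_n:
            mean = self._acc_sum / self._acc_n
            self.moving_mean = mean
            self.moving_var = self._acc_sumsq / self._acc_n - mean**2

    def backward(self, dout):
        xhat, inv_std, shape = self._cache
        dy = dout.reshape(-1, shape[-1])
        N = dy.shape[0]
        self.grads["beta"] += dy.sum(axis=0)
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        dxhat = dy * self.params["gamma"]
        dx = inv_std / N * (
            N * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx.reshape(shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, mode, rng):
        if mode != "train" or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    """Affine map on the last axis (activation handled by the caller)."""

    def __init__(self, input_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, input_dim, units, (input_dim, units)),
            "b": np.zeros(units),
        }
        self.zero_grads()

    def forward(self, x, mode, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class Adam:
    """Adam optimizer over a network's layer parameters."""

    def __init__(self, layers: list[Layer], learning_rate: float,
                 beta_1: float = 0.9, beta_2: float = 0.999, epsilon: float = 1e-7) -> None:
        self.layers = layers
        self.lr = learning_rate
        self.beta_1, self.beta_2, self.epsilon = beta_1, beta_2, epsilon
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta_2 ** self.t) / (1 - self.beta_1 ** self.t)
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta_1 * m[k] + (1 - self.beta_1) * g
                v[k] = self.beta_2 * v[k] + (1 - self.beta_2) * g * g
                p -= lr_t * m[k] / (np.sqrt(v[k]) + self.epsilon)


class SequenceClassifier:
    """Stacked-LSTM binary classifier for fixed-length sequences.

    Layer sequence: for each entry u of ``units`` an LSTM(u) (all but the
    last returning sequences) followed by batch-norm and dropout, then a
    1-unit dense layer; :meth:`predict_proba` applies the sigmoid.
    """

    def __init__(self, n_features: int, units: list[int], dropout_rate: float,
                 bn_momentum: float, bn_epsilon: float, seed: int) -> None:
        self.seed = seed
        init_rng = np.random.default_rng(seed)
        self.layers: list[Layer] = []
        dim = n_features
        for idx, u in enumerate(units):
            last = idx == len(units) - 1
            self.layers.append(LSTM(dim, u, return_sequences=not last, rng=init_rng))
            self.layers.append(BatchNorm(u, momentum=bn_momentum, epsilon=bn_epsilon))
            self.layers.append(Dropout(dropout_rate))
            dim = u
        self.layers.append(Dense(dim, 1, rng=init_rng))
        self._dropout_rng = np.random.default_rng(init_rng.integers(2**31))

    def forward(self, x: np.ndarray, mode: str = "infer") -> np.ndarray:
        """Logits (B,) for a batch of sequences (B, T, C)."""
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, mode, self._dropout_rng)
        return out[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.concatenate([
            sigmoid(self.forward(x[s:s + batch_size], mode="infer"))
            for s in range(0, x.shape[0], batch_size)
        ]) if x.shape[0] else np.empty(0)

    def train_batch(self, x: np.ndarray, y: np.ndarray, optimizer: Adam) -> tuple[float, float]:
        """One gradient step on a batch; returns (BCE loss, accuracy)."""
        for layer in self.layers:
            layer.zero_grads()
        logits = self.forward(x, mode="train")
        p = sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        dlogits = ((p - y) / y.shape[0])[:, None]
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        optimizer.step()
        return float(loss), float(np.mean((p > 0.5) == (y == 1)))

    def calibrate_batchnorm(self, x: np.ndarray, batch_size: int = 256) -> None:
        """Replace batch-norm moving statistics with exact dataset statistics.

        Short training runs leave the exponentially averaged statistics far
        from the activations the trained weights actually produce, which
        opens a train/inference gap; one calibration pass (dropout off,
        batch statistics used for normalization, as in training) closes it.
        """
        bns = [l for l in self.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn.start_calibration()
        for s in range(0, x.shape[0], batch_size):
            self.forward(x[s:s + batch_size], mode="calibrate")
        for bn in bns:
            bn.finish_calibration()

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self.layers):
            for k, v in lay.params.items():
                arrays[f"layer{i}_{k}"] = v
            if isinstance(lay, BatchNorm):
                arrays[f"layer{i}_moving_mean"] = lay.moving_mean
                arrays[f"layer{i}_moving_var"] = lay.moving_var
        return arrays

    def load_state_arrays(self, arrays) -> None:
        for i, lay in enumerate(self.layers):
            for k in lay.params:
                lay.params[k][...] = arrays[f"layer{i}_{k}"]
            if isinstance(lay, BatchNorm):
                lay.moving_mean = np.array(arrays[f"layer{i}_moving_mean"])
                lay.moving_var = np.array(arrays[f"layer{i}_moving_var"])
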