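"""Minimal feed-forward / recurrent network library used by the predictor.

The hexapeptide classifier is a small stack of layers (time-distributed input
projection, one or two bidirectional LSTMs, a dense block with dropout, and a
sigmoid output). Sequence length is six residues and hidden widths are below a
hundred units, so the networks are implemented directly on NumPy arrays with
hand-derived backpropagation (through time for the recurrent layers) and an
Adam optimizer. All stochasticity flows through an explicit
``numpy.random.Generator``, which makes training bit-reproducible on a single
thread.

Conventions: activations are row-major batches; recurrent layers run over axis
1 (time). The forward pass caches whatever the matching ``backward`` needs, so
a layer must see ``forward`` before ``backward`` within a step.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TimeDistributedDense",
    "BiLSTM",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "sigmoid",
    "binary_cross_entropy",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binary_cross_entropy(prob: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(prob, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameters, gradients, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k, p in self.params.items():
            self.grads[k] = np.zeros_like(p)


class TimeDistributedDense(Layer):
    """Dense layer applied independently at every time step, tanh activation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params = {
            "W": _glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.zero_grads()

    def forward(self, x, *, train=False, rng=None):
        self._x = x  # (B, T, in)
        z = x @ self.params["W"] + self.params["b"]
        self._a = np.tanh(z)
        return self._a

    def backward(self, grad):
        dz = grad * (1.0 - self._a**2)
        self.grads["W"] += np.einsum("bti,bto->io", self._x, dz)
        self.grads["b"] += dz.sum(axis=(0, 1))
        return dz @ self.params["W"].T


class _LSTMDirection:
    """One direction of an LSTM; owns its parameter slice of the parent layer.

    Gate layout in the fused weight matrices is [input, forget, cell, output].
    The forget-gate bias starts at 1, the usual remedy for early vanishing
    cell-state gradients.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.in_dim, self.hidden = in_dim, hidden
        h = hidden
        self.params = {
            "Wx": _glorot(rng, in_dim, h, (in_dim, 4 * h)),
            "Wh": _glorot(rng, h, h, (h, 4 * h)),
            "b": np.zeros(4 * h),
        }
        self.params["b"][h:2 * h] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, in) in processing order; returns hidden states (B, T, h)."""
        B, T, _ = x.shape
        h = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        self._x = x
        self._cache = []
        hs = np.empty((B, T, h))
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        for t in range(T):
            z = x[:, t, :] @ Wx + h_t @ Wh + b
            i = sigmoid(z[:, :h])
            f = sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = sigmoid(z[:, 3 * h:])
            c_prev, h_prev = c_t, h_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            hs[:, t, :] = h_t
            self._cache.append((h_prev, c_prev, i, f, g, o, c_t, tc))
        return hs

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        """dh_seq: (B, T, h) gradient w.r.t. each emitted hidden state."""
        B, T, _ = self._x.shape
        h = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c, tc = self._cache[t]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads["Wx"] += self._x[:, t, :].T @ dz
            self.grads["Wh"] += h_prev.T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM; concatenates forward and backward hidden states.

    With ``return_sequences`` the output is ``(B, T, 2*hidden)`` (step t holds
    the forward state after reading residues 1..t and the backward state after
    reading residues T..t). Otherwise the output is ``(B, 2*hidden)``: the two
    final states, i.e. each direction after reading the whole window.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool):
        super().__init__()
        self.in_dim, self.hidden = in_dim, hidden
        self.return_sequences = return_sequences
        self.fwd = _LSTMDirection(in_dim, hidden, rng)
        self.bwd = _LSTMDirection(in_dim, hidden, rng)
        self._sync_params()

    def _sync_params(self) -> None:
        self.params = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        self.params.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        self.grads = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        self.grads.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})

    def zero_grads(self) -> None:
        for d in (self.fwd, self.bwd):
            for k in d.grads:
                d.grads[k][...] = 0.0

    def forward(self, x, *, train=False, rng=None):
        self._T = x.shape[1]
        hs_f = self.fwd.forward(x)
        hs_b = self.bwd.forward(x[:, ::-1, :])
        if self.return_sequences:
            return np.concatenate([hs_f, hs_b[:, ::-1, :]], axis=2)
        return np.concatenate([hs_f[:, -1, :], hs_b[:, -1, :]], axis=1)

    def backward(self, grad):
        h = self.hidden
        B = grad.shape[0]
        if self.return_sequences:
            dh_f = grad[:, :, :h]
            dh_b = grad[:, ::-1, h:]
        else:
            dh_f = np.zeros((B, self._T, h))
            dh_b = np.zeros((B, self._T, h))
            dh_f[:, -1, :] = grad[:, :h]
            dh_b[:, -1, :] = grad[:, h:]
        dx_f = self.fwd.backward(np.ascontiguousarray(dh_f))
        dx_b = self.bwd.backward(np.ascontiguousarray(dh_b))
        return dx_f + dx_b[:, ::-1, :]


class Dense(Layer):
    """Fully connected layer; activation is 'relu' or None (linear)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = "relu"):
        super().__init__()
        if activation not in ("relu", None):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.params = {
            "W": _glorot(rng, in_dim, out_dim, (in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.zero_grads()

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads["W"] += self._x.T @ grad
        self.grads["b"] += grad.sum(axis=0)
        return grad @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Network:
    """An ordered stack of layers ending in a single logit.

    ``predict_proba`` applies the logistic squashing, so scores are in [0, 1];
    the training loop works on the logit for numerical stability (the
    cross-entropy gradient at the logit is simply ``p - y``).
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward_logit(self, x: np.ndarray, *, train: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out.reshape(-1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logit(x, train=False))

    def backward(self, dlogit: np.ndarray) -> None:
        grad = dlogit.reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    # -- parameter access -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i:02d}/{name}": arr
            for i, layer in enumerate(self.layers)
            for name, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i:02d}/{name}": arr
            for i, layer in enumerate(self.layers)
            for name, arr in layer.grads.items()
        }

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(weights) != set(params):
            missing = sorted(set(params) - set(weights))
            extra = sorted(set(weights) - set(params))
            raise ValueError(
                f"weight keys do not match network (missing {missing}, extra {extra})"
            )
        for k, v in params.items():
            w = np.asarray(weights[k])
            if w.shape != v.shape:
                raise ValueError(f"shape mismatch for {k}: {w.shape} vs {v.shape}")
            v[...] = w


class Adam:
    """Adam optimizer over a Network's parameters."""

    def __init__(self, net: Network, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        params = net.parameters()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        params = self.net.parameters()
        grads = self.net.gradients()
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
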