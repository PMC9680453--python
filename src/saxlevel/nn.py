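"""Minimal numpy neural-network core for the classifier heads.

Only the trainable heads live here — the convolutional backbones are
frozen, so the networks that actually train are small: a dense classifier
and recurrent (LSTM/GRU) sequence encoders.  Layers implement explicit
forward/backward passes (float64 throughout), and recurrent layers carry
state through masked time steps so post-padding is inert: a padded input
row can never influence a valid step's output, loss, or gradient, in
either temporal direction.

Gradient correctness is enforced by central-difference checks in the test
suite rather than relying on an autodiff framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Dense",
    "Dropout",
    "LSTMLayer",
    "GRULayer",
    "Bidirectional",
    "Head",
    "Adam",
    "masked_softmax_xent",
    "softmax",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Dropout:
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Head:
    """Per-item classifier: Dense(256) -> ReLU -> Dropout(0.5) -> Dense(5)."""

    def __init__(self, n_in: int, hidden_units: int, dropout_rate: float,
                 n_classes: int, rng: np.random.Generator):
        self.fc1 = Dense(n_in, hidden_units, rng)
        self.fc2 = Dense(hidden_units, n_classes, rng)
        self.drop = Dropout(dropout_rate)
        self._relu_in: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return self.fc1.params + self.fc2.params

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.fc1.forward(x)
        self._relu_in = h
        h = np.maximum(h, 0.0)
        h = self.drop.forward(h, train, rng)
        return self.fc2.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = self.fc2.backward(dout)
        dh = self.drop.backward(dh)
        dh = dh * (self._relu_in > 0)
        return self.fc1.backward(dh)


class LSTMLayer:
    """Unidirectional LSTM over (B, T, D) with mask carry-through.

    At a masked step the cell and hidden state pass through unchanged and
    the emitted output is zero, so padded rows are inert.  Gate order in
    the fused kernels is (i, f, g, o); the forget-gate bias starts at 1.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = Param(_glorot(rng, (n_in, 4 * hidden)))
        self.Wh = Param(_glorot(rng, (hidden, 4 * hidden)))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Param(b)
        self._cache: list[tuple] = []
        self._mask: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        out = np.zeros((B, T, H))
        self._cache = []
        self._mask = mask
        for t in range(T):
            m = mask[:, t : t + 1].astype(np.float64)
            z = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((x[:, t], h, c, i, f, g, o, c_new, tanh_c, m))
            c = m * c_new + (1.0 - m) * c
            h = m * h_new + (1.0 - m) * h
            out[:, t] = h * m
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, _ = dout.shape
        H = self.hidden
        dx = np.zeros((B, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = self._cache[t]
            dh_total = dout[:, t] * m + dh_next
            dh = dh_total * m  # into the cell update
            dh_carry = dh_total * (1.0 - m)
            dc = dc_next * m
            dc_carry = dc_next * (1.0 - m)

            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f

            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            self.Wx.grad += xt.T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T + dh_carry
            dc_next = dc_prev + dc_carry
        return dx


class GRULayer:
    """Unidirectional GRU (classic formulation) with mask carry-through.

    Gate order (z, r, n): h_t = (1-z) * n + z * h_{t-1} with
    n = tanh(x W_xn + (r * h_{t-1}) W_hn + b_n).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.Wx = Param(_glorot(rng, (n_in, 3 * hidden)))
        self.Wh = Param(_glorot(rng, (hidden, 3 * hidden)))
        self.b = Param(np.zeros(3 * hidden))
        self._cache: list[tuple] = []

    @property
    def params(self) -> list[Param]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        out = np.zeros((B, T, H))
        self._cache = []
        for t in range(T):
            m = mask[:, t : t + 1].astype(np.float64)
            ax = x[:, t] @ self.Wx.value + self.b.value
            ahz = h @ self.Wh.value[:, :H]
            ahr = h @ self.Wh.value[:, H : 2 * H]
            z = _sigmoid(ax[:, :H] + ahz)
            r = _sigmoid(ax[:, H : 2 * H] + ahr)
            rh = r * h
            n = np.tanh(ax[:, 2 * H :] + rh @ self.Wh.value[:, 2 * H :])
            h_new = (1.0 - z) * n + z * h
            self._cache.append((x[:, t], h, z, r, n, rh, m))
            h = m * h_new + (1.0 - m) * h
            out[:, t] = h * m
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, _ = dout.shape
        H = self.hidden
        dx = np.zeros((B, T, self.Wx.value.shape[0]))
        dh_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, n, rh, m = self._cache[t]
            dh_total = dout[:, t] * m + dh_next
            dh = dh_total * m
            dh_carry = dh_total * (1.0 - m)

            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z

            dan = dn * (1.0 - n**2)
            drh = dan @ self.Wh.value[:, 2 * H :].T
            self.Wh.grad[:, 2 * H :] += rh.T @ dan
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r

            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            self.Wh.grad[:, :H] += h_prev.T @ daz
            self.Wh.grad[:, H : 2 * H] += h_prev.T @ dar
            dh_prev = dh_prev + daz @ self.Wh.value[:, :H].T + dar @ self.Wh.value[:, H : 2 * H].T

            da = np.concatenate([daz, dar, dan], axis=1)
            self.Wx.grad += xt.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.value.T
            dh_next = dh_prev + dh_carry
        return dx


class Bidirectional:
    """Run one cell forward and an independent cell backward in time.

    The reversed direction sees the reversed sequence and reversed mask;
    the mask carry rule keeps trailing padding inert in both directions.
    Outputs are concatenated (2 x hidden per step).
    """

    def __init__(self, fwd, bwd):
        self.fwd = fwd
        self.bwd = bwd

    @property
    def params(self) -> list[Param]:
        return self.fwd.params + self.bwd.params

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        yf = self.fwd.forward(x, mask)
        yb = self.bwd.forward(x[:, ::-1], mask[:, ::-1])[:, ::-1]
        return np.concatenate([yf, yb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.hidden
        dxf = self.fwd.backward(dout[:, :, :H])
        dxb = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dxf + dxb


def masked_softmax_xent(
    logits: np.ndarray, labels: np.ndarray, mask: np.ndarray | None
) -> tuple[float, np.ndarray, np.ndarray]:
    """Categorical cross-entropy averaged over valid positions.

    Works on (N, K) with mask (N,) or None.  Returns (loss, dlogits,
    probabilities); dlogits is zero at masked positions so padding
    contributes nothing to any gradient.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    valid = np.flatnonzero(mask)
    if valid.size == 0:
        raise ValueError("no valid positions in batch")
    y = labels[valid]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[valid, y] + eps)))
    dlogits = np.zeros_like(logits)
    dlogits[valid] = probs[valid]
    dlogits[valid, y] -= 1.0
    dlogits /= valid.size
    return loss, dlogits, probs


class Adam:
    """Adam with the conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
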