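"""Minimal 1D-convolutional network backend in NumPy.

Implements exactly the layer vocabulary the behaviour classifier needs —
1D valid convolution, dropout, max-pooling, flatten, dense — with
backpropagation and an Adam optimizer, all in float32.  Convolutions are
evaluated as a single GEMM per layer over an im2col view, which keeps a
full training run tractable on one CPU core.

Conventions follow the common deep-learning defaults: Glorot-uniform
weight initialisation, zero biases, inverted dropout (active only during
training), Adam with lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: stateless unless it owns parameters."""

    params: list  # list of np.ndarray, updated in-place by the optimizer
    grads: list   # matching gradients, filled by backward()

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Valid-padding, stride-1 1D convolution with optional ReLU.

    Input (B, L, C_in) -> output (B, L - k + 1, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, activation: str = "relu") -> None:
        super().__init__()
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.activation = activation
        # weight layout (k * c_in, c_out) so the forward pass is one GEMM
        self.w = _glorot_uniform(rng, kernel * c_in, c_out,
                                 (kernel * c_in, c_out))
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, _ = x.shape
        lo = length - self.k + 1
        if lo < 1:
            raise ValueError(
                f"conv kernel {self.k} longer than input length {length}")
        # (B, L', k, C_in) -> (B*L', k*C_in); copy needed for GEMM layout
        patches = sliding_window_view(x, self.k, axis=1)  # (B, L', C_in, k)
        patches = np.ascontiguousarray(patches.transpose(0, 1, 3, 2))
        cols = patches.reshape(b * lo, self.k * self.c_in)
        z = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        if self.activation == "relu":
            np.maximum(z, 0.0, out=z)
            if train:
                self._mask = z > 0
        return z.reshape(b, lo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, lo, _ = dout.shape
        dz = dout.reshape(b * lo, self.c_out)
        if self.activation == "relu":
            dz = dz * self._mask
        self.grads[0][...] = self._cols.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        # dx = full correlation of dz with the kernel flipped along k
        dz3 = dz.reshape(b, lo, self.c_out)
        pad = np.zeros((b, lo + 2 * (self.k - 1), self.c_out),
                       dtype=np.float32)
        pad[:, self.k - 1: self.k - 1 + lo] = dz3
        win = sliding_window_view(pad, self.k, axis=1)  # (B, L, C_out, k)
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
        length = self._in_shape[1]
        cols = win.reshape(b * length, self.k * self.c_out)
        wf = self.w.reshape(self.k, self.c_in, self.c_out)[::-1]
        wf = np.ascontiguousarray(wf.transpose(0, 2, 1)).reshape(
            self.k * self.c_out, self.c_in)
        return (cols @ wf).reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep)
        return x * self._mask / np.float32(keep)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask / np.float32(1.0 - self.rate)


class MaxPool1D(Layer):
    """Non-overlapping max pooling (stride = pool size); trailing
    remainder that does not fill a window is discarded (valid padding)."""

    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        lo = length // self.pool
        xr = x[:, : lo * self.pool].reshape(b, lo, self.pool, c)
        out = xr.max(axis=2)
        if train:
            self._argmax = xr.argmax(axis=2)
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, lo, c = dout.shape
        dx = np.zeros((b, lo, self.pool, c), dtype=np.float32)
        ib, il, ic = np.ogrid[:b, :lo, :c]
        dx[ib, il, self._argmax, ic] = dout
        full = np.zeros(self._in_shape, dtype=np.float32)
        full[:, : lo * self.pool] = dx.reshape(b, lo * self.pool, c)
        return full


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer; activation in {relu, softmax, none}.

    Softmax output is intended to pair with the cross-entropy loss below,
    whose gradient is taken with respect to the pre-softmax logits.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "none") -> None:
        super().__init__()
        self.n_in = n_in
        self.n_out = n_out
        self.activation = activation
        self.w = _glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.w + self.b
        if train:
            self._x = x
        if self.activation == "relu":
            np.maximum(z, 0.0, out=z)
            if train:
                self._mask = z > 0
        elif self.activation == "softmax":
            z = softmax(z)
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # for softmax the caller passes d(loss)/d(logits) directly
        if self.activation == "relu":
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def categorical_crossentropy(probs: np.ndarray, onehot: np.ndarray,
                             eps: float = 1e-7) -> float:
    p = np.clip(probs, eps, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


class Sequential:
    """Ordered layer stack with a softmax/cross-entropy training step."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def train_step(self, x: np.ndarray, onehot: np.ndarray) -> float:
        """One forward/backward pass; fills every layer's grads.

        Returns the batch categorical cross-entropy.  Assumes the final
        layer is Dense(softmax): the combined softmax + cross-entropy
        gradient (probs - targets) / B is fed to its backward pass.
        """
        probs = self.forward(x, train=True)
        loss = categorical_crossentropy(probs, onehot)
        dlogits = (probs - onehot).astype(np.float32) / np.float32(len(x))
        dout = dlogits
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class Adam:
    """Adam optimizer with the standard framework defaults."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
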