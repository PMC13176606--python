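"""Minimal feed-forward neural-network core on NumPy.

Implements exactly the pieces the translation model needs: linear layers,
per-feature batch normalization, leaky-rectifier activation, inverted
dropout, explicit reverse-mode gradients, and the Adam optimizer. Every
forward call returns a cache object so a network can appear several times
in one computation graph (e.g. a translator used by both cycle directions);
parameter gradients accumulate across backward calls until ``zero_grad``.

All arithmetic is float32 by default (float64 available for gradient
checks). With a fixed seed and single-threaded BLAS the whole stack is
bit-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "BatchNorm", "LeakyReLU", "Dropout", "MLP", "Adam"]


class Layer:
    """Base class: parameters, gradients, and a cache-passing forward/backward pair."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])

    def forward(self, x, training: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, cache, gy, param_grads: bool = True):  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


class Linear(Layer):
    """Affine map with fan-in-scaled uniform initialization U(-1/sqrt(fan_in), ...)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        bound = 1.0 / np.sqrt(in_dim)
        self.params["W"] = rng.uniform(-bound, bound, size=(in_dim, out_dim)).astype(dtype)
        self.params["b"] = rng.uniform(-bound, bound, size=out_dim).astype(dtype)
        self.zero_grad()

    def forward(self, x, training, rng):
        return x @ self.params["W"] + self.params["b"], x

    def backward(self, cache, gy, param_grads=True):
        x = cache
        if param_grads:
            self.grads["W"] += x.T @ gy
            self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["W"].T


class BatchNorm(Layer):
    """Per-feature batch normalization with running statistics for eval mode.

    Uses the biased (population) variance both for normalization and the
    running estimate; momentum 0.1. Training batches must have >= 2 rows.
    """

    def __init__(self, dim: int, dtype=np.float32, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(dim, dtype=dtype)
        self.params["beta"] = np.zeros(dim, dtype=dtype)
        self.buffers["running_mean"] = np.zeros(dim, dtype=dtype)
        self.buffers["running_var"] = np.ones(dim, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    def forward(self, x, training, rng):
        if training:
            if x.shape[0] < 2:
                raise ValueError("batch normalization needs batches of size >= 2 in training")
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"] + m * mu).astype(x.dtype)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"] + m * var).astype(x.dtype)
        else:
            mu = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        y = self.params["gamma"] * xhat + self.params["beta"]
        return y, (xhat, inv_std, training)

    def backward(self, cache, gy, param_grads=True):
        xhat, inv_std, training = cache
        if param_grads:
            self.grads["gamma"] += (gy * xhat).sum(axis=0)
            self.grads["beta"] += gy.sum(axis=0)
        g = self.params["gamma"] * inv_std
        if not training:
            return gy * g
        # batch statistics participate in the graph during training
        n = gy.shape[0]
        return g * (gy - gy.mean(axis=0) - xhat * (gy * xhat).mean(axis=0)) if n > 1 else gy * g


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.slope = negative_slope

    def forward(self, x, training, rng):
        neg = x < 0
        y = np.where(neg, self.slope * x, x)
        return y, neg

    def backward(self, cache, gy, param_grads=True):
        neg = cache
        return np.where(neg, self.slope * gy, gy)


class Dropout(Layer):
    """Inverted dropout: active only in training mode; identity in eval."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0.0:
            return x, None
        keep = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64) >= self.p
        scale = np.asarray(1.0 / (1.0 - self.p), dtype=x.dtype)
        mask = keep.astype(x.dtype) * scale
        return x * mask, mask

    def backward(self, cache, gy, param_grads=True):
        if cache is None:
            return gy
        return gy * cache


class MLP:
    """Hidden blocks of Linear -> BatchNorm -> LeakyReLU -> Dropout, linear output layer."""

    def __init__(
        self,
        in_dim: int,
        hidden_dims: list[int],
        out_dim: int,
        rng: np.random.Generator,
        dropout_p: float = 0.2,
        negative_slope: float = 0.01,
        dtype=np.float32,
    ):
        self.in_dim = int(in_dim)
        self.hidden_dims = [int(h) for h in hidden_dims]
        self.out_dim = int(out_dim)
        self.dropout_p = float(dropout_p)
        self.dtype = dtype
        self.trainable = True
        self.layers: list[Layer] = []
        d = in_dim
        for h in self.hidden_dims:
            self.layers.append(Linear(d, h, rng, dtype))
            self.layers.append(BatchNorm(h, dtype))
            self.layers.append(LeakyReLU(negative_slope))
            self.layers.append(Dropout(dropout_p))
            d = h
        self.layers.append(Linear(d, out_dim, rng, dtype))

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        """Return (output, caches). ``caches`` feeds ``backward`` for this call only."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x, training, rng)
            caches.append(cache)
        return x, caches

    def __call__(self, x, training: bool = False, rng=None):
        return self.forward(x, training, rng)[0]

    def backward(self, caches, gy, param_grads: bool | None = None):
        """Propagate ``gy`` back through one recorded forward pass; returns dL/dx.

        Parameter gradients accumulate into each layer (skipped entirely for
        frozen networks, where only the input gradient is needed).
        """
        if param_grads is None:
            param_grads = self.trainable
        gy = np.ascontiguousarray(gy, dtype=self.dtype)
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(cache, gy, param_grads)
        return gy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def parameters(self):
        """Yield (layer, name) handles for every trainable array."""
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def state_arrays(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"{prefix}/{i}/{name}"] = arr
            for name, arr in layer.buffers.items():
                out[f"{prefix}/{i}/{name}"] = arr
        return out

    def load_state_arrays(self, prefix: str, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(arrays[f"{prefix}/{i}/{name}"], dtype=self.dtype)
            for name in layer.buffers:
                layer.buffers[name] = np.array(arrays[f"{prefix}/{i}/{name}"], dtype=self.dtype)
        self.zero_grad()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays("w").items()}


class Adam:
    """Adam with the usual moment defaults (0.9, 0.999) and bias correction."""

    def __init__(self, nets, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        if not isinstance(nets, (list, tuple)):
            nets = [nets]
        self.handles = [(layer, name) for net in nets for layer, name in net.parameters()]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.handles]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.handles]

    def step(self) -> None:
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for i, (layer, name) in enumerate(self.handles):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / c1
            vhat = self.v[i] / c2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype
            )
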