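"""Minimal 3D convolutional network engine (NumPy, manual backprop).

Implements exactly the pieces the contour-position classifier needs:
3x3x3 convolution (stride 1, same padding), spatial batch normalization
(batch size is one volume, so statistics are per-channel over the spatial
grid, with running averages for inference), PReLU with a learned per-channel
negative slope, 2x2x2 max pooling, dense layers, inverted dropout, and a
softmax cross-entropy head with an L2 weight penalty.  Optimization is
stochastic gradient descent with momentum and a decoupled weight-decay term:

    v <- zeta * v - alpha * grad - eta * w,     w <- w + v

with a staircase learning-rate schedule alpha = lr0 * decay^(step // period).

Everything is float32 and bit-deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import truncnorm

__all__ = [
    "prelu",
    "Conv3D",
    "BatchNorm",
    "PReLULayer",
    "MaxPool3D",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "softmax",
    "SGDMomentum",
    "truncated_normal",
]


def prelu(x, a):
    """Parametric ReLU: x for x > 0, a*x for x <= 0 (elementwise)."""
    x = np.asarray(x)
    return np.where(x > 0, x, a * x)


def softmax(z):
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def truncated_normal(rng: np.random.Generator, shape, sigma: float,
                     trunc: float = 2.0) -> np.ndarray:
    """Truncated-normal draw on (-trunc*sigma, trunc*sigma) via inverse CDF."""
    u = rng.random(np.prod(shape))
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    vals = truncnorm.ppf(u, -trunc, trunc, loc=0.0, scale=sigma)
    return vals.reshape(shape).astype(np.float32)


class Layer:
    """Base: parameters in ``self.params``, matching grads in ``self.grads``.
    ``self.decay`` marks which parameters the L2/weight-decay term touches."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.decay: set[str] = set()

    def forward(self, x, train: bool, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3D(Layer):
    """3x3x3 convolution, stride 1, same (zero) padding.  Data layout is
    channels-last: (D, H, W, C)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, sigma: float):
        super().__init__()
        self.params = {
            "w": truncated_normal(rng, (3, 3, 3, cin, cout), sigma),
            "b": np.zeros(cout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.decay = {"w"}

    def forward(self, x, train: bool, rng):
        self._xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(self._xp, (3, 3, 3), axis=(0, 1, 2))
        # win: (D, H, W, C, 3, 3, 3)
        return (
            np.einsum("dhwcijk,ijkco->dhwo", win, self.params["w"], optimize=True)
            + self.params["b"]
        )

    def backward(self, dy):
        win = sliding_window_view(self._xp, (3, 3, 3), axis=(0, 1, 2))
        self.grads["w"][...] = np.einsum("dhwcijk,dhwo->ijkco", win, dy, optimize=True)
        self.grads["b"][...] = dy.sum(axis=(0, 1, 2))
        dyp = np.pad(dy, ((1, 1), (1, 1), (1, 1), (0, 0)))
        win_dy = sliding_window_view(dyp, (3, 3, 3), axis=(0, 1, 2))
        wflip = self.params["w"][::-1, ::-1, ::-1]
        dx = np.einsum("dhwoijk,ijkco->dhwc", win_dy, wflip, optimize=True)
        self._xp = None
        return dx.astype(np.float32)


class BatchNorm(Layer):
    """Per-channel normalization over the spatial grid of one volume.

    A batch is a single volume, so the normalization statistics are spatial;
    running averages (decay 0.9 by default) are used at inference.
    """

    def __init__(self, channels: int, eps: float = 1e-3, decay: float = 0.9):
        super().__init__()
        self.eps = float(eps)
        self.momentum = float(decay)
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, train: bool, rng):
        axes = tuple(range(x.ndim - 1))
        if train:
            m = x.mean(axis=axes, dtype=np.float64)
            v = x.var(axis=axes, dtype=np.float64)
            if getattr(self, "_calibrating", False):
                self._stat_sum[0] += m
                self._stat_sum[1] += v
                self._stat_sum[2] += 1
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * m
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * v
        else:
            m, v = self.running_mean, self.running_var
        ivstd = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m.astype(np.float32)) * ivstd.astype(np.float32)
        self._cache = (xhat, ivstd.astype(np.float32), x.ndim)
        return self.params["gamma"] * xhat + self.params["beta"]

    def begin_calibration(self) -> None:
        self._calibrating = True
        self._stat_sum = [np.zeros_like(self.running_mean),
                          np.zeros_like(self.running_var), 0]

    def end_calibration(self) -> None:
        if self._stat_sum[2] > 0:
            self.running_mean = self._stat_sum[0] / self._stat_sum[2]
            self.running_var = self._stat_sum[1] / self._stat_sum[2]
        self._calibrating = False

    def backward(self, dy):
        xhat, ivstd, ndim = self._cache
        axes = tuple(range(ndim - 1))
        n = float(np.prod(dy.shape[:-1]))
        self.grads["gamma"][...] = (dy * xhat).sum(axis=axes)
        self.grads["beta"][...] = dy.sum(axis=axes)
        dxhat = dy * self.params["gamma"]
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * ivstd
        self._cache = None
        return dx.astype(np.float32)


class PReLULayer(Layer):
    def __init__(self, channels: int, init: float = 0.25):
        super().__init__()
        self.params = {"a": np.full(channels, init, dtype=np.float32)}
        self.grads = {"a": np.zeros(channels, dtype=np.float32)}

    def forward(self, x, train: bool, rng):
        self._x = x
        return prelu(x, self.params["a"])

    def backward(self, dy):
        x = self._x
        axes = tuple(range(x.ndim - 1))
        self.grads["a"][...] = (dy * np.minimum(x, 0)).sum(axis=axes)
        dx = dy * np.where(x > 0, np.float32(1.0), self.params["a"])
        self._x = None
        return dx.astype(np.float32)


class MaxPool3D(Layer):
    """Max pooling with a per-axis window (e.g. (2, 2, 2) or (2, 2, 1));
    floor semantics: trailing remainder slices are dropped."""

    def __init__(self, size=(2, 2, 2)):
        super().__init__()
        self.size = tuple(int(s) for s in size)
        if any(s < 1 for s in self.size):
            raise ValueError(f"invalid pool size {self.size}")

    def forward(self, x, train: bool, rng):
        (sd, sh, sw), (d, h, w, c) = self.size, x.shape
        d2, h2, w2 = d // sd, h // sh, w // sw
        self._in_shape = x.shape
        xc = x[: d2 * sd, : h2 * sh, : w2 * sw]
        xr = xc.reshape(d2, sd, h2, sh, w2, sw, c).transpose(0, 2, 4, 6, 1, 3, 5)
        xr = xr.reshape(d2, h2, w2, c, sd * sh * sw)
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        (sd, sh, sw), (d, h, w, c) = self.size, self._in_shape
        d2, h2, w2 = d // sd, h // sh, w // sw
        dxr = np.zeros((d2, h2, w2, c, sd * sh * sw), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dxc = dxr.reshape(d2, h2, w2, c, sd, sh, sw).transpose(0, 4, 1, 5, 2, 6, 3)
        dxc = dxc.reshape(d2 * sd, h2 * sh, w2 * sw, c)
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[: d2 * sd, : h2 * sh, : w2 * sw] = dxc
        self._idx = None
        return dx


class Flatten(Layer):
    def forward(self, x, train: bool, rng):
        self._shape = x.shape
        return x.reshape(-1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator, sigma: float):
        super().__init__()
        self.params = {
            "w": truncated_normal(rng, (nin, nout), sigma),
            "b": np.zeros(nout, dtype=np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.decay = {"w"}

    def forward(self, x, train: bool, rng):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads["w"][...] = np.outer(self._x, dy)
        self.grads["b"][...] = dy
        dx = self.params["w"] @ dy
        self._x = None
        return dx.astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)

    def forward(self, x, train: bool, rng):
        if not train or self.rate == 0.0 or rng is None:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Network:
    """A plain layer stack mapping one (D, H, W) tensor to 3 class
    probabilities.  ``forward`` returns logits; ``predict_proba`` applies
    softmax in inference mode."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dlogits):
        dy = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    @property
    def num_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    def l2_norm_sq(self, decayed_only: bool = True) -> float:
        tot = 0.0
        for layer in self.layers:
            for name, p in layer.params.items():
                if not decayed_only or name in layer.decay:
                    tot += float((p.astype(np.float64) ** 2).sum())
        return tot

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and running stats."""
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"layer{i}.{name}"] = p
            if isinstance(layer, BatchNorm):
                out[f"layer{i}.running_mean"] = layer.running_mean
                out[f"layer{i}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i}.{name}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]


class SGDMomentum:
    """v <- zeta*v - alpha*grad - eta*w ; w <- w + v, with a staircase
    learning-rate decay every ``decay_period`` global steps."""

    def __init__(self, network: Network, lr_init: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 4e-5, lr_decay: float = 0.1,
                 decay_period: int = 100, clip_norm: float = 5.0):
        self.network = network
        self.lr_init = float(lr_init)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self.lr_decay = float(lr_decay)
        self.decay_period = int(decay_period)
        # single-volume batches produce occasional gradient spikes; a global
        # norm clip keeps the float32 momentum update finite
        self.clip_norm = float(clip_norm)
        self.step_count = 0
        self._vel = {
            (id(layer), name): np.zeros_like(layer.params[name])
            for layer, name in network.parameters()
        }

    @property
    def lr(self) -> float:
        return self.lr_init * self.lr_decay ** (self.step_count // self.decay_period)

    def step(self) -> None:
        alpha = np.float32(self.lr)
        zeta = np.float32(self.momentum)
        eta = np.float32(self.weight_decay)
        scale = np.float32(1.0)
        if self.clip_norm > 0:
            sq = 0.0
            for layer, name in self.network.parameters():
                g = layer.grads[name]
                sq += float((g.astype(np.float64) ** 2).sum())
            gnorm = np.sqrt(sq)
            if gnorm > self.clip_norm:
                scale = np.float32(self.clip_norm / gnorm)
        for layer, name in self.network.parameters():
            w = layer.params[name]
            g = layer.grads[name] * scale
            v = self._vel[(id(layer), name)]
            decay = eta if name in layer.decay else np.float32(0.0)
            v *= zeta
            v -= alpha * g + decay * w
            w += v
        self.step_count += 1
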