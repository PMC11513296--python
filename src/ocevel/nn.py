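"""Minimal NHWC neural-network layers with explicit backpropagation.

A small, purpose-built engine carrying exactly the pieces the velocity
regression network needs: strided and depthwise 2-D convolution with
"same" padding, batch normalisation, ReLU, squeeze-and-excitation
channel gating, global average pooling and a dense head, trained with
Adam.  Arrays are NHWC (batch, height, width, channels).  Every layer
caches what its backward pass needs; gradients are accumulated into a
``grads`` dict parallel to ``params`` so the optimiser can update in
place.  ``Sequential`` can record per-layer activations and activation
gradients, which is what gradient-weighted activation mapping consumes.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "BatchNorm",
    "ReLU",
    "SqueezeExcite",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "mae_loss",
]


def same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output size and (before, after) padding for 'same' convolution."""
    out = -(-size // stride)
    pad = max((out - 1) * stride + kernel - size, 0)
    return out, pad // 2, pad - pad // 2


class Layer:
    """Base layer: named, with params/grads dicts and a forward/backward pair."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """2-D convolution, 'same' padding, optional stride, no bias (BN follows)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, rng=None, use_bias=False, name="conv"):
        super().__init__(name)
        self.in_ch, self.out_ch, self.k, self.s = in_ch, out_ch, kernel, stride
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * kernel * in_ch))  # He init
        self.params["w"] = rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)).astype(np.float32)
        self.use_bias = use_bias
        if use_bias:
            self.params["b"] = np.zeros(out_ch, np.float32)

    def forward(self, x, training=False):
        n, h, w, _ = x.shape
        ho, pt, pb = same_pad(h, self.k, self.s)
        wo, pl, pr = same_pad(w, self.k, self.s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))[:, :: self.s, :: self.s]
        # win: (N, Ho, Wo, C, k, k) -> cols (N*Ho*Wo, k*k*C)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, self.k * self.k * self.in_ch
        )
        # weight (k,k,Cin,Cout) flattened to match cols laid out as (k,k,Cin)
        wmat = self.params["w"].reshape(self.k * self.k * self.in_ch, self.out_ch)
        y = cols @ wmat
        if self.use_bias:
            y = y + self.params["b"]
        self._cache = (cols, x.shape, (ho, wo, pt, pb, pl, pr))
        return y.reshape(n, ho, wo, self.out_ch)

    def backward(self, grad_out):
        cols, xshape, (ho, wo, pt, pb, pl, pr) = self._cache
        n, h, w, c = xshape
        g = grad_out.reshape(n * ho * wo, self.out_ch).astype(cols.dtype)
        wmat = self.params["w"].reshape(self.k * self.k * self.in_ch, self.out_ch)
        self.grads["w"] = (cols.T @ g).reshape(self.params["w"].shape)
        if self.use_bias:
            self.grads["b"] = g.sum(axis=0)
        dcols = (g @ wmat.T).reshape(n, ho, wo, self.k, self.k, c)
        dxp = np.zeros((n, pt + h + pb, pl + w + pr, c), dtype=cols.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + self.s * ho : self.s, j : j + self.s * wo : self.s, :] += dcols[
                    :, :, :, i, j, :
                ]
        return dxp[:, pt : pt + h, pl : pl + w, :]


class DepthwiseConv2D(Layer):
    """Channel-wise 3x3 (by default) convolution, stride 1, 'same' padding."""

    def __init__(self, channels, kernel=3, rng=None, name="dwconv"):
        super().__init__(name)
        self.c, self.k = channels, kernel
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (kernel * kernel))
        self.params["w"] = rng.normal(0.0, std, (kernel, kernel, channels)).astype(np.float32)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        _, pt, pb = same_pad(h, self.k, 1)
        _, pl, pr = same_pad(w, self.k, 1)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))  # (N,H,W,C,k,k)
        y = np.einsum("nhwckl,klc->nhwc", win, self.params["w"], optimize=True)
        self._cache = (win, x.shape, (pt, pb, pl, pr))
        return y.astype(x.dtype)

    def backward(self, grad_out):
        win, xshape, (pt, pb, pl, pr) = self._cache
        n, h, w, c = xshape
        self.grads["w"] = np.einsum("nhwckl,nhwc->klc", win, grad_out, optimize=True)
        dxp = np.zeros((n, pt + h + pb, pl + w + pr, c), dtype=grad_out.dtype)
        wgt = self.params["w"]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h + pt + pb - self.k + 1, j : j + w + pl + pr - self.k + 1, :] += (
                    grad_out * wgt[i, j, :]
                )
        return dxp[:, pt : pt + h, pl : pl + w, :]


class BatchNorm(Layer):
    """Batch normalisation over all non-channel axes (4-D or 2-D input)."""

    # momentum 0.9 keeps the running statistics responsive at the modest
    # step counts of CPU-scale training runs
    def __init__(self, channels, eps=1e-3, momentum=0.9, name="bn"):
        super().__init__(name)
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, np.float32)
        self.params["beta"] = np.zeros(channels, np.float32)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, axes, training, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad_out):
        xhat, inv_std, axes, training, xshape = self._cache
        self.grads["gamma"] = (grad_out * xhat).sum(axis=axes)
        self.grads["beta"] = grad_out.sum(axis=axes)
        dxhat = grad_out * self.params["gamma"]
        if not training:
            return dxhat * inv_std
        m = np.prod([xshape[a] for a in axes])
        return (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        )


class ReLU(Layer):
    def __init__(self, name="relu"):
        super().__init__(name)

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class SqueezeExcite(Layer):
    """Channel gating: x * sigmoid(W2 relu(W1 GAP(x))), bottleneck C/4."""

    def __init__(self, channels, rng=None, name="se"):
        super().__init__(name)
        if channels % 4 != 0:
            raise ValueError(f"SqueezeExcite needs channels divisible by 4, got {channels}")
        self.c = channels
        hidden = channels // 4
        rng = rng or np.random.default_rng(0)
        self.params["w1"] = rng.normal(0, np.sqrt(2.0 / channels), (channels, hidden)).astype(np.float32)
        self.params["b1"] = np.zeros(hidden, np.float32)
        self.params["w2"] = rng.normal(0, np.sqrt(2.0 / hidden), (hidden, channels)).astype(np.float32)
        self.params["b2"] = np.zeros(channels, np.float32)

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        s = x.mean(axis=(1, 2))  # squeeze (N,C)
        pre = s @ self.params["w1"] + self.params["b1"]
        hmid = np.maximum(pre, 0)
        logits = hmid @ self.params["w2"] + self.params["b2"]
        g = 1.0 / (1.0 + np.exp(-logits))  # (N,C)
        self._cache = (x, s, pre, hmid, g)
        return x * g[:, None, None, :]

    def backward(self, grad_out):
        x, s, pre, hmid, g = self._cache
        n, h, w, c = x.shape
        dg = (grad_out * x).sum(axis=(1, 2))
        dx = grad_out * g[:, None, None, :]
        dlogits = dg * g * (1.0 - g)
        self.grads["w2"] = hmid.T @ dlogits
        self.grads["b2"] = dlogits.sum(axis=0)
        dh = (dlogits @ self.params["w2"].T) * (pre > 0)
        self.grads["w1"] = s.T @ dh
        self.grads["b1"] = dh.sum(axis=0)
        ds = dh @ self.params["w1"].T
        dx += ds[:, None, None, :] / (h * w)
        return dx


class GlobalAvgPool(Layer):
    def __init__(self, name="gap"):
        super().__init__(name)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad_out):
        n, h, w, c = self._shape
        return np.broadcast_to(grad_out[:, None, None, :], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None, name="dense"):
        super().__init__(name)
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.params["w"] = rng.normal(0, std, (in_features, out_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, np.float32)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad_out):
        self.grads["w"] = self._x.T @ grad_out
        self.grads["b"] = grad_out.sum(axis=0)
        return grad_out @ self.params["w"].T


class Sequential:
    """Ordered layer stack with optional activation/gradient recording."""

    def __init__(self, layers: list[Layer], name: str = "model"):
        self.layers = layers
        self.name = name
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.activations: dict[str, np.ndarray] = {}
        self.activation_grads: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> Layer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def forward(self, x: np.ndarray, training: bool = False, record: bool = False) -> np.ndarray:
        if record:
            self.activations = {}
        for layer in self.layers:
            x = layer.forward(x, training=training)
            if record:
                self.activations[layer.name] = x
        return x

    def backward(self, grad_out: np.ndarray, record: bool = False) -> np.ndarray:
        if record:
            self.activation_grads = {}
        g = grad_out
        for layer in reversed(self.layers):
            if record:
                self.activation_grads[layer.name] = g
            g = layer.backward(g)
        return g

    def parameters(self):
        for layer in self.layers:
            for key in layer.params:
                yield layer, key

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state_dict(self) -> dict:
        state = {}
        for layer in self.layers:
            for key, val in layer.params.items():
                state[f"{layer.name}/{key}"] = val.copy()
            if isinstance(layer, BatchNorm):
                state[f"{layer.name}/running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}/running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for layer in self.layers:
            for key in layer.params:
                layer.params[key] = state[f"{layer.name}/{key}"].copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = state[f"{layer.name}/running_mean"].copy()
                layer.running_var = state[f"{layer.name}/running_var"].copy()

    def copy_state(self) -> dict:
        return copy.deepcopy(self.state_dict())


class Adam:
    """Adam optimiser over a :class:`Sequential` model's parameters."""

    def __init__(self, model: Sequential, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {f"{l.name}/{k}": np.zeros_like(l.params[k]) for l, k in model.parameters()}
        self.v = {f"{l.name}/{k}": np.zeros_like(l.params[k]) for l, k in model.parameters()}

    def step(self) -> None:
        self.t += 1
        for layer, key in self.model.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            tag = f"{layer.name}/{key}"
            self.m[tag] = self.b1 * self.m[tag] + (1 - self.b1) * g
            self.v[tag] = self.b2 * self.v[tag] + (1 - self.b2) * g * g
            mhat = self.m[tag] / (1 - self.b1**self.t)
            vhat = self.v[tag] / (1 - self.b2**self.t)
            layer.params[key] = (
                layer.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(layer.params[key].dtype)


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = np.sign(diff) / diff.size
    return loss, grad
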