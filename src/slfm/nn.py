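"""Minimal CPU neural-network layers with explicit backpropagation.

The two trainable models in this package (the 3D deblurring/fusion trunk
and the 2D motion-weighting net) are small — a few hundred thousand
parameters — so they run on plain numpy. Each layer implements
``forward(x)`` and ``backward(grad_out)``; ``backward`` accumulates
parameter gradients in ``layer.grads`` and returns the input gradient.
Convolutions use im2col + BLAS matmul; all arithmetic is float32.

Conventions: 3D tensors are (C, D, H, W); 2D tensors are (C, H, W). No
batch axis — training steps here operate on one patch at a time, as the
patch itself carries tens of thousands of pixels.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "Conv2d",
    "LeakyReLU",
    "Softplus",
    "Square",
    "Sigmoid",
    "UpsampleLateral",
    "Upsample2d",
    "Sequential",
    "Adam",
]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}
        self.trainable = True

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out):  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _pad_same(x, k, spatial_axes):
    pads = [(0, 0)] * x.ndim
    for ax, kk in zip(spatial_axes, k):
        p = kk // 2
        pads[ax] = (p, p)
    return np.pad(x, pads)


class Conv3d(Layer):
    """Stride-1 'same' 3D convolution, kernels (Cout, Cin, kd, kh, kw)."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel, kernel)
        self.k = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * int(np.prod(kernel))
        self.params = {
            "w": _he_init(rng, (c_out, c_in) + kernel, fan_in),
            "b": np.zeros(c_out, np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x):
        # x: (Cin, D+pd, H+ph, W+pw) padded -> (D*H*W, Cin*kd*kh*kw)
        win = sliding_window_view(x, self.k, axis=(1, 2, 3))
        # win: (Cin, D, H, W, kd, kh, kw)
        c_in = x.shape[0]
        d, h, w = win.shape[1:4]
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, -1)
        return np.ascontiguousarray(cols, np.float32), (d, h, w)

    def forward(self, x):
        self._x_shape = x.shape
        xp = _pad_same(x, self.k, (1, 2, 3))
        self._cols, out_sp = self._im2col(xp)
        w = self.params["w"].reshape(self.params["w"].shape[0], -1)
        out = self._cols @ w.T + self.params["b"]
        self._out_sp = out_sp
        return np.ascontiguousarray(
            out.T.reshape(w.shape[0], *out_sp), np.float32
        )

    def backward(self, grad_out):
        c_out = grad_out.shape[0]
        g = grad_out.reshape(c_out, -1)  # (Cout, N)
        self.grads["w"] += (g @ self._cols).reshape(self.params["w"].shape)
        self.grads["b"] += g.sum(axis=1)
        # input gradient: full correlation of grad_out with w
        w = self.params["w"]
        c_in = w.shape[1]
        # conv_transpose == conv of grad_out with w flipped, channels swapped
        wt = w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        gp = _pad_same(grad_out, self.k, (1, 2, 3))
        win = sliding_window_view(gp, self.k, axis=(1, 2, 3))
        d, h, w_ = win.shape[1:4]
        cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w_, -1)
        wt2 = np.ascontiguousarray(wt).reshape(c_in, -1)
        gx = cols @ wt2.T
        return np.ascontiguousarray(gx.T.reshape(c_in, d, h, w_), np.float32)


class Conv2d(Layer):
    """Stride-1 'same' 2D convolution, kernels (Cout, Cin, kh, kw)."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        super().__init__()
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        self.k = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * int(np.prod(kernel))
        self.params = {
            "w": _he_init(rng, (c_out, c_in) + kernel, fan_in),
            "b": np.zeros(c_out, np.float32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        xp = _pad_same(x, self.k, (1, 2))
        win = sliding_window_view(xp, self.k, axis=(1, 2))
        h, w = win.shape[1:3]
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w, -1)
        self._cols = np.ascontiguousarray(cols, np.float32)
        wm = self.params["w"].reshape(self.params["w"].shape[0], -1)
        out = self._cols @ wm.T + self.params["b"]
        return np.ascontiguousarray(out.T.reshape(wm.shape[0], h, w), np.float32)

    def backward(self, grad_out):
        c_out = grad_out.shape[0]
        g = grad_out.reshape(c_out, -1)
        self.grads["w"] += (g @ self._cols).reshape(self.params["w"].shape)
        self.grads["b"] += g.sum(axis=1)
        w = self.params["w"]
        c_in = w.shape[1]
        wt = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gp = _pad_same(grad_out, self.k, (1, 2))
        win = sliding_window_view(gp, self.k, axis=(1, 2))
        h, w_ = win.shape[1:3]
        cols = win.transpose(1, 2, 0, 3, 4).reshape(h * w_, -1)
        gx = cols @ np.ascontiguousarray(wt).reshape(c_in, -1).T
        return np.ascontiguousarray(gx.T.reshape(c_in, h, w_), np.float32)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, grad_out):
        return np.where(self._mask, grad_out, self.slope * grad_out).astype(np.float32)


class Softplus(Layer):
    """Non-negative output head: log(1 + e^x), numerically stable."""

    def forward(self, x):
        self._x = x
        return (np.logaddexp(0.0, x)).astype(np.float32)

    def backward(self, grad_out):
        from scipy.special import expit

        return (grad_out * expit(self._x)).astype(np.float32)


class Square(Layer):
    """Non-negative output head: y = x^2.

    Preferred over softplus for sparse fluorescence scenes: near zero its
    gradient attenuates only linearly (2|x|), so dark regions do not freeze
    exponentially and bright structures can still pull the estimate back up
    through the head.
    """

    def forward(self, x):
        self._x = x
        return (x * x).astype(np.float32)

    def backward(self, grad_out):
        return (2.0 * self._x * grad_out).astype(np.float32)


class Sigmoid(Layer):
    def forward(self, x):
        from scipy.special import expit

        self._y = expit(x).astype(np.float32)
        return self._y

    def backward(self, grad_out):
        return (grad_out * self._y * (1.0 - self._y)).astype(np.float32)


def _linear_interp_matrix(n_in: int, num: int, den: int) -> np.ndarray:
    """Sparse-as-dense 1D linear interpolation matrix for factor num/den.

    Output sample i sits at input coordinate (i + 0.5) * den / num - 0.5
    (area-aligned grids); edge samples clamp.
    """
    n_out = n_in * num // den
    A = np.zeros((n_out, n_in), np.float32)
    for i in range(n_out):
        src = (i + 0.5) * den / num - 0.5
        lo = int(np.floor(src))
        f = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        A[i, lo_c] += 1 - f
        A[i, hi_c] += f
    return A


class UpsampleLateral(Layer):
    """Linear interpolation on the last two axes of a (C, D, H, W) tensor.

    Factor is a rational num/den (e.g. 2/1 or 13/12); depth is untouched.
    The backward pass is the exact transpose.
    """

    def __init__(self, num: int, den: int = 1):
        super().__init__()
        self.num, self.den = num, den
        self._mats = {}

    def _mat(self, n):
        if n not in self._mats:
            self._mats[n] = _linear_interp_matrix(n, self.num, self.den)
        return self._mats[n]

    def forward(self, x):
        self._in_shape = x.shape
        Ah = self._mat(x.shape[-2])
        Aw = self._mat(x.shape[-1])
        y = np.tensordot(x, Ah, axes=([-2], [1]))  # (C, D, W, H')
        y = np.tensordot(y, Aw, axes=([-2], [1]))  # (C, D, H', W')
        return np.ascontiguousarray(y, np.float32)

    def backward(self, grad_out):
        Ah = self._mat(self._in_shape[-2])
        Aw = self._mat(self._in_shape[-1])
        g = np.tensordot(grad_out, Ah, axes=([-2], [0]))
        g = np.tensordot(g, Aw, axes=([-2], [0]))
        return np.ascontiguousarray(g, np.float32)


class Upsample2d(Layer):
    """Linear interpolation on the last two axes of a (C, H, W) tensor."""

    def __init__(self, num: int, den: int = 1):
        super().__init__()
        self.num, self.den = num, den
        self._mats = {}

    def _mat(self, n):
        if n not in self._mats:
            self._mats[n] = _linear_interp_matrix(n, self.num, self.den)
        return self._mats[n]

    def forward(self, x):
        self._in_shape = x.shape
        Ah = self._mat(x.shape[-2])
        Aw = self._mat(x.shape[-1])
        y = np.tensordot(x, Ah, axes=([-2], [1]))
        y = np.tensordot(y, Aw, axes=([-2], [1]))
        return np.ascontiguousarray(y, np.float32)

    def backward(self, grad_out):
        Ah = self._mat(self._in_shape[-2])
        Aw = self._mat(self._in_shape[-1])
        g = np.tensordot(grad_out, Ah, axes=([-2], [0]))
        g = np.tensordot(g, Aw, axes=([-2], [0]))
        return np.ascontiguousarray(g, np.float32)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def parameters(self):
        """Yield (layer, name, array) triples for all parameterized layers."""
        for l in self.layers:
            if isinstance(l, Sequential):
                yield from l.parameters()
            else:
                for name, p in l.params.items():
                    yield l, name, p

    def state_dict(self):
        state = {}
        for i, (l, name, p) in enumerate(self.parameters()):
            state[f"{i}:{name}"] = p.copy()
        return state

    def load_state_dict(self, state):
        for i, (l, name, p) in enumerate(self.parameters()):
            p[...] = state[f"{i}:{name}"]


class Adam:
    """Adaptive-moment optimizer over a Sequential's trainable parameters."""

    def __init__(self, model: Sequential, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}
        for i, (l, name, p) in enumerate(model.parameters()):
            self._m[i] = np.zeros_like(p)
            self._v[i] = np.zeros_like(p)

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        for i, (l, name, p) in enumerate(self.model.parameters()):
            if not l.trainable:
                continue
            g = l.grads[name]
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self):
        self.model.zero_grad()
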