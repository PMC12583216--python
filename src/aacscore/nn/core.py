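"""Compact NumPy neural-network core with explicit backpropagation.

Implements exactly the layers the package's two models need — 2-D
convolution (via sliding-window views and GEMM-shaped einsums), batch
normalisation, ReLU, 2x2 max pooling, nearest-neighbour upsampling, linear
layers, dropout and global average pooling — plus the segmentation
(soft-Dice + cross-entropy) and regression (MSE) losses and SGD with
momentum and weight decay.  Every layer caches what its backward pass needs
during forward; all parameter initialisation is driven by a seeded
``numpy.random.Generator``.  All tensors are float32 ``(N, C, H, W)``.

The layer set is deliberately small and fully gradient-checked in the test
suite; it is not a general autodiff framework.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    """A trainable tensor with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: forward caches, backward consumes the cache."""

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def state(self) -> dict[str, np.ndarray]:
        """Flat named-array snapshot (parameters + batchnorm running stats)."""
        out: dict[str, np.ndarray] = {}
        self._collect_state(out, prefix="")
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.state()
        if set(own) != set(state):
            raise ValueError("state keys do not match model structure")
        self._assign_state(state, prefix="")

    def _state_items(self):
        for name, v in self.__dict__.items():
            if isinstance(v, Param):
                yield name, v
            elif isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _collect_state(self, out: dict, prefix: str) -> None:
        for name, v in self._state_items():
            if isinstance(v, Param):
                out[prefix + name] = v.value
            else:
                v._collect_state(out, prefix=f"{prefix}{name}/")
        for name in ("running_mean", "running_var"):
            if name in self.__dict__:
                out[prefix + name] = self.__dict__[name]

    def _assign_state(self, state: dict, prefix: str) -> None:
        for name, v in self._state_items():
            if isinstance(v, Param):
                v.value[...] = state[prefix + name]
            else:
                v._assign_state(state, prefix=f"{prefix}{name}/")
        for name in ("running_mean", "running_var"):
            if name in self.__dict__:
                self.__dict__[name][...] = state[prefix + name]


class Conv2d(Module):
    """3x3/7x7/1x1 convolution with 'same'-style padding and stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Param(np.zeros(out_ch)) if bias else None

    def forward(self, x, train=False):
        K, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        view = sliding_window_view(xp, (K, K), axis=(2, 3))
        cols = view[:, :, ::s, ::s]  # (N, C, Ho, Wo, K, K)
        out = np.einsum("nchwkl,fckl->nfhw", cols, self.weight.value, optimize=True)
        if self.bias is not None:
            out += self.bias.value[:, None, None]
        self._cache = (xp, cols, x.shape)
        return np.ascontiguousarray(out, dtype=F32)

    def backward(self, gy):
        xp, cols, x_shape = self._cache
        K, s, p = self.kernel, self.stride, self.pad
        self.weight.grad += np.einsum("nfhw,nchwkl->fckl", gy, cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        Ho, Wo = gy.shape[2], gy.shape[3]
        for k in range(K):
            for l in range(K):
                gxp[:, :, k : k + s * Ho : s, l : l + s * Wo : s] += np.einsum(
                    "nfhw,fc->nchw", gy, self.weight.value[:, :, k, l], optimize=True
                )
        if p:
            gxp = gxp[:, :, p:-p, p:-p]
        # stride may leave trailing rows/cols of x unused by any window
        gx = np.zeros(x_shape, dtype=F32)
        gx[:, :, : gxp.shape[2], : gxp.shape[3]] = gxp[:, :, : x_shape[2], : x_shape[3]]
        return gx


class _BatchNormBase(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=F32)
        self.running_var = np.ones(num_features, dtype=F32)
        self.momentum, self.eps = momentum, eps

    _axes: tuple[int, ...] = (0,)

    def _shape(self, x):  # broadcastable parameter shape
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * invstd.reshape(sh)
        self._cache = (xhat, invstd, train, x.shape)
        return (self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)).astype(F32)

    def backward(self, gy):
        xhat, invstd, train, x_shape = self._cache
        sh = self._shape(gy)
        self.gamma.grad += (gy * xhat).sum(axis=self._axes)
        self.beta.grad += gy.sum(axis=self._axes)
        g = self.gamma.value.reshape(sh)
        if not train:
            return (gy * g * invstd.reshape(sh)).astype(F32)
        n = np.prod([x_shape[a] for a in self._axes])
        gxhat = gy * g
        gx = (invstd.reshape(sh) / n) * (
            n * gxhat
            - gxhat.sum(axis=self._axes).reshape(sh)
            - xhat * (gxhat * xhat).sum(axis=self._axes).reshape(sh)
        )
        return gx.astype(F32)


class BatchNorm2d(_BatchNormBase):
    _axes = (0, 2, 3)


class BatchNorm1d(_BatchNormBase):
    _axes = (0,)


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, gy):
        return np.where(self._mask, gy, 0).astype(F32)


class Sigmoid(Module):
    def forward(self, x, train=False):
        self._y = (0.5 * (1.0 + np.tanh(0.5 * x))).astype(F32)  # overflow-safe sigmoid
        return self._y

    def backward(self, gy):
        return (gy * self._y * (1.0 - self._y)).astype(F32)


class MaxPool2d(Module):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        Ho, Wo = H // 2, W // 2
        xc = x[:, :, : 2 * Ho, : 2 * Wo]
        xr = xc.reshape(N, C, Ho, 2, Wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Ho, Wo, 4)
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0].astype(F32)

    def backward(self, gy):
        N, C, H, W = self._in_shape
        Ho, Wo = H // 2, W // 2
        g4 = np.zeros((N, C, Ho, Wo, 4), dtype=F32)
        np.put_along_axis(g4, self._idx[..., None], gy[..., None], axis=-1)
        gx = np.zeros(self._in_shape, dtype=F32)
        gx[:, :, : 2 * Ho, : 2 * Wo] = (
            g4.reshape(N, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, 2 * Ho, 2 * Wo)
        )
        return gx


class UpsampleNearest2d(Module):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, train=False):
        self._in_shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3).astype(F32)

    def backward(self, gy):
        N, C, H, W = self._in_shape
        return gy.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)).astype(F32)


class GlobalAvgPool(Module):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3)).astype(F32)

    def backward(self, gy):
        N, C, H, W = self._in_shape
        return (np.broadcast_to(gy[:, :, None, None], self._in_shape) / (H * W)).astype(F32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Param(np.zeros(out_features))

    def forward(self, x, train=False):
        self._x = x
        return (x @ self.weight.value.T + self.bias.value).astype(F32)

    def backward(self, gy):
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return (gy @ self.weight.value).astype(F32)


class Dropout(Module):
    def __init__(self, p: float, seed: int = 0):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self._rng.random(x.shape) >= self.p).astype(F32) / (1.0 - self.p)
        return (x * self._mask).astype(F32)

    def backward(self, gy):
        if self._mask is None:
            return gy
        return (gy * self._mask).astype(F32)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x, train=False):
        for m in self.modules:
            x = m.forward(x, train=train)
        return x

    def backward(self, gy):
        for m in reversed(self.modules):
            gy = m.backward(gy)
        return gy


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    pred = pred.reshape(-1)
    target = np.asarray(target, dtype=F32).reshape(-1)
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, (2.0 * diff / diff.size).astype(F32)


def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=axis, keepdims=True)).astype(F32)


def dice_ce_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    n_classes: int,
    eps: float = 1e-5,
    w_dice: float = 0.5,
    w_ce: float = 0.5,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Combined soft-Dice + cross-entropy segmentation loss.

    ``loss = w_ce * CE + w_dice * (1 - mean foreground soft-Dice)``; returns
    the loss and its gradient with respect to ``logits`` (N, n_classes, H, W).
    Background (class 0) is excluded from the Dice average, as is usual for
    medical segmentation, but fully participates in the cross-entropy.
    ``class_weights`` (length ``n_classes``) reweights pixels in the CE term
    by their true class, guarding minority labels against collapse.
    """
    N, C, H, W = logits.shape
    p = softmax(logits, axis=1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None].astype(np.int64), 1.0, axis=1)

    if class_weights is None:
        wmap = np.ones((N, 1, H, W), dtype=F32)
    else:
        cw = np.asarray(class_weights, dtype=F32)
        if cw.shape != (n_classes,):
            raise ValueError(f"class_weights must have shape ({n_classes},)")
        wmap = cw[labels][:, None]
    npix = float(wmap.sum())
    ce = float(-(wmap * onehot * np.log(np.clip(p, 1e-12, None))).sum() / npix)

    fg = range(1, C)
    dices, dLdp = [], np.zeros_like(p)
    n_fg = C - 1
    for c in fg:
        A = float((p[:, c] * onehot[:, c]).sum())
        B = float(p[:, c].sum() + onehot[:, c].sum())
        d = (2 * A + eps) / (B + eps)
        dices.append(d)
        # d(1-d)/dp_c, averaged over foreground classes
        dLdp[:, c] += -(2 * onehot[:, c] * (B + eps) - (2 * A + eps)) / ((B + eps) ** 2 * n_fg)
    dice_loss = 1.0 - float(np.mean(dices))
    loss = w_ce * ce + w_dice * dice_loss

    # CE gradient w.r.t. logits is w*(p - y)/sum(w); Dice gradient goes
    # through the softmax Jacobian: gz_c = p_c * (dLdp_c - sum_k dLdp_k p_k).
    gz = w_ce * wmap * (p - onehot) / npix
    gz += w_dice * p * (dLdp - (dLdp * p).sum(axis=1, keepdims=True))
    return loss, gz.astype(F32)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with momentum and (coupled) weight decay."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p.grad + self.weight_decay * p.value
            v *= self.momentum
            v -= self.lr * g
            p.value += v


class Adam:
    """Adam optimiser (bias-corrected first/second moments)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad + self.weight_decay * p.value
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
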