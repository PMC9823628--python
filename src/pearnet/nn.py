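"""Minimal reverse-mode autograd on numpy arrays.

This module supplies exactly the primitives the detector needs — 2-D
convolution, batch normalisation, max pooling, nearest-neighbour upsampling,
batched matrix products and the usual pointwise nonlinearities — each with a
hand-written backward pass.  Tensors wrap ``numpy.ndarray`` (float32 by
default) and record a tape of parent nodes; ``Tensor.backward`` walks the
tape in reverse topological order.

A process-global multiply-accumulate counter can be armed with
:func:`count_macs`; while active, conv and matmul forward passes add their
MAC cost to it.  This is how the profiler measures FLOPs without a separate
shape-propagation code path.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Conv2d", "BatchNorm2d",
    "SGD", "count_macs", "concat", "bce_with_logits",
]

_DTYPE = np.float32

# ---------------------------------------------------------------------------
# MAC counting
# ---------------------------------------------------------------------------

_MAC_COUNTER: list[int] | None = None


@contextlib.contextmanager
def count_macs():
    """Context manager yielding a one-element list accumulating MACs."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = counter = [0]
    try:
        yield counter
    finally:
        _MAC_COUNTER = prev


def _add_macs(n: int) -> None:
    if _MAC_COUNTER is not None:
        _MAC_COUNTER[0] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _sum_to(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (result of a broadcast op) back to ``shape``."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd machinery -------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=_DTYPE))

    def __add__(self, other):
        other = self._wrap(other)
        out = _node(self.data + other.data, (self, other))
        def _bw():
            if self.requires_grad or self._prev:
                self._accum(_sum_to(out.grad, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_sum_to(out.grad, other.data.shape))
        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = _node(self.data * other.data, (self, other))
        def _bw():
            if self.requires_grad or self._prev:
                self._accum(_sum_to(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_sum_to(out.grad * self.data, other.data.shape))
        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = _node(self.data / other.data, (self, other))
        def _bw():
            if self.requires_grad or self._prev:
                self._accum(_sum_to(out.grad / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_sum_to(-out.grad * self.data / other.data ** 2,
                                     other.data.shape))
        out._backward = _bw
        return out

    def __pow__(self, p: float):
        out = _node(self.data ** p, (self,))
        out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        def _bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)  # duplicate fancy indices accumulate
            self._accum(g)
        out._backward = _bw
        return out

    def maximum(self, other):
        other = self._wrap(other)
        out = _node(np.maximum(self.data, other.data), (self, other))
        def _bw():
            mask = self.data >= other.data
            if self.requires_grad or self._prev:
                self._accum(_sum_to(out.grad * mask, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_sum_to(out.grad * ~mask, other.data.shape))
        out._backward = _bw
        return out

    def minimum(self, other):
        other = self._wrap(other)
        out = _node(np.minimum(self.data, other.data), (self, other))
        def _bw():
            mask = self.data <= other.data
            if self.requires_grad or self._prev:
                self._accum(_sum_to(out.grad * mask, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_sum_to(out.grad * ~mask, other.data.shape))
        out._backward = _bw
        return out

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(*axes), (self,))
        out._backward = lambda: self._accum(out.grad.transpose(*inv))
        return out

    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                ax = (axis,) if isinstance(axis, int) else axis
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in ax))
            self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities -----------------------------------------------------
    def sigmoid(self):
        s = _sigmoid(self.data)
        out = _node(s, (self,))
        out._backward = lambda: self._accum(out.grad * s * (1.0 - s))
        return out

    def silu(self):
        s = _sigmoid(self.data)
        out = _node(self.data * s, (self,))
        out._backward = lambda: self._accum(out.grad * (s * (1.0 + self.data * (1.0 - s))))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = _node(e, (self,))
        out._backward = lambda: self._accum(out.grad * e)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        out._backward = lambda: self._accum(out.grad / self.data)
        return out

    def clip(self, lo, hi):
        out = _node(np.clip(self.data, lo, hi), (self,))
        mask = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda: self._accum(out.grad * mask)
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = _node(s, (self,))
        def _bw():
            g = out.grad
            self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    # -- linear algebra -----------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = _node(self.data @ other.data, (self, other))
        _add_macs(out.data.size // out.data.shape[-1]
                  * self.data.shape[-1] * out.data.shape[-1])
        def _bw():
            g = out.grad
            if self.requires_grad or self._prev:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_sum_to(ga, self.data.shape))
            if other.requires_grad or other._prev:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_sum_to(gb, other.data.shape))
        out._backward = _bw
        return out

    __matmul__ = matmul


def _node(data: np.ndarray, prev: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._prev = tuple(p for p in prev if isinstance(p, Tensor))
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# Functional ops with dedicated kernels
# ---------------------------------------------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def _bw():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(a, b)
            t._accum(out.grad[tuple(sl)])
    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col + matmul."""
    N, C, H, W = x.data.shape
    O, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    s, p = stride, padding
    OH = (H + 2 * p - kh) // s + 1
    OW = (W + 2 * p - kw) // s + 1
    if OH < 1 or OW < 1:
        raise ValueError("conv2d: output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    cols = np.empty((N, C, kh, kw, OH, OW), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + s * OH:s, j:j + s * OW:s]
    colsm = cols.reshape(N, C * kh * kw, OH * OW)
    wm = w.data.reshape(O, C * kh * kw)
    y = np.matmul(wm, colsm).reshape(N, O, OH, OW)
    _add_macs(N * O * OH * OW * C * kh * kw)
    if b is not None:
        y = y + b.data.reshape(1, O, 1, 1)
    out = _node(y, (x, w) + ((b,) if b is not None else ()))

    def _bw():
        g = out.grad
        gm = g.reshape(N, O, OH * OW)
        if w.requires_grad or w._prev:
            gw = np.einsum("nop,nkp->ok", gm, colsm, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._prev):
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcols = np.matmul(wm.T, gm).reshape(N, C, kh, kw, OH, OW)
            gxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=_DTYPE)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += gcols[:, :, i, j]
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out._backward = _bw
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None,
               padding: int = 0) -> Tensor:
    """Max pooling; backward routes gradient to every max-attaining input."""
    s = stride or kernel
    k, p = kernel, padding
    N, C, H, W = x.data.shape
    OH = (H + 2 * p - k) // s + 1
    OW = (W + 2 * p - k) // s + 1
    xp = (np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                 constant_values=-np.inf) if p else x.data)
    y = np.full((N, C, OH, OW), -np.inf, dtype=_DTYPE)
    for i in range(k):
        for j in range(k):
            np.maximum(y, xp[:, :, i:i + s * OH:s, j:j + s * OW:s], out=y)
    out = _node(y, (x,))

    def _bw():
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                view = xp[:, :, i:i + s * OH:s, j:j + s * OW:s]
                gxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += out.grad * (view == y)
        x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out._backward = _bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _node(y, (x,))
    def _bw():
        g = out.grad.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))
        x._accum(g)
    out._backward = _bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(_DTYPE) / (1.0 - p)
    return x * Tensor(mask)


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    reduction: str = "mean") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    z = np.asarray(targets, dtype=_DTYPE)
    x = logits.data
    loss = np.maximum(x, 0) - x * z + np.log1p(np.exp(-np.abs(x)))
    if reduction == "mean":
        val, scale = loss.mean(), 1.0 / loss.size
    elif reduction == "sum":
        val, scale = loss.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    out = _node(np.asarray(val), (logits,))
    out._backward = lambda: logits._accum((_sigmoid(x) - z) * (out.grad * scale))
    return out


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------


class Module:
    """Tiny module base: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # buffers (running BN stats) are discovered by attribute convention
    def named_buffers(self, prefix: str = ""):
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray) and k.startswith("running_"):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{k}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        sd = {k: p.data.copy() for k, p in self.named_parameters()}
        sd.update({k: v.copy() for k, v in self.named_buffers()})
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray], strict: bool = True):
        """Load matching entries; returns (loaded, skipped) name lists."""
        loaded, skipped = [], []
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        for k, arr in sd.items():
            target = own_p.get(k)
            if target is not None:
                if target.data.shape == arr.shape:
                    target.data = arr.astype(_DTYPE).copy()
                    loaded.append(k)
                else:
                    skipped.append(k)
                continue
            if k in own_b:
                if own_b[k].shape == arr.shape:
                    own_b[k][...] = arr
                    loaded.append(k)
                else:
                    skipped.append(k)
                continue
            skipped.append(k)
        if strict and skipped:
            raise KeyError(f"state mismatch for keys: {skipped[:5]}...")
        return loaded, skipped

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(_DTYPE)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, dtype=_DTYPE))
        self.bias = Parameter(np.zeros(c, dtype=_DTYPE))
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
            xn = xc * (var + self.eps) ** -0.5
        else:
            xn = (x + Tensor(-self.running_mean.reshape(1, -1, 1, 1))) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1))
        return xn * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (c_in, c_out), c_in))
        self.bias = Parameter(np.zeros(c_out, dtype=_DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class SGD:
    """SGD with momentum and decoupled-style weight decay (stock YOLO recipe:
    decay applied only to conv/linear weights, not biases or BN scales)."""

    def __init__(self, params_decay: list[Parameter], params_nodecay: list[Parameter],
                 lr: float, momentum: float = 0.937, weight_decay: float = 0.00048):
        self.groups = [
            {"params": params_decay, "wd": weight_decay},
            {"params": params_nodecay, "wd": 0.0},
        ]
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self):
        for g in self.groups:
            for p in g["params"]:
                if p.grad is None:
                    continue
                d = p.grad + g["wd"] * p.data
                v = self._vel.get(id(p))
                if v is None:
                    v = np.zeros_like(p.data)
                    self._vel[id(p)] = v
                v *= self.momentum
                v += d
                p.data -= self.lr * v
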