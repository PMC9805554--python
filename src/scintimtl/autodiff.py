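"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the multi-task segmentation network and its
losses need: broadcasted arithmetic, matmul, 3x3 "same" convolution, 2x2 max
pooling, 2x2-stride-2 transposed convolution, channel concatenation, instance
normalization, ReLU/sigmoid/softmax/log, reductions, and a zero-padded spatial
shift (used by the CRF regularizer). Gradients of every primitive are checked
against central finite differences in the test suite.

Array layout is NCHW (batch, channel, row, column) throughout.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other, self.dtype)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other, self.dtype)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bwd)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), parents=(self,), backward=bwd)

    # ----------------------------------------------------------- nonlinearity
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; the gradient passes only through unclamped entries."""
        mask = (self.data >= lo) & (self.data <= hi)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    def softmax(self, axis: int = 1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            self._accumulate(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        return Tensor(s, parents=(self,), backward=bwd)

    # ------------------------------------------------------------ convolution
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Same-padded stride-1 2D convolution (cross-correlation), NCHW.

        weight: (out_ch, in_ch, k, k) with k odd.
        """
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        o, ci, k, k2 = w.shape
        assert k == k2 and k % 2 == 1 and ci == c, (x.shape, w.shape)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        s0, s1, s2, s3 = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, (n, c, k, k, h, wd), (s0, s1, s2, s3, s2, s3)
        ).reshape(n, c * k * k, h * wd)
        wmat = w.reshape(o, c * k * k)
        out = np.matmul(wmat, cols).reshape(n, o, h, wd)
        del cols, xp  # large im2col buffers must not outlive the forward pass
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        def bwd(g):
            # re-derive the im2col buffer instead of retaining it in this
            # closure (k^2 x activation memory otherwise); two GEMMs do the
            # heavy lifting, the k^2 loop only scatter-adds views
            gm = g.reshape(n, o, h * wd)
            xp = np.pad(self.data, ((0, 0), (0, 0), (p, p), (p, p)))
            t0, t1, t2, t3 = xp.strides
            cols = np.lib.stride_tricks.as_strided(
                xp, (n, c, k, k, h, wd), (t0, t1, t2, t3, t2, t3)
            ).reshape(n, c * k * k, h * wd)
            if weight.requires_grad:
                gw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(o, c, k, k)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gc = np.matmul(wmat.T, gm).reshape(n, c, k, k, h, wd)
                gxp = np.zeros_like(xp)
                for a in range(k):
                    for b in range(k):
                        gxp[:, :, a : a + h, b : b + wd] += gc[:, :, a, b]
                self._accumulate(gxp[:, :, p : p + h, p : p + wd])

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor(out, parents=parents, backward=bwd)

    def maxpool2(self) -> "Tensor":
        """2x2 max pooling with stride 2 (ties resolved to the first entry)."""
        n, c, h, w = self.shape
        h2, w2 = h // 2, w // 2
        xr = self.data[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = xf.argmax(axis=-1)
        out = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gf = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            gx = gf.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, 2 * h2, 2 * w2
            )
            if (h, w) != (2 * h2, 2 * w2):
                gx = np.pad(gx, ((0, 0), (0, 0), (0, h - 2 * h2), (0, w - 2 * w2)))
            self._accumulate(gx)

        return Tensor(out, parents=(self,), backward=bwd)

    def conv_transpose2(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Transposed convolution, kernel 2, stride 2 (doubles H and W).

        weight: (in_ch, out_ch, 2, 2). Non-overlapping, so each input pixel
        maps to an independent 2x2 output block.
        """
        x = self.data
        w = weight.data
        n, c, h, wd = x.shape
        ci, o, _, _ = w.shape
        assert ci == c
        out6 = np.einsum("ncij,coab->noiajb", x, w, optimize=True)
        out = out6.reshape(n, o, 2 * h, 2 * wd)
        if bias is not None:
            out = out + bias.data.reshape(1, o, 1, 1)

        def bwd(g):
            g6 = g.reshape(n, o, h, 2, wd, 2)
            if weight.requires_grad:
                weight._accumulate(np.einsum("ncij,noiajb->coab", x, g6, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                self._accumulate(np.einsum("noiajb,coab->ncij", g6, w, optimize=True))

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor(out, parents=parents, backward=bwd)

    # --------------------------------------------------------- normalization
    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Per-sample, per-channel normalization over the spatial axes."""
        x = self.data
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        gm = gamma.data.reshape(1, -1, 1, 1)
        out = gm * xhat + beta.data.reshape(1, -1, 1, 1)

        def bwd(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gh = g * gm
                m1 = gh.mean(axis=(2, 3), keepdims=True)
                m2 = (gh * xhat).mean(axis=(2, 3), keepdims=True)
                self._accumulate(inv * (gh - m1 - xhat * m2))

        return Tensor(out, parents=(self, gamma, beta), backward=bwd)

    # ------------------------------------------------------------------ shift
    def shift2d(self, dy: int, dx: int) -> "Tensor":
        """Spatial shift with zero fill: out[..., i, j] = x[..., i+dy, j+dx]."""
        out = np.zeros_like(self.data)
        h, w = self.shape[-2:]
        ys = slice(max(0, -dy), min(h, h - dy))
        yd = slice(max(0, dy), min(h, h + dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        xd = slice(max(0, dx), min(w, w + dx))
        out[..., ys, xs] = self.data[..., yd, xd]

        def bwd(g):
            gx = np.zeros_like(self.data)
            gx[..., yd, xd] = g[..., ys, xs]
            self._accumulate(gx)

        return Tensor(out, parents=(self,), backward=bwd)


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=dtype if dtype is not None else np.float32)
    return Tensor(arr)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along `axis` (used for U-Net skip connections)."""
    sizes = [t.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor(out, parents=tuple(tensors), backward=bwd)


class Adam:
    """Adaptive moment estimation with decoupled inverse-time LR decay.

    `momentum` maps to beta1; `weight_decay` is classic L2 added to the
    gradient; the step-t learning rate is lr / (1 + lr_decay * t).
    """

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        lr_decay: float = 1e-8,
        momentum: float = 0.9,
        beta2: float = 0.999,
        weight_decay: float = 1e-4,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.lr_decay = lr, lr_decay
        self.b1, self.b2 = momentum, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr / (1.0 + self.lr_decay * self.t)
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= lr_t * mhat / (np.sqrt(vhat) + self.eps)
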