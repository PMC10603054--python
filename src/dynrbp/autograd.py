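"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the binding model needs: broadcasted
arithmetic, matmul (batched), 1-D convolution via im2col, max-pooling,
reductions, softmax and elementwise nonlinearities.  Gradients accumulate
into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (evaluation mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _coerce_like(self, x) -> "Tensor":
        """Wrap scalars at this tensor's float dtype to avoid silent
        float64 promotion."""
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if arr.ndim == 0 and np.issubdtype(self.data.dtype, np.floating):
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def __add__(self, other):
        other = self._coerce_like(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce_like(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce_like(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                a2 = a[None, :]
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2))[..., 0, :]
                gb = np.swapaxes(a2, -1, -2) @ g[..., None, :]
            elif b.ndim == 1:
                ga = g[..., :, None] @ b[None, :]
                gb = np.swapaxes(a, -1, -2) @ g[..., :, None]
                gb = gb[..., 0]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(np.where(mask, self.data, 0.0), (self,),
                            lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out_data, (self,),
                            lambda g: (g * out_data * (1.0 - out_data),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * (1.0 - out_data ** 2),))

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(out_data, (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # split ties evenly so the gradient check stays clean
        mask = mask / mask.sum(axis=axis, keepdims=True)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (g * mask,)

        return Tensor._make(out_data if keepdims else out_data.squeeze(axis),
                            (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._make(out_data, (self,), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(out_data, (self,), backward)

    def pad_last(self, before: int, after: int, value: float = 0.0):
        """Constant-pad the last axis."""
        pad = [(0, 0)] * (self.ndim - 1) + [(before, after)]
        out_data = np.pad(self.data, pad, constant_values=value)
        length = self.shape[-1]

        def backward(g):
            return (g[..., before:before + length],)

        return Tensor._make(out_data, (self,), backward)

    # -- structured ops -------------------------------------------------------
    def batchnorm_train(self, gamma: "Tensor", beta: "Tensor",
                        eps: float = 1e-5):
        """Fused training-mode batch normalization over axes (0, 2) of an
        (N, C, L) tensor.  Returns ``(out, mean, var)`` with mean/var as
        plain per-channel arrays for running-statistic updates."""
        x = self.data
        axes = (0, 2)
        n_red = x.shape[0] * x.shape[2]
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mean) * inv_std
        g_col = gamma.data.reshape(1, -1, 1)
        out_data = xhat * g_col + beta.data.reshape(1, -1, 1)

        def backward(g):
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            mean_g = g.mean(axis=axes, keepdims=True)
            mean_gx = (g * xhat).mean(axis=axes, keepdims=True)
            dx = (g_col * inv_std) * (g - mean_g - xhat * mean_gx)
            return dx, dgamma, dbeta

        out = Tensor._make(out_data, (self, gamma, beta), backward)
        return out, mean.ravel(), var.ravel()

    def conv1d(self, weight: "Tensor", padding: int = 0):
        """1-D cross-correlation, no bias.

        self: (N, C_in, L); weight: (C_out, C_in, K) -> (N, C_out, L_out)
        with L_out = L + 2*padding - K + 1.
        """
        x, w = self.data, weight.data
        n, c_in, length = x.shape
        c_out, c_in_w, k = w.shape
        if c_in != c_in_w:
            raise ValueError(f"conv1d channel mismatch: input {c_in}, kernel {c_in_w}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        else:
            xp = x
        l_out = xp.shape[-1] - k + 1
        # shift-and-matmul: k small GEMMs instead of an im2col copy
        out_data = np.matmul(w[:, :, 0], xp[:, :, :l_out])
        for kk in range(1, k):
            out_data += np.matmul(w[:, :, kk], xp[:, :, kk:kk + l_out])

        def backward(g):
            gw = np.empty_like(w)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                xs = xp[:, :, kk:kk + l_out]
                gw[:, :, kk] = np.tensordot(g, xs, axes=([0, 2], [0, 2]))
                gxp[:, :, kk:kk + l_out] += np.matmul(w[:, :, kk].T, g)
            gx = gxp[:, :, padding:padding + length] if padding else gxp
            return gx, gw

        return Tensor._make(out_data, (self, weight), backward)

    def maxpool1d(self, size: int = 3, stride: int = 2):
        """Max pool over the last axis; requires L >= size."""
        x = self.data
        length = x.shape[-1]
        if length < size:
            raise ValueError(f"maxpool1d: length {length} < pool size {size}")
        l_out = (length - size) // stride + 1
        windows = np.lib.stride_tricks.sliding_window_view(x, size, axis=-1)
        windows = windows[..., ::stride, :]  # (..., L_out, size)
        out_data = windows.max(axis=-1)
        arg = windows.argmax(axis=-1)  # (..., L_out)

        def backward(g):
            gx = np.zeros_like(x)
            idx_last = np.arange(l_out) * stride + arg  # (..., L_out)
            flat_gx = gx.reshape(-1, length)
            rows = np.arange(flat_gx.shape[0])[:, None]
            np.add.at(flat_gx, (rows, idx_last.reshape(-1, l_out)),
                      g.reshape(-1, l_out))
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    # -- backprop -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if p._backward is None and p._parents == ():
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)
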