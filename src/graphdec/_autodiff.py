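"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the deconvolution model needs: dense and
sparse matrix products, broadcasting elementwise arithmetic, ReLU/sigmoid/
log/exp/sqrt, reductions, row gathering, concatenation, a numerically
stable softmax, and a gradient-reversal pass-through for adversarial
training. Gradients are accumulated into ``Tensor.grad`` by ``backward()``
over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_shared = False

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        # first contribution adopts the array (may alias the child's
        # buffer); a second contribution allocates instead of mutating,
        # so shared buffers are never corrupted
        if self.grad is None:
            self.grad = grad
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _coerce(self, other):
        """Wrap scalars in the tensor's own dtype to avoid silent upcasts."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._result(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._result(out_data, (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._result(out_data, (self, other), bw)

    @property
    def T(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor._result(self.data.T, (self,), bw)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(out_data, (self,), bw)

    def sigmoid(self):
        from scipy.special import expit

        out_data = expit(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), bw)

    def softplus(self):
        """log(1 + exp(x)), computed stably; gradient is sigmoid(x)."""
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            if self.requires_grad:
                from scipy.special import expit

                self._accum(g * expit(self.data))

        return Tensor._result(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._result(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._result(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only through the interior."""
        mask = (self.data > lo) & (self.data < hi)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._result(out_data, (self,), bw)

    # -- reductions / reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_rows(self, idx):
        idx = np.asarray(idx)
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data, dtype=g.dtype)
                np.add.at(acc, idx, g)
                self._accum(acc)

        return Tensor._result(out_data, (self,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._result(out_data, tuple(tensors), bw)


def spmm(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product (the graph aggregation)."""
    a = sp.csr_matrix(a)
    out_data = a @ x.data

    def bw(g):
        if x.requires_grad:
            x._accum(a.T @ g)

    return Tensor._result(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shift = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def grad_reverse(x: Tensor, lam: float = 1.0) -> Tensor:
    """Identity forward; multiplies the gradient by -lam on the way back."""
    lam = float(lam)

    def bw(g):
        if x.requires_grad:
            x._accum(g * np.asarray(-lam, dtype=g.dtype))

    return Tensor._result(x.data, (x,), bw)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 lr_scales: list[float] | None = None):
        self.params = params
        self.lr = lr
        self.lr_scales = lr_scales or [1.0] * len(params)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - (self.lr * self.lr_scales[i]) * mhat / (
                np.sqrt(vhat) + self.eps)
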