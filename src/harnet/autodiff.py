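"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based autodiff engine: tensors wrap numpy
arrays and record the operations that produced them; calling
:meth:`Tensor.backward` on a scalar loss walks the tape in reverse
topological order and accumulates gradients into every tensor with
``requires_grad=True``.

Only the operations the activity-recognition network needs are
implemented (broadcast arithmetic, batched matmul, same-length 1-D
convolution, layer normalisation, softmax, weighted cross-entropy).
Gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "relu",
    "sigmoid",
    "softmax",
    "layer_norm",
    "conv1d_same",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _result(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python scalars stay "weak" so they never upcast float32 data

            def backward(g, a=self):
                if a.requires_grad:
                    a._accumulate(g)

            return self._result(self.data + other, (self,), backward)
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):

            def backward(g, a=self, c=other):
                if a.requires_grad:
                    a._accumulate(g * c)

            return self._result(self.data * other, (self,), backward)
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return self._result(self.data / other.data, (self, other), backward)

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1))

        return self._result(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a_nd, b_nd = self.data.ndim, other.data.ndim

        if a_nd > 2 and b_nd == 2:
            # stacked-vectors @ matrix: collapse the batch axes into one
            # GEMM instead of looping many small ones
            A, B = self.data, other.data
            A2 = A.reshape(-1, A.shape[-1])
            out = (A2 @ B).reshape(*A.shape[:-1], B.shape[1])

            def backward(g, a=self, b=other, A2=A2, B=B):
                g2 = g.reshape(-1, g.shape[-1])
                if a.requires_grad:
                    a._accumulate((g2 @ B.T).reshape(a.data.shape))
                if b.requires_grad:
                    b._accumulate(A2.T @ g2)

            return self._result(out, (self, other), backward)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return self._result(self.data @ other.data, (self, other), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g, a=self, orig=orig):
            if a.requires_grad:
                a._accumulate(g.reshape(orig))

        return self._result(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))

        def backward(g, a=self, inverse=inverse):
            if a.requires_grad:
                a._accumulate(g.transpose(inverse))

        return self._result(self.data.transpose(axes), (self,), backward)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    # -- autodiff driver ------------------------------------------------------

    def _accumulate(self, g: np.ndarray):
        # first contribution stores the array; later ones allocate a fresh sum,
        # so gradient arrays handed to several parents are never mutated
        self.grad = g if self.grad is None else self.grad + g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this tensor (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient requires a scalar")
            grad = np.ones_like(self.data)
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
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# -- nonlinearities and composite primitives ----------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, a=x, mask=mask):
        if a.requires_grad:
            a._accumulate(g * mask)

    return Tensor._result(np.where(mask, x.data, 0.0), (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    xd = x.data
    s = np.where(xd >= 0, 1.0 / (1.0 + np.exp(-np.abs(xd))),
                 np.exp(-np.abs(xd)) / (1.0 + np.exp(-np.abs(xd))))

    def backward(g, a=x, s=s):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return Tensor._result(s, (x,), backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g, a=x, s=s):
        if a.requires_grad:
            a._accumulate((g - (g * s).sum(axis=-1, keepdims=True)) * s)

    return Tensor._result(s, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std

    def backward(g, a=x, gm=gamma, bt=beta, xhat=xhat, inv_std=inv_std):
        reduce_axes = tuple(range(g.ndim - 1))
        if bt.requires_grad:
            bt._accumulate(g.sum(axis=reduce_axes))
        if gm.requires_grad:
            gm._accumulate((g * xhat).sum(axis=reduce_axes))
        if a.requires_grad:
            gx_hat = g * gm.data
            term = gx_hat - gx_hat.mean(axis=-1, keepdims=True) \
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            a._accumulate(term * inv_std)

    return Tensor._result(xhat * gamma.data + beta.data, (x, gamma, beta), backward)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-length 1-D convolution (cross-correlation), stride 1.

    ``x``: [B, C_in, L]; ``weight``: [C_out, C_in, k] with odd k;
    ``bias``: [C_out]. Output: [B, C_out, L].
    """
    k = weight.data.shape[-1]
    if k % 2 == 0:
        raise ValueError("same-length padding impossible: kernel size must be odd")
    pad = k // 2
    B, c_in, L = x.data.shape
    c_out = weight.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # [B, C_in, L, k] -> [B, L, C_in * k]
    cols = sliding_window_view(xp, k, axis=2)
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B, L, c_in * k)
    wmat = weight.data.reshape(c_out, c_in * k)
    y = cols2 @ wmat.T + bias.data  # [B, L, C_out]
    y = y.transpose(0, 2, 1)

    def backward(g, a=x, w=weight, b=bias, cols2=cols2, wmat=wmat,
                 B=B, L=L, c_in=c_in, c_out=c_out, k=k, pad=pad):
        g2 = g.transpose(0, 2, 1)  # [B, L, C_out]
        if b.requires_grad:
            b._accumulate(g2.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = g2.reshape(-1, c_out).T @ cols2.reshape(-1, c_in * k)
            w._accumulate(gw.reshape(w.data.shape))
        if a.requires_grad:
            gcols = (g2 @ wmat).reshape(B, L, c_in, k).transpose(0, 2, 1, 3)
            gxp = np.zeros((B, c_in, L + 2 * pad), dtype=g.dtype)
            for kk in range(k):
                gxp[:, :, kk:kk + L] += gcols[:, :, :, kk]
            a._accumulate(gxp[:, :, pad:pad + L])

    return Tensor._result(y, (x, weight, bias), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted cross-entropy over a batch of logits.

    ``logits``: [B, K]; ``labels``: int [B]. Weighted mean of per-sample
    negative log-likelihoods, each scaled by its true class's weight and
    normalised by the total weight (so balanced weights reduce to the
    plain mean).
    """
    labels = np.asarray(labels)
    B, K = logits.data.shape
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logZ
    w = np.ones(B, dtype=logits.data.dtype) if class_weights is None \
        else np.asarray(class_weights, dtype=logits.data.dtype)[labels]
    wsum = w.sum()
    loss = -(w * logp[np.arange(B), labels]).sum() / wsum

    def backward(g, a=logits, labels=labels, logp=logp, w=w, wsum=wsum, B=B):
        if a.requires_grad:
            p = np.exp(logp)
            grad = p * w[:, None]
            grad[np.arange(B), labels] -= w
            a._accumulate(grad * (g / wsum))

    return Tensor._result(np.asarray(loss), (logits,), backward)
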