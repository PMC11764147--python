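"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in :mod:`dgil6.nn` is small (peptide graphs have at most a few
dozen nodes) and dense, so a tape-based engine over plain ``ndarray`` values
is sufficient and keeps the whole training path dependency-free and easy to
verify against numerical gradients.

Supported operations cover exactly what the dual-channel model needs:
broadcast-aware ``+``/``*``/``/``, (batched) ``@``, reshape, reductions,
element-wise nonlinearities, masked-softmax building blocks, an attention
contraction, and a fused weighted binary cross-entropy with logits.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "weighted_bce_with_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- infrastructure ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self, free_tape: bool = True) -> None:
        """Backpropagate from this (scalar) tensor through the tape.

        With ``free_tape`` (default) the tape is dismantled afterwards:
        the closure-based graph is cyclic, and breaking it lets large
        intermediates die by reference counting instead of waiting for the
        garbage collector. Leaf gradients survive for the optimiser.
        """
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        if free_tape:
            for node in topo:
                if node._backward is not None:  # interior node, not a leaf
                    node._parents = ()
                    node._backward = None
                    node.grad = None

    def release(self) -> None:
        """Break the tape below this tensor (for inference-only passes)."""
        stack: list[Tensor] = [self]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.extend(node._parents)
            node._parents = ()
            node._backward = None

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)

        def backward():
            other._accum(out.grad)
            self._accum(out.grad)

        out = self._make(self.data + other.data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            self._accum(-out.grad)

        out = self._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward():
            self._accum(out.grad * other.data)
            other._accum(out.grad * self.data)

        out = self._make(self.data * other.data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward():
            self._accum(out.grad / other.data)
            other._accum(-out.grad * self.data / (other.data**2))

        out = self._make(self.data / other.data, (self, other), backward)
        return out

    def __pow__(self, exponent: float):
        def backward():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out = self._make(self.data**exponent, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward():
            a, b = self.data, other.data
            ga = out.grad @ np.swapaxes(b, -1, -2) if b.ndim > 1 else np.outer(out.grad, b)
            gb = np.swapaxes(a, -1, -2) @ out.grad if a.ndim > 1 else np.outer(a, out.grad)
            self._accum(ga)
            other._accum(gb)

        out = self._make(self.data @ other.data, (self, other), backward)
        return out

    # -- shape ------------------------------------------------------------

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape

        def backward():
            self._accum(out.grad.reshape(self.data.shape))

        out = self._make(self.data.reshape(shape), (self,), backward)
        return out

    def __getitem__(self, idx):
        def backward():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out = self._make(self.data[idx], (self,), backward)
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along ``axis``; gradient routes to the first arg-max."""
        idx = np.argmax(self.data, axis=axis)

        def backward():
            g = np.zeros_like(self.data)
            np.put_along_axis(
                g, np.expand_dims(idx, axis), np.expand_dims(out.grad, axis), axis
            )
            self._accum(g)

        out = self._make(np.max(self.data, axis=axis), (self,), backward)
        return out

    # -- nonlinearities ---------------------------------------------------

    def exp(self):
        def backward():
            self._accum(out.grad * out.data)

        out = self._make(np.exp(self.data), (self,), backward)
        return out

    def log(self):
        def backward():
            self._accum(out.grad / self.data)

        out = self._make(np.log(self.data), (self,), backward)
        return out

    def relu(self):
        def backward():
            self._accum(out.grad * (self.data > 0))

        out = self._make(np.maximum(self.data, 0.0), (self,), backward)
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        def backward():
            self._accum(out.grad * np.where(self.data > 0, 1.0, negative_slope))

        out = self._make(
            np.where(self.data > 0, self.data, negative_slope * self.data),
            (self,),
            backward,
        )
        return out

    def sigmoid(self):
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward():
            self._accum(out.grad * sig * (1.0 - sig))

        out = self._make(sig, (self,), backward)
        return out

    # -- attention-specific fused ops --------------------------------------

    def masked_softmax(self, support: np.ndarray, axis: int):
        """Softmax along ``axis`` restricted to ``support`` (a boolean mask).

        Off-support entries are exactly zero in the output and receive no
        gradient. Every slice must contain at least one supported entry.
        """
        x = np.where(support, self.data, -np.inf)
        x = x - np.max(x, axis=axis, keepdims=True)
        ez = np.exp(x, where=np.isfinite(x), out=np.zeros_like(x))
        alpha = ez / ez.sum(axis=axis, keepdims=True)

        def backward():
            g = out.grad
            dot = np.sum(g * alpha, axis=axis, keepdims=True)
            self._accum(alpha * (g - dot))

        out = self._make(alpha, (self,), backward)
        return out

    def pairwise_softmax(self, dst: "Tensor", support: np.ndarray,
                         negative_slope: float = 0.0):
        """Fused attention coefficients from per-node source/target terms.

        ``self`` (src) and ``dst`` have shape ``(B, L, K)``; ``support`` is a
        boolean ``(B, L, L)`` adjacency. Edge logits are
        ``act(src[b,i,k] + dst[b,j,k])`` with ReLU (``negative_slope=0``) or
        leaky ReLU, softmax-normalised over each node's supported
        neighbours ``j``. Fusing the three steps avoids materialising the
        intermediate ``(B, L, L, K)`` arrays on the tape.
        """
        src = self
        dst = self._wrap(dst)
        # single large buffer reused through logits -> exp -> alpha
        z = src.data[:, :, None, :] + dst.data[:, None, :, :]
        pos = z > 0
        if negative_slope == 0.0:
            np.copyto(z, 0.0, where=~pos)
        else:
            np.multiply(z, negative_slope, where=~pos, out=z)
        np.copyto(z, -np.inf, where=~support[..., None])
        z -= np.max(z, axis=2, keepdims=True)
        np.exp(z, out=z)  # exp(-inf) underflows to exactly 0 off-support
        z /= z.sum(axis=2, keepdims=True)
        alpha = z

        def backward():
            buf = out.grad * alpha
            dot = buf.sum(axis=2, keepdims=True)
            np.subtract(out.grad, dot, out=buf)
            buf *= alpha
            if negative_slope == 0.0:
                np.copyto(buf, 0.0, where=~pos)
            else:
                np.multiply(buf, negative_slope, where=~pos, out=buf)
            src._accum(buf.sum(axis=2))
            dst._accum(buf.sum(axis=1))

        out = self._make(alpha, (src, dst), backward)
        return out

    def attend(self, values: "Tensor"):
        """Per-head neighbourhood aggregation.

        ``self``: attention weights ``(B, L, L, K)``; ``values``: projected
        node features ``(B, L, K, d)``. Returns ``(B, L, K, d)`` where
        ``out[b, i, k, :] = sum_j alpha[b, i, j, k] * values[b, j, k, :]``.
        Implemented as head-major batched matmuls.
        """
        alpha, v = self, self._wrap(values)
        a2 = np.ascontiguousarray(alpha.data.transpose(0, 3, 1, 2))  # (B,K,L,L)
        v2 = np.ascontiguousarray(v.data.transpose(0, 2, 1, 3))  # (B,K,L,d)

        def backward():
            g2 = out.grad.transpose(0, 2, 1, 3)  # (B,K,L,d)
            alpha._accum((g2 @ v2.swapaxes(-1, -2)).transpose(0, 2, 3, 1))
            v._accum((a2.swapaxes(-1, -2) @ g2).transpose(0, 2, 1, 3))

        out = self._make((a2 @ v2).transpose(0, 2, 1, 3), (alpha, v), backward)
        return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            t._accum(np.take(out.grad, np.arange(lo, hi), axis=axis))

    out = tensors[0]._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )
    return out


def weighted_bce_with_logits(
    logits: Tensor, labels: np.ndarray, pos_weight: float = 1.0
) -> Tensor:
    """Mean of ``-[w*y*log(sigmoid(p)) + (1-y)*log(1-sigmoid(p))]``.

    Computed in the log-sum-exp form ``c * softplus(a*p)`` with ``a = -1,
    c = pos_weight`` for positives and ``a = +1, c = 1`` for negatives,
    which is exact and stable for logits of any magnitude.
    """
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != logits.data.shape:
        raise ValueError("logits and labels must have the same shape")
    sign = np.where(y == 1, -1.0, 1.0)
    weight = np.where(y == 1, float(pos_weight), 1.0)
    n = max(y.size, 1)
    per_sample = weight * np.logaddexp(0.0, sign * logits.data)

    def backward():
        # d/dp [c*softplus(a*p)] = c*a*sigmoid(a*p)
        z = sign * logits.data
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        logits._accum(out.grad * weight * sign * sig / n)

    out = logits._make(per_sample.sum() / n, (logits,), backward)
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
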