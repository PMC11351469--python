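"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the gated dilated-convolution denoiser needs:
broadcast add/mul, matmul, same-padded dilated 1D convolution, tanh, sigmoid,
ReLU, channel split, and mean reduction.  Gradients are accumulated by a
topological backward sweep.  Correctness is established by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=parents if req else (),
                      backward=backward if req else None)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, self.shape), _unbroadcast(g * a, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (self._lift(other) * Tensor(-1.0))

    def matmul(self, other: "Tensor") -> "Tensor":
        """2D matrix product ``(n, k) @ (k, m)``."""
        other = self._lift(other)
        a, b = self.data, other.data
        out_data = a @ b

        def backward(g):
            return (g @ b.T, a.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities ---------------------------------------------------

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data * out_data),)

        return self._make(out_data, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            return (g * mask,)

        return self._make(out_data, (self,), backward)

    def swish(self) -> "Tensor":
        """x * sigmoid(x) (the smooth gate used in the step-embedding MLP)."""
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def backward(g):
            return (g * (s + out_data * (1.0 - s)),)

        return self._make(out_data, (self,), backward)

    # -- shape ops --------------------------------------------------------

    def split2(self, axis: int = 1) -> tuple["Tensor", "Tensor"]:
        """Split an even axis into two halves (gate/filter split)."""
        n = self.data.shape[axis]
        if n % 2:
            raise ValueError("axis size must be even")
        h = n // 2
        sl_a = [slice(None)] * self.data.ndim
        sl_b = [slice(None)] * self.data.ndim
        sl_a[axis] = slice(0, h)
        sl_b[axis] = slice(h, n)
        sl_a, sl_b = tuple(sl_a), tuple(sl_b)

        def backward_a(g):
            full = np.zeros_like(self.data)
            full[sl_a] = g
            return (full,)

        def backward_b(g):
            full = np.zeros_like(self.data)
            full[sl_b] = g
            return (full,)

        a = self._make(self.data[sl_a], (self,), backward_a)
        b = self._make(self.data[sl_b], (self,), backward_b)
        return a, b

    def narrow(self, axis: int, start: int, length: int) -> "Tensor":
        """Contiguous slice along one axis."""
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def backward(g):
            full = np.zeros_like(self.data)
            full[sl] = g
            return (full,)

        return self._make(self.data[sl], (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            return (g.reshape(old),)

        return self._make(out_data, (self,), backward)

    def mean(self) -> "Tensor":
        n = self.data.size
        out_data = np.asarray(self.data.mean())

        def backward(g):
            return (np.broadcast_to(g / n, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    # -- convolution -------------------------------------------------------

    def conv1d(self, w: "Tensor", b: "Tensor", dilation: int = 1) -> "Tensor":
        """Same-padded (zero) dilated 1D convolution.

        ``self``: (B, Cin, L); ``w``: (Cout, Cin, K) with K odd; ``b``: (Cout,).
        Symmetric zero padding keeps the output length at L, making the layer
        non-causal: every output sample sees both past and future context.
        """
        x = self.data
        W, bias = w.data, b.data
        B, Cin, L = x.shape
        Cout, Cin2, K = W.shape
        if Cin != Cin2 or K % 2 == 0:
            raise ValueError("kernel shape mismatch or even kernel")
        pad = dilation * (K // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        out_data = np.empty((B, Cout, L))
        # (B, Cin, L) gathered per tap, contracted against (Cout, Cin).
        acc = np.zeros((B, Cout, L))
        for k in range(K):
            seg = xp[:, :, k * dilation : k * dilation + L]
            acc += np.einsum("oi,bil->bol", W[:, :, k], seg, optimize=True)
        out_data = acc + bias[None, :, None]

        def backward(g):
            dxp = np.zeros_like(xp)
            dW = np.zeros_like(W)
            for k in range(K):
                seg = xp[:, :, k * dilation : k * dilation + L]
                dW[:, :, k] = np.einsum("bol,bil->oi", g, seg, optimize=True)
                dxp[:, :, k * dilation : k * dilation + L] += np.einsum(
                    "oi,bol->bil", W[:, :, k], g, optimize=True
                )
            dx = dxp[:, :, pad : pad + L] if pad else dxp
            db = g.sum(axis=(0, 2))
            return (dx, dW, db)

        return self._make(out_data, (self, w, b), backward)

    # -- backward sweep ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable ``requires_grad`` tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad += g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] += pg
                else:
                    grads[id(p)] = pg


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """Wrap an array as a trainable tensor."""
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)
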