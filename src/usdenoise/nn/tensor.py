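"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for each operation,
a closure that propagates the output gradient back to its parents.
``backward()`` walks the tape in reverse topological order.  Only the
operations the denoising networks need are provided (see
:mod:`usdenoise.nn.functional`); this is deliberately not a general
framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "set_default_dtype", "get_default_dtype", "no_grad"]

_DTYPE = np.float32
_GRAD_ENABLED = True


class no_grad:
    """Context manager: skip tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def set_default_dtype(dtype) -> None:
    """Set the array dtype used by the tape (float32 default; float64 for
    e.g. finite-difference gradient checks)."""
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


class Tensor:
    """An array node on the autodiff tape.

    Parameters
    ----------
    data : array_like
        Values, stored at the tape default dtype (float32 unless changed).
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _node(data, parents, backward_fn) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward_fn
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- basic ops ----------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        def bw(g, a=self, b=other):
            a._accumulate(g)
            b._accumulate(g)

        return Tensor._node(self.data + other.data, (self, other), bw)

    def __sub__(self, other: "Tensor") -> "Tensor":
        def bw(g, a=self, b=other):
            a._accumulate(g)
            b._accumulate(-g)

        return Tensor._node(self.data - other.data, (self, other), bw)

    def __mul__(self, scalar: float) -> "Tensor":
        s = float(scalar)

        def bw(g, a=self):
            a._accumulate(g * s)

        return Tensor._node(self.data * s, (self,), bw)

    __rmul__ = __mul__

    def sum(self) -> "Tensor":
        def bw(g, a=self):
            a._accumulate(np.broadcast_to(g, a.data.shape))

        return Tensor._node(self.data.sum(), (self,), bw)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bw(g, a=self):
            a._accumulate(np.broadcast_to(g / n, a.data.shape))

        return Tensor._node(self.data.mean(), (self,), bw)

    def square(self) -> "Tensor":
        def bw(g, a=self):
            a._accumulate(2.0 * a.data * g)

        return Tensor._node(self.data ** 2, (self,), bw)

    # -- backprop -----------------------------------------------------------

    def backward(self, grad=None) -> None:
        """Backpropagate from this node; ``grad`` defaults to ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- misc ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
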