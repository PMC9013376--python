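"""A minimal reverse-mode tape over numpy arrays.

Only the handful of operations the super-resolution network needs are
provided: convolution, transpose convolution, ReLU and channel
concatenation. Gradients accumulate into `Parameter` objects; the tape is
rebuilt on every forward pass (define-by-run), so the same network object
handles any input size.
"""

from __future__ import annotations

import numpy as np

from . import ops

__all__ = ["Parameter", "Node", "conv2d", "conv_transpose2d", "relu", "concat", "as_node"]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Node:
    """One value in the computation graph."""

    __slots__ = ("value", "grad", "_backward", "_parents")

    def __init__(self, value, parents=(), backward=None):
        self.value = value
        self.grad = None
        self._parents = parents
        self._backward = backward

    def backward(self, grad: np.ndarray) -> None:
        """Reverse-topological sweep seeding this node with ``grad``."""
        order: list[Node] = []
        seen: set[int] = set()

        def visit(n: Node) -> None:
            if id(n) in seen:
                return
            seen.add(id(n))
            for p in n._parents:
                visit(p)
            order.append(n)

        visit(self)
        for n in order:
            n.grad = None
        self.grad = np.ascontiguousarray(grad, dtype=np.float32)
        for n in reversed(order):
            if n.grad is not None and n._backward is not None:
                n._backward(n.grad)
            n.grad = None  # consumed; free eagerly to bound the working set

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def as_node(x: np.ndarray) -> Node:
    return Node(np.ascontiguousarray(x, dtype=np.float32))


def conv2d(x: Node, w: Parameter, b: Parameter | None, stride: int = 1) -> Node:
    y, cache = ops.conv2d(x.value, w.value, b.value if b is not None else None, stride)
    out = Node(y, parents=(x,))

    def backward(g):
        dx, dw, db = ops.conv2d_backward(g, w.value, cache, with_bias=b is not None)
        w.grad += dw
        if b is not None:
            b.grad += db
        x._accumulate(dx)

    out._backward = backward
    return out


def conv_transpose2d(x: Node, w: Parameter, b: Parameter | None, stride: int = 2) -> Node:
    y, cache = ops.conv_transpose2d(x.value, w.value, b.value if b is not None else None, stride)
    out = Node(y, parents=(x,))

    def backward(g):
        dx, dw, db = ops.conv_transpose2d_backward(g, w.value, cache, with_bias=b is not None)
        w.grad += dw
        if b is not None:
            b.grad += db
        x._accumulate(dx)

    out._backward = backward
    return out


def relu(x: Node) -> Node:
    y = np.maximum(x.value, 0.0)
    out = Node(y, parents=(x,))

    def backward(g):
        # y > 0 identifies the pass-through entries; no separate mask is stored
        x._accumulate(np.where(y > 0, g, 0.0))

    out._backward = backward
    return out


def concat(nodes: list[Node]) -> Node:
    """Concatenate along the channel axis (NHWC: the last axis)."""
    if len(nodes) == 1:
        return nodes[0]
    values = [n.value for n in nodes]
    splits = np.cumsum([v.shape[-1] for v in values])[:-1]
    out = Node(np.concatenate(values, axis=-1), parents=tuple(nodes))

    def backward(g):
        for n, piece in zip(nodes, np.split(g, splits, axis=-1)):
            n._accumulate(piece)

    out._backward = backward
    return out
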