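"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports the small set of operations needed by the conditional WGAN-GP:
dense affine maps, leaky-ReLU / tanh nonlinearities, reductions, column
concatenation and elementwise arithmetic.  Backward rules are themselves
expressed as graph operations, so gradients are differentiable again --
the double backprop required by the gradient-penalty term (a loss on the
norm of the critic's input gradient, differentiated with respect to the
critic's weights) works without special casing.

Only float64 2-D/1-D arrays are exercised; this is not a general tensor
library and deliberately omits broadcasting beyond bias addition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "grad", "concat", "leaky_relu", "tanh",
           "sum_", "mean_", "matmul"]


class Tensor:
    """A node in the computation graph wrapping a numpy array.

    ``parents`` and ``vjps`` are parallel tuples: ``vjps[i]`` maps the
    upstream gradient (a Tensor) to the gradient w.r.t. ``parents[i]``,
    built out of Tensor operations so it can be differentiated again.
    """

    __slots__ = ("data", "requires_grad", "parents", "vjps")

    def __init__(self, data, requires_grad=False, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        # Graph edges are only kept where gradients can flow.
        if self.requires_grad and parents:
            kept = [(p, v) for p, v in zip(parents, vjps) if p.requires_grad]
            self.parents = tuple(p for p, _ in kept)
            self.vjps = tuple(v for _, v in kept)
        else:
            self.parents = ()
            self.vjps = ()

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        return Tensor(
            self.data + other.data,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g, self.shape),
                lambda g: _unbroadcast(g, other.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), vjps=(lambda g: -g,))

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)
        return Tensor(
            self.data * other.data,
            parents=(self, other),
            vjps=(
                lambda g: _unbroadcast(g * other, self.shape),
                lambda g: _unbroadcast(g * self, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / float(other))

    def __pow__(self, p):
        p = float(p)
        out = Tensor(
            self.data ** p,
            parents=(self,),
            vjps=(lambda g: g * (self ** (p - 1.0)) * p,),
        )
        return out

    # -- linear algebra ---------------------------------------------------
    def __matmul__(self, other):
        other = astensor(other)
        return Tensor(
            self.data @ other.data,
            parents=(self, other),
            vjps=(
                lambda g: g @ other.T,
                lambda g: self.T @ g,
            ),
        )

    @property
    def T(self):
        return Tensor(self.data.T, parents=(self,), vjps=(lambda g: g.T,))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        old = self.shape
        return Tensor(
            self.data.reshape(shape),
            parents=(self,),
            vjps=(lambda g: g.reshape(old),),
        )


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a gradient back to ``shape`` after numpy broadcasting."""
    if g.shape == tuple(shape):
        return g
    # Sum out prepended axes.
    while g.data.ndim > len(shape):
        g = sum_(g, axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = sum_(g, axis=ax, keepdims=True)
    if g.shape != tuple(shape):
        g = g.reshape(shape)
    return g


def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = astensor(x)
    in_shape = x.shape

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            expanded = list(g.shape)
            expanded.insert(axis if axis >= 0 else len(in_shape) + axis, 1)
            gd = g.reshape(tuple(expanded))
        return _broadcast_to(gd, in_shape)

    return Tensor(x.data.sum(axis=axis, keepdims=keepdims),
                  parents=(x,), vjps=(vjp,))


def _broadcast_to(x: Tensor, shape) -> Tensor:
    if x.shape == tuple(shape):
        return x
    return Tensor(
        np.broadcast_to(x.data, shape).copy(),
        parents=(x,),
        vjps=(lambda g: _unbroadcast(g, x.shape),),
    )


def mean_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    x = astensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return sum_(x, axis=axis, keepdims=keepdims) * (1.0 / n)


def matmul(a, b) -> Tensor:
    return astensor(a) @ astensor(b)


def tanh(x: Tensor) -> Tensor:
    x = astensor(x)
    out_data = np.tanh(x.data)
    out = Tensor(out_data, parents=(x,), vjps=())
    if out.requires_grad:
        out = Tensor(out_data, parents=(x,),
                     vjps=(lambda g: g * (1.0 - out * out),))
    return out


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    """Piecewise-linear activation; the slope mask is constant w.r.t. the
    graph, which is exact almost everywhere (second derivative is zero)."""
    x = astensor(x)
    m = np.where(x.data > 0.0, 1.0, slope)
    return x * Tensor(m)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    widths = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(widths)])

    def make_vjp(i):
        s, e = int(offsets[i]), int(offsets[i + 1])
        return lambda g: _slice_axis(g, s, e, axis)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        vjps=tuple(make_vjp(i) for i in range(len(tensors))),
    )


def _slice_axis(x: Tensor, start: int, stop: int, axis: int) -> Tensor:
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, stop)
    idx = tuple(idx)
    full = x.shape

    def vjp(g):
        return _pad_axis(g, start, full, axis)

    return Tensor(x.data[idx], parents=(x,), vjps=(vjp,))


def _pad_axis(x: Tensor, start: int, full_shape, axis: int) -> Tensor:
    width = x.shape[axis]

    def vjp(g):
        return _slice_axis(g, start, start + width, axis)

    out = np.zeros(full_shape, dtype=np.float64)
    idx = [slice(None)] * len(full_shape)
    idx[axis] = slice(start, start + width)
    out[tuple(idx)] = x.data
    return Tensor(out, parents=(x,), vjps=(vjp,))


def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, inputs, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``inputs``.

    Returned gradients are graph Tensors, so they may be differentiated
    again (used for the gradient penalty).
    """
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    grads = {id(output): grad_output}
    for node in reversed(_toposort(output)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            pg = vjp(g)
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else acc + pg
        if node in inputs or any(node is t for t in inputs):
            grads[id(node)] = g
    out = []
    for t in inputs:
        gt = grads.get(id(t))
        if gt is None:
            gt = Tensor(np.zeros_like(t.data))
        out.append(gt)
    return out
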