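"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training loss of the symbolic network is a composition of convolutions
(mirror-padded, Neumann-consistent), pointwise algebra including a guarded
division and a variable-exponent power, and reductions.  This module provides
exactly those primitives on a dynamic tape.  Gradients propagate by
vector-Jacobian products in reverse topological order; broadcasting follows
numpy semantics and is undone in the backward pass.

Only the operations needed by the package are implemented; this is not a
general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "leaf",
    "sin",
    "absolute",
    "relu",
    "power_var",
    "safe_div",
    "linear_map",
    "conv_mirror",
    "integral_channel",
    "total_sum",
    "backward",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    grad = np.asarray(grad)
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node on the tape: a value plus links to parents with local VJPs."""

    __slots__ = ("value", "parents", "grad", "requires_grad")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=float)
        self.parents = tuple(parents)  # (Tensor, vjp callable)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )

    @property
    def shape(self):
        return self.value.shape

    # -- pointwise algebra -------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value + other.value,
            [
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.value * other.value,
            [
                (self, lambda g: _unbroadcast(g * other.value, self.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        inv = 1.0 / other.value
        out = self.value * inv
        return Tensor(
            out,
            [
                (self, lambda g: _unbroadcast(g * inv, self.shape)),
                (other, lambda g: _unbroadcast(-g * out * inv, other.shape)),
            ],
        )

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("use power_var for a trainable exponent")
        val = self.value**k
        return Tensor(
            val, [(self, lambda g: g * k * self.value ** (k - 1))]
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def leaf(x) -> Tensor:
    """A trainable leaf whose gradient is collected by :func:`backward`."""
    return Tensor(x, requires_grad=True)


def sin(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor(np.sin(x.value), [(x, lambda g: g * np.cos(x.value))])


def absolute(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = np.sign(x.value)
    return Tensor(np.abs(x.value), [(x, lambda g: g * s)])


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    m = (x.value > 0).astype(float)
    return Tensor(x.value * m, [(x, lambda g: g * m)])


_POW_FLOOR = 1e-12


def power_var(base: Tensor, alpha: Tensor) -> Tensor:
    """base**alpha with a trainable scalar exponent.

    The base is clamped below at a tiny floor so that the exponent gradient
    ``out * log(base)`` stays finite; negative bases (which the data
    generator already clamps) contribute zero.
    """
    base, alpha = _as_tensor(base), _as_tensor(alpha)
    bc = np.maximum(base.value, _POW_FLOOR)
    out = bc**alpha.value
    active = (base.value > _POW_FLOOR).astype(float)
    logb = np.log(bc)

    def g_base(g):
        return _unbroadcast(
            g * alpha.value * bc ** (alpha.value - 1.0) * active, base.shape
        )

    def g_alpha(g):
        return _unbroadcast(g * out * logb * active, alpha.shape)

    return Tensor(out * (base.value > 0), [(base, g_base), (alpha, g_alpha)])


def safe_div(num: Tensor, den: Tensor, eps: float = 1e-6) -> Tensor:
    """Guarded division num / (sign(den) * max(|den|, eps)).

    Exact wherever |den| >= eps; inside the guard band the magnitude is
    clamped so values and gradients stay bounded (the clamp is treated as
    locally constant there).
    """
    num, den = _as_tensor(num), _as_tensor(den)
    s = np.sign(den.value)
    s = np.where(s == 0.0, 1.0, s)
    d = s * np.maximum(np.abs(den.value), eps)
    inv = 1.0 / d
    out = num.value * inv
    return Tensor(
        out,
        [
            (num, lambda g: _unbroadcast(g * inv, num.shape)),
            (den, lambda g: _unbroadcast(-g * out * inv, den.shape)),
        ],
    )


def linear_map(x: Tensor, A: np.ndarray, b: np.ndarray | float = 0.0) -> Tensor:
    """Affine map A @ x + b for a 1-D tensor x and constant A, b."""
    x = _as_tensor(x)
    A = np.asarray(A, dtype=float)
    out = A @ x.value + b
    return Tensor(out, [(x, lambda g: A.T @ np.asarray(g))])


def _pad_index_map(shape, pad):
    """Index map implementing symmetric (mirror) padding of the trailing axes."""
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    return np.pad(idx, pad, mode="symmetric")


def conv_mirror(field: Tensor, kernel: Tensor) -> Tensor:
    """'Same'-size correlation of `field` with `kernel` under mirror padding.

    The trailing ``kernel.ndim`` axes of `field` are spatial; leading axes are
    batch.  Mirror (even/symmetric) padding matches a zero-flux Neumann
    boundary, consistent with the data-generating scheme.  Differentiable in
    both the field and the kernel.
    """
    field, kernel = _as_tensor(field), _as_tensor(kernel)
    kshape = kernel.shape
    kdim = len(kshape)
    sshape = field.shape[-kdim:]
    bshape = field.shape[:-kdim]
    pad_b = [(0, 0)] * len(bshape)
    pad_s = [((k - 1) // 2, (k - 1) // 2) for k in kshape]
    padded = np.pad(field.value, pad_b + pad_s, mode="symmetric")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, kshape, axis=tuple(range(len(bshape), field.value.ndim))
    )
    out = np.tensordot(windows, kernel.value, axes=kdim)

    def g_field(g):
        # scatter the padded gradient back through the mirror map
        gpad = np.zeros(padded.shape, dtype=float)
        k = kernel.value
        if kdim == 1:
            (nx,) = sshape
            for a in range(kshape[0]):
                gpad[..., a : a + nx] += g * k[a]
        else:
            ny, nx = sshape
            for a in range(kshape[0]):
                for b in range(kshape[1]):
                    gpad[..., a : a + ny, b : b + nx] += g * k[a, b]
        idx = _pad_index_map(sshape, pad_s).ravel()
        nsp = int(np.prod(sshape))
        flat = gpad.reshape(-1, idx.size)
        acc = np.zeros((flat.shape[0], nsp))
        for i in range(flat.shape[0]):
            acc[i] = np.bincount(idx, weights=flat[i], minlength=nsp)
        return acc.reshape(field.shape)

    def g_kernel(g):
        w = windows.reshape(-1, *kshape)
        return np.tensordot(np.asarray(g).ravel(), w.reshape(w.shape[0], -1), axes=(0, 0)).reshape(kshape)

    return Tensor(out, [(field, g_field), (kernel, g_kernel)])


def integral_channel(field: Tensor, weights: np.ndarray) -> Tensor:
    """Quadrature integral over the last (1-D spatial) axis.

    Returns shape ``batch + (1,)`` so the integral broadcasts back over the
    grid as a spatially constant channel.
    """
    field = _as_tensor(field)
    w = np.asarray(weights, dtype=float)
    out = (field.value * w).sum(axis=-1, keepdims=True)

    def g(gout):
        return np.asarray(gout) * w

    return Tensor(out, [(field, g)])


def total_sum(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    return Tensor(
        x.value.sum(), [(x, lambda g: np.broadcast_to(g, x.shape).copy())]
    )


def backward(out: Tensor) -> None:
    """Accumulate d(out)/d(leaf) into ``leaf.grad`` for every trainable leaf."""
    if out.value.shape != ():
        raise ValueError("backward expects a scalar output")
    order: list[Tensor] = []
    seen = set()
    stack = [(out, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    grads = {id(out): np.asarray(1.0)}
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if not node.parents:
            node.grad = g if node.grad is None else node.grad + g
            continue
        for p, vjp in node.parents:
            if not p.requires_grad:
                continue
            contrib = vjp(g)
            if id(p) in grads:
                grads[id(p)] = grads[id(p)] + contrib
            else:
                grads[id(p)] = np.array(contrib, dtype=float, copy=True)
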