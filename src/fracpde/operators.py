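"""Convolutional differential operators with constrained moment matrices.

A kernel q of odd size acts by correlation, q (*) u (x) = sum_k q[k] u(x + k dx).
Its moment matrix m_ij = (1/i!j!) sum_k k1^i k2^j q[k1, k2] is an invertible
linear image of the kernel, so kernels are trained through their moments.
To make the kernel for derivative order (i, j) an at-least-second-order
approximation of d^{i+j}/dx^i dy^j, all moments of total order <= i + j + 1
are frozen (1 at (i, j), 0 elsewhere); higher moments are trainable.

With free moments at zero the kernels reduce to exact finite-difference
stencils, which is also the training initialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np

from . import autodiff as ad
from .grids import FieldSnapshot, SpatialGrid

__all__ = [
    "Filter",
    "MomentMatrix",
    "FilterBank",
    "moments_from_filter",
    "filter_from_moments",
    "apply_derivative",
    "integral_operator",
    "constraint_mask",
]


@lru_cache(maxsize=None)
def _moment_basis(n: int) -> np.ndarray:
    """A[i, k] = offset^i / i! with offsets -(n-1)/2 .. (n-1)/2."""
    h = (n - 1) // 2
    k = np.arange(-h, h + 1, dtype=float)
    return np.vstack([k**i / factorial(i) for i in range(n)])


@lru_cache(maxsize=None)
def _moment_basis_inv(n: int) -> np.ndarray:
    return np.linalg.inv(_moment_basis(n))


@dataclass
class Filter:
    """Correlation kernel on a uniform grid; 1-D shape (n,), 2-D (n, n)."""

    kernel: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float)
        if any(s % 2 == 0 for s in self.kernel.shape):
            raise ValueError("kernel side lengths must be odd")


@dataclass
class MomentMatrix:
    """Moment representation of a kernel plus its constraint pattern.

    ``fixed_mask`` flags entries frozen during training; their values live in
    ``values`` too (a 1 at the target derivative order, 0 elsewhere).
    """

    values: np.ndarray
    fixed_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(self.values.shape, dtype=bool)

    @property
    def n_free(self) -> int:
        return int((~self.fixed_mask).sum())


def moments_from_filter(f: Filter) -> MomentMatrix:
    q = f.kernel
    if q.ndim == 1:
        return MomentMatrix(_moment_basis(q.shape[0]) @ q)
    A = _moment_basis(q.shape[0])
    B = _moment_basis(q.shape[1])
    return MomentMatrix(A @ q @ B.T)


def filter_from_moments(m: MomentMatrix, spacing: float = 1.0) -> Filter:
    M = m.values
    if M.ndim == 1:
        return Filter(_moment_basis_inv(M.shape[0]) @ M, spacing)
    Ai = _moment_basis_inv(M.shape[0])
    Bi = _moment_basis_inv(M.shape[1])
    return Filter(Ai @ M @ Bi.T, spacing)


def constraint_mask(order: tuple, n: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """(fixed_mask, fixed_values) freezing all moments of total order
    <= sum(order) + 1 — a delta at `order`, zero elsewhere."""
    total = sum(order) + 1
    if dim == 1:
        i = np.arange(n)
        mask = i <= total
        vals = (i == order[0]).astype(float)
    else:
        i = np.arange(n)[:, None]
        j = np.arange(n)[None, :]
        mask = (i + j) <= total
        vals = ((i == order[0]) & (j == order[1])).astype(float)
    return mask, vals * mask


class FilterBank:
    """One constrained moment matrix per derivative order in the library.

    Orders are tuples: ``(i,)`` in 1-D, ``(i, j)`` in 2-D.  Orders listed in
    ``frozen_orders`` carry no trainable moments at all (exact stencils);
    the rest have their sub-threshold moments fixed and higher moments free.
    """

    def __init__(
        self,
        dim: int,
        size: int,
        spacing: float,
        orders: list[tuple],
        frozen_orders: tuple = (),
    ):
        self.dim = dim
        self.size = size
        self.spacing = spacing
        self.orders = list(orders)
        self.frozen_orders = tuple(frozen_orders)
        self.moments: dict[tuple, MomentMatrix] = {}
        self._free_basis: dict[tuple, np.ndarray] = {}
        self._base_kernel: dict[tuple, np.ndarray] = {}
        shape = (size,) if dim == 1 else (size, size)
        for order in self.orders:
            mask, vals = constraint_mask(order, size, dim)
            if order in self.frozen_orders:
                mask = np.ones(shape, dtype=bool)
            mm = MomentMatrix(vals.copy(), mask)
            self.moments[order] = mm
            # kernel is affine in the free moments: k = k0 + B @ theta
            self._base_kernel[order] = filter_from_moments(mm).kernel
            free_idx = np.flatnonzero(~mask.ravel())
            B = []
            for fi in free_idx:
                e = np.zeros(mask.size)
                e[fi] = 1.0
                B.append(
                    filter_from_moments(
                        MomentMatrix(e.reshape(shape))
                    ).kernel.ravel()
                )
            self._free_basis[order] = (
                np.array(B).T if B else np.zeros((mask.size, 0))
            )

    # -- trainable parameter plumbing --------------------------------------
    @property
    def n_trainable(self) -> int:
        return sum(self.moments[o].n_free for o in self.orders)

    def free_values(self) -> np.ndarray:
        out = []
        for o in self.orders:
            mm = self.moments[o]
            out.append(mm.values[~mm.fixed_mask])
        return np.concatenate(out) if out else np.zeros(0)

    def set_free_values(self, theta: np.ndarray) -> None:
        pos = 0
        for o in self.orders:
            mm = self.moments[o]
            n = mm.n_free
            mm.values[~mm.fixed_mask] = theta[pos : pos + n]
            pos += n
        if pos != len(theta):
            raise ValueError("parameter vector length mismatch")

    def split_theta(self, theta) -> dict:
        out, pos = {}, 0
        for o in self.orders:
            n = self.moments[o].n_free
            out[o] = theta[pos : pos + n]
            pos += n
        return out

    def kernel(self, order: tuple) -> np.ndarray:
        mm = self.moments[order]
        shape = mm.values.shape
        free = mm.values[~mm.fixed_mask]
        k = self._base_kernel[order].ravel() + self._free_basis[order] @ free
        return k.reshape(shape)

    def kernel_tensor(self, order: tuple, theta_free: "ad.Tensor") -> "ad.Tensor":
        """Differentiable kernel from a free-moment leaf tensor."""
        shape = self.moments[order].values.shape
        flat = ad.linear_map(
            theta_free, self._free_basis[order], self._base_kernel[order].ravel()
        )
        # reshape via a zero-cost view op
        return _reshape(flat, shape)

    def scale(self, order: tuple) -> float:
        return 1.0 / self.spacing ** sum(order)

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "size": self.size,
            "spacing": self.spacing,
            "orders": [list(o) for o in self.orders],
            "frozen_orders": [list(o) for o in self.frozen_orders],
            "free_values": self.free_values().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBank":
        bank = cls(
            d["dim"],
            d["size"],
            d["spacing"],
            [tuple(o) for o in d["orders"]],
            tuple(tuple(o) for o in d["frozen_orders"]),
        )
        bank.set_free_values(np.asarray(d["free_values"]))
        return bank


def _reshape(x: "ad.Tensor", shape) -> "ad.Tensor":
    val = x.value.reshape(shape)
    return ad.Tensor(
        val, [(x, lambda g: np.asarray(g).reshape(x.value.shape))]
    )


def apply_derivative(
    bank: FilterBank, order: tuple, field: FieldSnapshot | np.ndarray
) -> np.ndarray:
    """Apply the (constrained) derivative kernel to a field (numpy path).

    Mirror-reflection padding keeps the operator consistent with the
    zero-flux boundary of the data-generating scheme.
    """
    values = field.values if isinstance(field, FieldSnapshot) else np.asarray(field)
    if isinstance(field, FieldSnapshot) and not np.isclose(
        field.grid.spacing, bank.spacing
    ):
        raise ValueError("field grid spacing does not match filter bank")
    k = bank.kernel(order)
    if values.shape[-1] < (k.shape[0] + 1) // 2:
        raise ValueError("kernel larger than padded field")
    out = ad.conv_mirror(ad.constant(values), ad.constant(k)).value
    return out * bank.scale(order)


def integral_operator(field: FieldSnapshot) -> np.ndarray:
    """Spatial integral over the 1-D domain, broadcast as a constant field."""
    if field.grid.dim != 1:
        raise ValueError("integral channel is defined on 1-D grids only")
    val = float(np.sum(field.grid.quad_weights * field.values))
    return np.full_like(field.values, val)


def example1_bank(spacing: float, size: int = 5) -> FilterBank:
    """Shared 2-D bank: smoothing D00 plus second derivatives D20, D02."""
    return FilterBank(2, size, spacing, [(0, 0), (2, 0), (0, 2)])


def example2_bank(spacing: float, size: int = 19) -> FilterBank:
    """1-D bank: D0 and D2 trainable, first derivative kept exact."""
    return FilterBank(1, size, spacing, [(0,), (1,), (2,)], frozen_orders=((1,),))
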