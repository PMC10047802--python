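"""Synthetic data for the two benchmark reaction-diffusion systems.

Two ground-truth systems are provided:

* a 2-D two-species model on [-5, 5]^2 with a shared rational interaction
  -0.5 u v / (u^2 + 0.25 u + 0.25) (activator depletion with saturation),
  integrated by second-order Runge-Kutta;
* a 1-D pollen-tube-type model on [-2.5*pi, 2.5*pi] coupling a fractional
  power u^1.5, a nonlocal term u^1.5 * \int u dx, and a rational calcium
  feedback 0.081 u / (v^2 + 0.0215), integrated by implicit Euler on a fine
  600-point grid and restricted to 200 points.

Both use zero-flux (Neumann) boundaries imposed by mirror reflection.
Observation noise is proportional Gaussian: nl * N(0, sigma^2) with sigma the
empirical standard deviation of the true trajectory of that field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .grids import FieldSnapshot, SpatialGrid, TrajectoryDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrueSystemSpec",
    "InitialConditionSpec",
    "example1_system",
    "example2_system",
    "example1_grid",
    "example2_grid",
    "random_initial_condition",
    "eq18_field",
    "simulate_true_2d",
    "simulate_true_1d",
    "add_noise",
    "subsample_and_split",
    "laplacian",
    "make_example_dataset",
    "EX2_U_EQ",
    "EX2_V_EQ",
]

# approximate uniform equilibrium of the 1-D system; also the base level of
# the printed prediction initial state u0 = 0.0259 + 0.01 sin(3x)
EX2_U_EQ = 0.0259
EX2_V_EQ = 0.06475


@dataclass
class TrueSystemSpec:
    """Ground-truth right-hand side F_i = d_i * Lap + P_i + R_i."""

    d1: float
    d2: float
    P1: Callable  # P1(u, v, I) with I the spatial integral of u (or None)
    P2: Callable
    R1: Callable  # R1(u, v)
    R2: Callable
    dim: int
    uses_integral: bool = False
    alpha_true: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("diffusion coefficients must be nonnegative")

    def reaction(self, u, v, integral=None):
        return (
            self.P1(u, v, integral) + self.R1(u, v),
            self.P2(u, v, integral) + self.R2(u, v),
        )


def _rational_ex1(u, v):
    return -0.5 * u * v / (u * u + 0.25 * u + 0.25)


def example1_system() -> TrueSystemSpec:
    return TrueSystemSpec(
        d1=0.3,
        d2=0.4,
        P1=lambda u, v, I: 1.0 - u,
        P2=lambda u, v, I: 0.4 - 0.2 * v,
        R1=_rational_ex1,
        R2=_rational_ex1,
        dim=2,
        name="example1",
    )


def _pos_pow(u, p):
    """u**p for fractional p with negative bases clamped to zero."""
    neg = np.sum(np.asarray(u) < 0)
    if neg:
        logger.debug("clamped %d negative entries before power %.3f", neg, p)
    return np.maximum(u, 0.0) ** p


def example2_system() -> TrueSystemSpec:
    def P1(u, v, I):
        u15 = _pos_pow(u, 1.5)
        return 3.6 * u15 - 3.6 * u - 0.229 * u15 * I

    return TrueSystemSpec(
        d1=0.1,
        d2=10.0,
        P1=P1,
        P2=lambda u, v, I: u - 0.4 * v,
        R1=lambda u, v: 0.081 * u / (v * v + 0.0215),
        R2=lambda u, v: np.zeros_like(np.asarray(u, dtype=float)),
        dim=1,
        uses_integral=True,
        alpha_true=1.5,
        name="example2",
    )


def example1_grid(n: int = 64) -> SpatialGrid:
    return SpatialGrid(dim=2, extent=(-5.0, 5.0), n_points=n)


def example2_grid(n: int = 200) -> SpatialGrid:
    return SpatialGrid(dim=1, extent=(-2.5 * np.pi, 2.5 * np.pi), n_points=n)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------


@dataclass
class InitialConditionSpec:
    """Random multi-mode Fourier initial state.

    ``w0`` is a truncated double sum of products of low-frequency sines and
    cosines with independent standard-normal coefficients; the field is
    normalized by its maximum absolute value and shifted by a uniform offset,
    so ``|u0 - c1| <= 1`` everywhere.
    """

    truncation: int = 3
    c1_range: tuple = (-0.5, 0.5)
    c2_range: tuple = (0.5, 1.5)


def eq18_field(grid: SpatialGrid, a, b, c=None, d=None) -> np.ndarray:
    """Evaluate the truncated random Fourier sum from explicit coefficients.

    In 2-D the four coefficient arrays (indexed by mode offsets, shape
    ``(2B+1, 2B+1)``) weight cos(2ix)cos(2jy), sin((2i+1)x)sin((2j+1)y),
    sin((2i+1)x)cos(2jy) and cos(2ix)sin((2j+1)y).  In 1-D only ``a``
    (cosines cos(2ix)) and ``b`` (sines sin((2i+1)x)) are used.
    """
    a = np.asarray(a, dtype=float)
    B = (a.shape[0] - 1) // 2
    modes = np.arange(-B, B + 1)
    if grid.dim == 1:
        (x,) = grid.meshgrid()
        cos = np.cos(2.0 * modes[:, None] * x[None, :])
        sin = np.sin((2.0 * modes + 1.0)[:, None] * x[None, :])
        return np.einsum("i,ix->x", a, cos) + np.einsum(
            "i,ix->x", np.asarray(b, dtype=float), sin
        )
    x, y = grid.meshgrid()
    cx = np.cos(2.0 * modes[:, None, None] * x[None])
    sx = np.sin((2.0 * modes + 1.0)[:, None, None] * x[None])
    cy = np.cos(2.0 * modes[:, None, None] * y[None])
    sy = np.sin((2.0 * modes + 1.0)[:, None, None] * y[None])
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    out = np.einsum("ij,ixy,jxy->xy", a, cx, cy)
    out += np.einsum("ij,ixy,jxy->xy", b, sx, sy)
    out += np.einsum("ij,ixy,jxy->xy", c, sx, cy)
    out += np.einsum("ij,ixy,jxy->xy", d, cx, sy)
    return out


def _random_w0(grid: SpatialGrid, B: int, rng: np.random.Generator) -> np.ndarray:
    n = 2 * B + 1
    if grid.dim == 1:
        return eq18_field(grid, rng.standard_normal(n), rng.standard_normal(n))
    coef = [rng.standard_normal((n, n)) for _ in range(4)]
    return eq18_field(grid, *coef)


def random_initial_condition(
    grid: SpatialGrid, spec: InitialConditionSpec, seed: int
) -> tuple[FieldSnapshot, FieldSnapshot]:
    """Draw a random (u0, v0) pair; deterministic in ``seed``."""
    for attempt in range(10):
        rng = np.random.default_rng(seed + attempt)
        w0 = _random_w0(grid, spec.truncation, rng)
        wt0 = _random_w0(grid, spec.truncation, rng)
        m0, mt0 = np.max(np.abs(w0)), np.max(np.abs(wt0))
        if m0 > 0 and mt0 > 0:  # zero max is a probability-zero degeneracy
            break
    c1 = rng.uniform(*spec.c1_range)
    c2 = rng.uniform(*spec.c2_range)
    u0 = w0 / m0 + c1
    v0 = wt0 / mt0 + c2
    return (
        FieldSnapshot(u0, 0.0, grid),
        FieldSnapshot(v0, 0.0, grid),
    )


# ---------------------------------------------------------------------------
# finite-difference simulators
# ---------------------------------------------------------------------------


def _lap1d(values: np.ndarray, dx: float) -> np.ndarray:
    p = np.pad(values, [(0, 0)] * (values.ndim - 1) + [(1, 1)], mode="symmetric")
    return (p[..., :-2] - 2.0 * values + p[..., 2:]) / dx**2


def _lap2d(values: np.ndarray, dx: float) -> np.ndarray:
    pad = [(0, 0)] * (values.ndim - 2) + [(1, 1), (1, 1)]
    p = np.pad(values, pad, mode="symmetric")
    return (
        p[..., :-2, 1:-1]
        + p[..., 2:, 1:-1]
        + p[..., 1:-1, :-2]
        + p[..., 1:-1, 2:]
        - 4.0 * values
    ) / dx**2


def laplacian(values: np.ndarray, grid: SpatialGrid) -> np.ndarray:
    return (_lap1d if grid.dim == 1 else _lap2d)(values, grid.spacing)


class BlowUpError(RuntimeError):
    """Raised when the integrator produces non-finite fields."""


def _check_finite(u, v, step, scheme):
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise BlowUpError(f"{scheme} blow-up: non-finite field at step {step}")


def simulate_true_2d(
    sys: TrueSystemSpec,
    u0: FieldSnapshot,
    v0: FieldSnapshot,
    dt_fine: float,
    T: float,
):
    """Second-order (midpoint) Runge-Kutta integration of the 2-D system.

    Returns ``(u, v)`` arrays of shape ``(n_steps + 1, n, n)`` holding every
    fine-step snapshot including the initial one.
    """
    grid = u0.grid
    n_steps = int(round(T / dt_fine))
    if abs(n_steps * dt_fine - T) > 1e-9 * max(T, 1.0):
        raise ValueError("dt_fine must divide T")

    def rhs(u, v):
        r1, r2 = sys.reaction(u, v, None)
        return (
            sys.d1 * laplacian(u, grid) + r1,
            sys.d2 * laplacian(v, grid) + r2,
        )

    u = np.empty((n_steps + 1,) + grid.shape)
    v = np.empty_like(u)
    u[0], v[0] = u0.values, v0.values
    for k in range(n_steps):
        f1, f2 = rhs(u[k], v[k])
        uh = u[k] + 0.5 * dt_fine * f1
        vh = v[k] + 0.5 * dt_fine * f2
        g1, g2 = rhs(uh, vh)
        u[k + 1] = u[k] + dt_fine * g1
        v[k + 1] = v[k] + dt_fine * g2
        _check_finite(u[k + 1], v[k + 1], k + 1, "RK2")
    return u, v


def _neumann_tridiag(n: int, coef: float) -> sp.csc_matrix:
    """I - coef * Lap (tridiagonal, mirror boundary) for implicit Euler."""
    main = np.full(n, 1.0 + 2.0 * coef)
    main[0] = main[-1] = 1.0 + coef  # mirrored ghost cancels one neighbor
    off = np.full(n - 1, -coef)
    return sp.diags([off, main, off], [-1, 0, 1], format="csc")


def simulate_true_1d(
    sys: TrueSystemSpec,
    u0: FieldSnapshot,
    v0: FieldSnapshot,
    dt_fine: float,
    T: float,
    restrict_to: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 50,
):
    """Implicit-Euler integration of the 1-D system.

    The linear diffusion part is solved exactly each iteration (prefactored
    tridiagonal solve) while the nonlinear reaction is handled by fixed-point
    iteration until the residual of the full implicit system drops below
    ``tol`` in sup-norm.  The nonlocal term \int u dx uses the composite
    quadrature of the simulation grid each step.  If ``restrict_to`` is
    given, the returned snapshots are restricted to that coarser
    cell-centered grid (every third point for 600 -> 200).
    """
    grid = u0.grid
    n = grid.n_points
    n_steps = int(round(T / dt_fine))
    if abs(n_steps * dt_fine - T) > 1e-9 * max(T, 1.0):
        raise ValueError("dt_fine must divide T")
    dx = grid.spacing
    w = grid.quad_weights
    A1 = splu(_neumann_tridiag(n, dt_fine * sys.d1 / dx**2))
    A2 = splu(_neumann_tridiag(n, dt_fine * sys.d2 / dx**2))

    u = np.empty((n_steps + 1, n))
    v = np.empty_like(u)
    u[0], v[0] = u0.values, v0.values
    for k in range(n_steps):
        un, vn = u[k], v[k]
        x, y = un.copy(), vn.copy()
        for it in range(max_iter):
            integral = float(np.sum(w * x)) if sys.uses_integral else None
            r1, r2 = sys.reaction(x, y, integral)
            x_new = A1.solve(un + dt_fine * r1)
            y_new = A2.solve(vn + dt_fine * r2)
            res = max(
                np.max(np.abs(x_new - x)), np.max(np.abs(y_new - y))
            )
            x, y = x_new, y_new
            if res < tol:
                break
        else:
            raise BlowUpError(
                f"implicit Euler failed to converge at step {k + 1} "
                f"(residual {res:.3e})"
            )
        u[k + 1], v[k + 1] = x, y
        _check_finite(x, y, k + 1, "implicit Euler")
    if restrict_to is not None:
        if n % restrict_to:
            raise ValueError("fine grid size must be a multiple of the target")
        stride = n // restrict_to
        off = (stride - 1) // 2  # nested cell centers (600 -> 200: every 3rd)
        u = u[:, off::stride]
        v = v[:, off::stride]
    return u, v


# ---------------------------------------------------------------------------
# observation model and splitting
# ---------------------------------------------------------------------------


def add_noise(
    traj: TrajectoryDataset, nl: float, take_abs: bool = False, seed: int = 0
) -> TrajectoryDataset:
    """Proportional Gaussian observation noise, per-field per-trajectory sigma."""
    if nl < 0:
        raise ValueError("noise level must be nonnegative")
    if nl == 0 and not take_abs:
        return traj
    rng = np.random.default_rng(seed)
    u = traj.u.copy()
    v = traj.v.copy()
    for k in range(traj.n_init):
        su = np.std(traj.u[k])
        sv = np.std(traj.v[k])
        u[k] += nl * su * rng.standard_normal(traj.u[k].shape)
        v[k] += nl * sv * rng.standard_normal(traj.v[k].shape)
    if take_abs:
        u = np.abs(u)
        v = np.abs(v)
    return TrajectoryDataset(
        u, v, traj.grid, traj.dt_obs, nl, seed, dict(traj.meta)
    )


def subsample_and_split(
    fine_u: np.ndarray,
    fine_v: np.ndarray,
    grid: SpatialGrid,
    dt_fine: float,
    dt_obs: float,
    n_time: int,
    sizes: tuple[int, int, int],
):
    """Keep snapshots at multiples of dt_obs and split trajectories.

    ``fine_u/fine_v`` have shape ``(n_init, n_fine_steps + 1, *grid.shape)``.
    The first M1 trajectories form the training set, the next M2 validation,
    the last M3 test.
    """
    stride_f = dt_obs / dt_fine
    stride = int(round(stride_f))
    if abs(stride - stride_f) > 1e-9:
        raise ValueError("dt_obs must be an integer multiple of dt_fine")
    m1, m2, m3 = sizes
    if m1 + m2 + m3 != fine_u.shape[0]:
        raise ValueError("split sizes must sum to the number of trajectories")
    u = fine_u[:, : stride * n_time + 1 : stride]
    v = fine_v[:, : stride * n_time + 1 : stride]
    if u.shape[1] != n_time + 1:
        raise ValueError("trajectory too short for the requested blocks")

    def make(a, b, lo, hi):
        return TrajectoryDataset(a[lo:hi], b[lo:hi], grid, dt_obs)

    return (
        make(u, v, 0, m1),
        make(u, v, m1, m1 + m2),
        make(u, v, m1 + m2, m1 + m2 + m3),
    )


# ---------------------------------------------------------------------------
# benchmark dataset assembly
# ---------------------------------------------------------------------------


def _example2_initial_states(
    grid_fine: SpatialGrid, n_init: int, seed: int, burn_in_T: float = 5.0
):
    """Initial states for the 1-D system: periodic-pattern states from a
    burn-in simulation, plus sinusoid-sum states with positive offsets.

    Roughly 10 of 14 states come from burn-in (matching the benchmark mix);
    amplitudes are relative to the system's uniform equilibrium so that all
    fields stay positive.
    """
    sys = example2_system()
    n_burn = int(round(n_init * 10 / 14))
    # interleave so that every prefix (train split) keeps both state types:
    # pattern states carry the reaction structure, transient sinusoid states
    # carry the fast v-relaxation that identifies the large diffusivity
    kinds = []
    nb = ns = 0
    for k in range(n_init):
        if ns * n_burn <= nb * (n_init - n_burn) and ns < n_init - n_burn:
            kinds.append("sin")
            ns += 1
        else:
            kinds.append("burn")
            nb += 1
    states = []
    spec = InitialConditionSpec(truncation=3)
    (x,) = grid_fine.meshgrid()
    for k in range(n_init):
        rng = np.random.default_rng(seed * 1000 + k)
        if kinds[k] == "burn":
            w0 = _random_w0(grid_fine, spec.truncation, rng)
            wt0 = _random_w0(grid_fine, spec.truncation, rng)
            u0 = EX2_U_EQ * (1.0 + 0.4 * w0 / np.max(np.abs(w0)))
            v0 = EX2_V_EQ * (1.0 + 0.4 * wt0 / np.max(np.abs(wt0)))
            uu, vv = simulate_true_1d(
                sys,
                FieldSnapshot(u0, 0.0, grid_fine),
                FieldSnapshot(v0, 0.0, grid_fine),
                dt_fine=0.01,
                T=burn_in_T,
            )
            states.append((uu[-1], vv[-1]))
        else:
            # long-wavelength Neumann cosine modes: gentle transients whose
            # relaxation stays resolvable by one observation block
            L = -grid_fine.extent[0]
            m1, m2 = rng.integers(1, 3, size=2)
            amp_u = rng.uniform(0.2, 0.6)
            amp_v = rng.uniform(0.3, 0.5)
            # mass factors diversify the total amount of each species, which
            # separates the nonlocal term u^alpha * int(u) from u^alpha
            mass_u = rng.uniform(0.4, 1.9)
            mass_v = rng.uniform(0.7, 1.4)
            u0 = mass_u * EX2_U_EQ * (
                1.0 + amp_u * np.cos(m1 * np.pi * (x + L) / (2 * L))
            )
            v0 = mass_v * EX2_V_EQ * (
                1.0 + amp_v * np.cos(m2 * np.pi * (x + L) / (2 * L))
            )
            states.append((u0, v0))
    return states


def make_example_dataset(
    example: int,
    noise_level: float,
    seed: int,
    n_init: int | None = None,
    n_space: int | None = None,
    n_time: int = 15,
    sizes: tuple[int, int, int] | None = None,
):
    """Generate truth, add observation noise, subsample and split.

    Returns a dict with the observed ``train``/``valid``/``test`` splits, the
    noiseless subsampled ``truth`` (all trajectories) and the settings used.
    Defaults reproduce the benchmark conditions: example 1 on a 64x64 grid,
    12 trajectories, dt_obs 0.01, horizon 0.15, RK2 fine step 1/1600;
    example 2 on 200 points (simulated at 3x resolution), 14 trajectories,
    dt_obs 0.05, horizon 0.75, implicit-Euler step 0.01.
    """
    if example == 1:
        n_init = 12 if n_init is None else n_init
        n_space = 64 if n_space is None else n_space
        sizes = sizes or (n_init - 2, 1, 1)
        grid = example1_grid(n_space)
        sys = example1_system()
        dt_fine, dt_obs = 1.0 / 1600.0, 0.01
        spec = InitialConditionSpec()
        fu, fv = [], []
        for k in range(n_init):
            u0, v0 = random_initial_condition(grid, spec, seed * 1000 + k)
            uu, vv = simulate_true_2d(sys, u0, v0, dt_fine, dt_obs * n_time)
            fu.append(uu)
            fv.append(vv)
        take_abs = False
    elif example == 2:
        n_init = 14 if n_init is None else n_init
        n_space = 200 if n_space is None else n_space
        sizes = sizes or (n_init - 2, 1, 1)
        grid = example2_grid(n_space)
        grid_fine = example2_grid(3 * n_space)
        sys = example2_system()
        dt_fine, dt_obs = 0.01, 0.05
        fu, fv = [], []
        for u0, v0 in _example2_initial_states(grid_fine, n_init, seed):
            uu, vv = simulate_true_1d(
                sys,
                FieldSnapshot(u0, 0.0, grid_fine),
                FieldSnapshot(v0, 0.0, grid_fine),
                dt_fine,
                dt_obs * n_time,
                restrict_to=n_space,
            )
            fu.append(uu)
            fv.append(vv)
        take_abs = True
    else:
        raise ValueError("example must be 1 or 2")

    fu = np.stack(fu)
    fv = np.stack(fv)
    train, valid, test = subsample_and_split(
        fu, fv, grid, dt_fine, dt_obs, n_time, sizes
    )
    truth = TrajectoryDataset(
        np.concatenate([train.u, valid.u, test.u]),
        np.concatenate([train.v, valid.v, test.v]),
        grid,
        dt_obs,
    )
    train = add_noise(train, noise_level, take_abs, seed=seed * 7 + 1)
    valid = add_noise(valid, noise_level, take_abs, seed=seed * 7 + 2)
    test = add_noise(test, noise_level, take_abs, seed=seed * 7 + 3)
    return {
        "train": train,
        "valid": valid,
        "test": test,
        "truth": truth,
        "grid": grid,
        "system": sys,
        "dt_fine": dt_fine,
        "dt_obs": dt_obs,
        "sizes": sizes,
        "noise_level": noise_level,
        "seed": seed,
    }
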