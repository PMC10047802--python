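"""Uniform spatial grids and gridded trajectory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpatialGrid", "FieldSnapshot", "TrajectoryDataset"]


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform, cell-centered grid on a closed interval or square.

    ``spacing = (right - left) / n_points`` per axis, with sample points at
    cell centers.  This matches the benchmark settings dx = 10/64 on [-5, 5]
    and dx = 5*pi/200 on [-2.5*pi, 2.5*pi].
    """

    dim: int
    extent: tuple  # (left, right), shared by both axes in 2-D
    n_points: int  # per axis

    def __post_init__(self):
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 or 2")
        if self.n_points < 3:
            raise ValueError("need at least 3 grid points per axis")

    @property
    def spacing(self) -> float:
        left, right = self.extent
        return (right - left) / self.n_points

    @property
    def coords(self) -> np.ndarray:
        left, _ = self.extent
        dx = self.spacing
        return left + dx * (np.arange(self.n_points) + 0.5)

    @property
    def shape(self) -> tuple:
        return (self.n_points,) * self.dim

    def meshgrid(self):
        if self.dim == 1:
            return (self.coords,)
        return np.meshgrid(self.coords, self.coords, indexing="ij")

    @property
    def quad_weights(self) -> np.ndarray:
        """Composite quadrature weights over the closed interval.

        On a cell-centered grid the Neumann (zero-slope) edge extension makes
        every weight equal to the spacing, i.e. the midpoint rule; for a
        constant field the integral is exactly (right-left)*c.
        """
        return np.full(self.n_points, self.spacing)

    @property
    def cell_measure(self) -> float:
        """dx (1-D) or dx*dy (2-D) — the weight of the discrete L2 norm."""
        return self.spacing**self.dim


@dataclass
class FieldSnapshot:
    """One scalar field on a grid at one time."""

    values: np.ndarray
    time: float
    grid: SpatialGrid

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite entries")


def discrete_l2_sq(values: np.ndarray, grid: SpatialGrid) -> float:
    """Squared discrete L2 norm: cell measure times the sum of squares."""
    return float(grid.cell_measure * np.sum(np.square(values)))


@dataclass
class TrajectoryDataset:
    """Observed (u, v) snapshots for several initial conditions.

    ``u`` and ``v`` have shape ``(n_init, n_time + 1, *grid.shape)`` where
    index 0 along the time axis is the initial snapshot, and time block k
    sits at ``k * dt_obs``.
    """

    u: np.ndarray
    v: np.ndarray
    grid: SpatialGrid
    dt_obs: float
    noise_level: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must share shape")
        if self.u.shape[2:] != self.grid.shape:
            raise ValueError("trajectory spatial shape does not match grid")

    @property
    def n_init(self) -> int:
        return self.u.shape[0]

    @property
    def n_time(self) -> int:
        return self.u.shape[1] - 1

    @property
    def times(self) -> np.ndarray:
        return self.dt_obs * np.arange(self.u.shape[1])

    def subset(self, idx) -> "TrajectoryDataset":
        return TrajectoryDataset(
            self.u[idx],
            self.v[idx],
            self.grid,
            self.dt_obs,
            self.noise_level,
            self.seed,
            dict(self.meta),
        )

    def truncate_blocks(self, n_blocks: int) -> "TrajectoryDataset":
        """Keep snapshots up to time block ``n_blocks`` (inclusive)."""
        return TrajectoryDataset(
            self.u[:, : n_blocks + 1],
            self.v[:, : n_blocks + 1],
            self.grid,
            self.dt_obs,
            self.noise_level,
            self.seed,
            dict(self.meta),
        )

    def save_h5(self, path, truth: "TrajectoryDataset | None" = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("observed")
            g.create_dataset("u", data=self.u)
            g.create_dataset("v", data=self.v)
            if truth is not None:
                t = f.create_group("truth")
                t.create_dataset("u", data=truth.u)
                t.create_dataset("v", data=truth.v)
            f.attrs["dt_obs"] = self.dt_obs
            f.attrs["noise_level"] = self.noise_level
            f.attrs["seed"] = -1 if self.seed is None else self.seed
            f.attrs["extent"] = self.grid.extent
            f.attrs["dim"] = self.grid.dim
            f.attrs["n_points"] = self.grid.n_points

    @classmethod
    def load_h5(cls, path) -> "TrajectoryDataset":
        import h5py

        with h5py.File(path, "r") as f:
            grid = SpatialGrid(
                int(f.attrs["dim"]),
                tuple(f.attrs["extent"]),
                int(f.attrs["n_points"]),
            )
            seed = int(f.attrs["seed"])
            return cls(
                f["observed/u"][...],
                f["observed/v"][...],
                grid,
                float(f.attrs["dt_obs"]),
                float(f.attrs["noise_level"]),
                None if seed < 0 else seed,
            )
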