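"""Density-field formulation: logistic growth with nonlocal competition plus
mutation diffusion on a regular trait-space grid.

    du/dt = r u (1 - (integral alpha(z', z) u(z') dz') / K(z)) + D lap(u)

The competition integral is a dense kernel quadrature (the kernel is not
translation-invariant when b != 0), precomputed once per grid.  Time stepping
is classical RK4 with no-flux boundaries; negative values are clamped and a
noise floor removes the infinite tail that would otherwise make continuous
models branch everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from nichepack.kernels import ModelParams, carrying_capacity, log_competition

__all__ = ["DensityField", "competition_operator", "step_pde", "run_pde", "find_peaks_2d"]

_MAX_GRID = 96  # dense n^4 kernel guard


@dataclass
class DensityField:
    """Nonnegative density over an n x n lattice covering [-L, L]^2."""

    values: NDArray[np.float64]  # (n, n), row index = y, col index = x
    extent: float = 2.5
    time: float = 0.0
    diffusion: float = 1e-4
    noise_floor_fraction: float = 1e-12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be a square 2-D array")
        if self.values.shape[0] > _MAX_GRID:
            raise ValueError(f"grid larger than {_MAX_GRID} nodes per axis is not supported")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        if self.diffusion < 0:
            raise ValueError("diffusion must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def spacing(self) -> float:
        return 2 * self.extent / (self.n - 1)

    @property
    def cell_area(self) -> float:
        return self.spacing**2

    def axes(self) -> NDArray[np.float64]:
        return np.linspace(-self.extent, self.extent, self.n)

    def nodes(self) -> NDArray[np.float64]:
        """(n*n, 2) phenotype coordinates of every grid node."""
        ax = self.axes()
        xx, yy = np.meshgrid(ax, ax)
        return np.stack([xx.ravel(), yy.ravel()], axis=-1)

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_area)

    @classmethod
    def gaussian_blob(
        cls,
        center: tuple[float, float],
        width: float,
        mass: float = 0.1,
        n: int = 64,
        extent: float = 2.5,
        **kwargs,
    ) -> "DensityField":
        ax = np.linspace(-extent, extent, n)
        xx, yy = np.meshgrid(ax, ax)
        u = np.exp(-(((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * width**2)))
        h = 2 * extent / (n - 1)
        u *= mass / (u.sum() * h * h)
        return cls(u, extent=extent, **kwargs)


def competition_operator(field: DensityField, params: ModelParams) -> NDArray[np.float64]:
    """Dense quadrature matrix C with C[a, b] = alpha(z_b, z_a).

    ``(C @ u.ravel()) * cell_area`` approximates the nonlocal competition
    integral at every node.  float32 storage: the kernel is smooth and O(1),
    so quadrature error dominates rounding.
    """
    nodes = field.nodes()
    c = np.empty((len(nodes), len(nodes)), np.float32)
    # row-blocked evaluation keeps peak memory modest
    block = 1024
    for start in range(0, len(nodes), block):
        sl = slice(start, min(start + block, len(nodes)))
        c[sl] = np.exp(
            log_competition(nodes[None, :, :], nodes[sl, None, :], params)
        ).astype(np.float32)
    return c


def _laplacian_noflux(u: NDArray, h: float) -> NDArray:
    """5-point Laplacian with reflecting (no-flux) boundaries."""
    up = np.empty_like(u)
    up[:] = -4.0 * u
    up[1:, :] += u[:-1, :]
    up[0, :] += u[0, :]
    up[:-1, :] += u[1:, :]
    up[-1, :] += u[-1, :]
    up[:, 1:] += u[:, :-1]
    up[:, 0] += u[:, 0]
    up[:, :-1] += u[:, 1:]
    up[:, -1] += u[:, -1]
    return up / (h * h)


def admissible_dt(field: DensityField, params: ModelParams) -> float:
    """Largest stable explicit step for the current diffusion and spacing."""
    bounds = [0.5 / params.r]
    if field.diffusion > 0:
        bounds.append(field.spacing**2 / (4.0 * field.diffusion))
    return min(bounds)


def step_pde(
    field: DensityField,
    dt: float,
    params: ModelParams,
    kernel: NDArray | None = None,
    k_grid: NDArray | None = None,
) -> DensityField:
    """One RK4 step of the reaction-diffusion dynamics.

    ``kernel`` and ``k_grid`` may pass the precomputed competition matrix
    and carrying-capacity grid.  Raises if ``dt`` exceeds the explicit-scheme
    stability bound.  Values are clamped at 0 and entries below the noise
    floor (``noise_floor_fraction`` of the field maximum) are zeroed.
    """
    dt_max = admissible_dt(field, params)
    if dt > dt_max:
        raise ValueError(f"dt={dt} violates the stability bound; admissible dt <= {dt_max:.6g}")
    if kernel is None:
        kernel = competition_operator(field, params)
    if k_grid is None:
        k_grid = carrying_capacity(field.nodes(), params).reshape(field.values.shape)
    h = field.spacing
    area = field.cell_area
    r = params.r
    d_coef = field.diffusion

    def rhs(u: NDArray) -> NDArray:
        load = (kernel @ u.ravel().astype(np.float32)).astype(float).reshape(u.shape) * area
        react = r * u * (1.0 - load / k_grid)
        if d_coef > 0:
            return react + d_coef * _laplacian_noflux(u, h)
        return react

    u0 = field.values
    k1 = rhs(u0)
    k2 = rhs(np.maximum(u0 + 0.5 * dt * k1, 0.0))
    k3 = rhs(np.maximum(u0 + 0.5 * dt * k2, 0.0))
    k4 = rhs(np.maximum(u0 + dt * k3, 0.0))
    u1 = u0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    u1 = np.maximum(u1, 0.0)
    floor = field.noise_floor_fraction * u1.max()
    u1[u1 < floor] = 0.0
    return replace(field, values=u1, time=field.time + dt)


def run_pde(
    model: ModelParams,
    field0: DensityField,
    t_end: float,
    dt: float | None = None,
    snapshot_every: float | None = None,
    mass_limit: float = 1e6,
) -> dict:
    """Time-step the field to ``t_end`` and report peaks of the final state.

    Returns a dict with ``snapshots`` (list of (time, values)), ``final``
    (DensityField), ``peaks`` ((p, 2) phenotypes of local maxima) and
    ``peak_count``.  Aborts with a diagnostic if total mass diverges.
    """
    if dt is None:
        dt = 0.5 * admissible_dt(field0, model)
    if snapshot_every is None:
        snapshot_every = max(t_end / 50.0, dt)
    kernel = competition_operator(field0, model)
    k_grid = carrying_capacity(field0.nodes(), model).reshape(field0.values.shape)
    field = field0
    snapshots = [(field.time, field.values.copy())]
    next_snap = field.time + snapshot_every
    n_steps = int(np.ceil(t_end / dt))
    for _ in range(n_steps):
        step = min(dt, t_end - field.time)
        if step <= 0:
            break
        field = step_pde(field, step, model, kernel=kernel, k_grid=k_grid)
        if not np.isfinite(field.values).all() or field.total_mass() > mass_limit:
            raise RuntimeError(
                f"PDE diverged at t={field.time:.3f} (mass={field.total_mass():.3g})"
            )
        if field.time >= next_snap - 1e-12:
            snapshots.append((field.time, field.values.copy()))
            next_snap += snapshot_every
    if snapshots[-1][0] < field.time:
        snapshots.append((field.time, field.values.copy()))
    peaks = find_peaks_2d(field)
    return {
        "snapshots": snapshots,
        "final": field,
        "peaks": peaks,
        "peak_count": len(peaks),
    }


def find_peaks_2d(field: DensityField, rel_threshold: float = 1e-3) -> NDArray[np.float64]:
    """Phenotypes of strict local maxima above ``rel_threshold * max``."""
    u = field.values
    if u.max() <= 0:
        return np.empty((0, 2))
    pad = np.pad(u, 1, mode="constant", constant_values=-np.inf)
    core = pad[1:-1, 1:-1]
    is_peak = np.ones_like(u, bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_peak &= core >= pad[1 + di : pad.shape[0] - 1 + di, 1 + dj : pad.shape[1] - 1 + dj]
    is_peak &= u > rel_threshold * u.max()
    iy, ix = np.nonzero(is_peak)
    ax = field.axes()
    return np.stack([ax[ix], ax[iy]], axis=-1)
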