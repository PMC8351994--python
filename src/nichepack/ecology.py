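"""Ecological layer: Lotka-Volterra dynamics, equilibria, extinction pruning.

The equilibrium solver uses a direct linear solve with iterative feasibility
pruning (and re-insertion of excluded species that could still invade), which
is the fast path used inside the evolutionary loop.  ODE integration of the
full dynamics is provided both as a user-facing operation and as the
verification oracle / fallback for the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

from nichepack.kernels import (
    ModelParams,
    carrying_capacity,
    log_competition,
)

__all__ = [
    "Community",
    "EquilibriumError",
    "interaction_matrix",
    "ecological_equilibrium",
    "integrate_lv",
    "prune_extinct",
]


class EquilibriumError(RuntimeError):
    """Raised when no feasible positive equilibrium subset can be found."""


@dataclass
class Community:
    """M distinct phenotypes with abundances and stable integer labels."""

    phenotypes: NDArray[np.float64]  # (M, d)
    abundances: NDArray[np.float64]  # (M,)
    labels: NDArray[np.int64] | None = None

    def __post_init__(self) -> None:
        self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))
        self.abundances = np.atleast_1d(np.asarray(self.abundances, dtype=float))
        m = len(self.phenotypes)
        if len(self.abundances) != m:
            raise ValueError("phenotypes and abundances must have equal length")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be nonnegative")
        if self.labels is None:
            self.labels = np.arange(m, dtype=np.int64)
        else:
            self.labels = np.atleast_1d(np.asarray(self.labels, dtype=np.int64))
            if len(self.labels) != m:
                raise ValueError("labels must have equal length")
            if len(np.unique(self.labels)) != m:
                raise ValueError("labels must be unique")

    @property
    def size(self) -> int:
        return len(self.abundances)

    @property
    def d(self) -> int:
        return self.phenotypes.shape[1]

    def subset(self, idx: ArrayLike) -> "Community":
        idx = np.asarray(idx)
        return Community(self.phenotypes[idx], self.abundances[idx], self.labels[idx])

    def copy(self) -> "Community":
        return Community(
            self.phenotypes.copy(), self.abundances.copy(), self.labels.copy()
        )

    @classmethod
    def empty(cls, d: int = 2) -> "Community":
        return cls(
            np.empty((0, d)), np.empty(0), np.empty(0, dtype=np.int64)
        )


def interaction_matrix(community: Community, params: ModelParams) -> NDArray[np.float64]:
    """M x M matrix with entry (i, j) = alpha(z_j, z_i): effect of j on i."""
    z = community.phenotypes
    # log_competition(u, v) is effect of u on v; row i is the focal species.
    return np.exp(log_competition(z[None, :, :], z[:, None, :], params))


def _growth_residual(
    a: NDArray, n: NDArray, k: NDArray
) -> NDArray[np.float64]:
    """Per-capita growth rates 1 - (A n)_i / K_i."""
    return 1.0 - (a @ n) / k


def ecological_equilibrium(
    community: Community,
    params: ModelParams,
    tol: float = 1e-10,
    max_rounds: int | None = None,
) -> Community:
    """Saturated ecological equilibrium of Eq-4 dynamics by linear solve.

    Solves ``sum_j alpha(z_j, z_i) N_j = K(z_i)`` on a subset of species such
    that retained abundances are strictly positive and no excluded species
    has positive invasion fitness.  Infeasible species are removed largest
    violation first; excluded species that could re-invade are re-inserted.
    Falls back to ODE integration if the subset search cycles.

    Returns a new :class:`Community` containing survivors only (labels
    preserved).  Raises :class:`EquilibriumError` on a singular interaction
    matrix (duplicate phenotypes: merging is required first).
    """
    m = community.size
    if m == 0:
        return community.copy()
    a_full = interaction_matrix(community, params)
    k_full = carrying_capacity(community.phenotypes, params)
    active = np.ones(m, dtype=bool)
    if max_rounds is None:
        max_rounds = 4 * m + 16
    seen: set[bytes] = set()
    for _ in range(max_rounds):
        key = active.tobytes()
        if key in seen:  # subset cycle: hand over to the ODE oracle
            return _equilibrium_by_integration(community, params, tol)
        seen.add(key)
        idx = np.flatnonzero(active)
        a = a_full[np.ix_(idx, idx)]
        k = k_full[idx]
        try:
            n = np.linalg.solve(a, k)
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(
                "singular interaction matrix (near-duplicate phenotypes); "
                "merge close phenotypes before equilibrating"
            ) from exc
        if np.any(n <= 0):
            worst = idx[np.argmin(n)]
            active[worst] = False
            if not active.any():
                raise EquilibriumError("no feasible positive subset found")
            continue
        # feasible: check excluded species cannot invade
        n_full = np.zeros(m)
        n_full[idx] = n
        fitness = _growth_residual(a_full, n_full, k_full)
        invaders = np.flatnonzero(~active & (fitness > tol))
        if invaders.size:
            active[invaders[np.argmax(fitness[invaders])]] = True
            continue
        out = community.subset(idx)
        out.abundances = n
        return out
    return _equilibrium_by_integration(community, params, tol)


def _equilibrium_by_integration(
    community: Community, params: ModelParams, tol: float, t_span: float = 5e3
) -> Community:
    """ODE-integration fallback: run Eq 4 to a (numerically) stationary state."""
    n0 = np.maximum(community.abundances, 1e-8)
    ts, ns = integrate_lv(community, n0, t_span, params)
    n_end = ns[-1]
    keep = n_end > tol
    if not keep.any():
        return Community.empty(community.d)
    out = community.subset(np.flatnonzero(keep))
    out.abundances = n_end[keep]
    return out


def integrate_lv(
    community: Community,
    initial_abundances: ArrayLike,
    t_span: float,
    params: ModelParams,
    n_points: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> tuple[NDArray, NDArray]:
    """Integrate the Lotka-Volterra dynamics from given initial abundances.

    Returns ``(times, trajectory)`` with trajectory shape (n_points, M).
    Abundances are clamped at 0 (absorbing).
    """
    n0 = np.asarray(initial_abundances, float)
    if np.any(n0 < 0):
        raise ValueError("initial abundances must be nonnegative")
    a = interaction_matrix(community, params)
    k = carrying_capacity(community.phenotypes, params)
    r = params.r

    def rhs(_t, n):
        n = np.maximum(n, 0.0)
        return r * n * (1.0 - (a @ n) / k)

    ts = np.linspace(0.0, t_span, n_points)
    sol = solve_ivp(rhs, (0.0, t_span), n0, t_eval=ts, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - integrator diagnostics
        raise RuntimeError(
            f"LV integration failed: {sol.message}; state={sol.y[:, -1] if sol.y.size else n0}"
        )
    return sol.t, np.maximum(sol.y.T, 0.0)


def prune_extinct(community: Community, min_viable: float) -> Community:
    """Remove species with abundance below ``min_viable``; labels preserved."""
    keep = community.abundances >= min_viable
    if keep.all():
        return community.copy()
    return community.subset(np.flatnonzero(keep))
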