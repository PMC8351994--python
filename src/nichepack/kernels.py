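"""Closed-form model functions shared by all three simulation frameworks.

Carrying capacity ``K(z)``, competition kernel ``alpha(z_i, z_j)``, invasion
fitness of a rare mutant, and the selection gradient.  All functions are
vectorised over trailing phenotype axes and evaluated in log space where
underflow is a concern.

Conventions
-----------
``competition(u, v)`` is the competitive effect *of* ``u`` *on* ``v``: the
per-capita loss term of a focal phenotype ``v`` sums ``competition(z_j, v)``
over competitors ``j``.  The kernel equals 1 for identical phenotypes and is
generally asymmetric when the ``b`` coefficients are nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import numpy as np
from numpy.typing import ArrayLike, NDArray

if TYPE_CHECKING:  # pragma: no cover
    from nichepack.ecology import Community

__all__ = [
    "ModelParams",
    "log_carrying_capacity",
    "carrying_capacity",
    "grad_log_carrying_capacity",
    "log_competition",
    "competition",
    "invasion_fitness_mono",
    "invasion_fitness_community",
    "selection_gradient",
    "community_selection_gradients",
]

# log K below this is treated as an underflow: invasion fitness into such a
# phenotype is reported as a large negative number instead of inf/nan.
_LOG_UNDERFLOW = -700.0
_FITNESS_FLOOR = -1e300


@dataclass(frozen=True, eq=False)
class ModelParams:
    """Kernel choices and coefficients shared by all frameworks.

    Parameters
    ----------
    carrying_kind:
        ``"quartic"`` for ``exp(-sum_k z_k^4 / 4)`` or ``"radial"`` for the
        radially symmetric ``exp(-(sum_k z_k^2 / 2)^2 / 2)``.
    sigma_alpha:
        Width of the Gaussian part of the competition kernel (trait units).
    b:
        d x d asymmetry coefficients; the all-zero matrix gives symmetric
        Gaussian competition.
    r:
        Intrinsic per-capita growth rate in the Lotka-Volterra dynamics.
    d:
        Trait-space dimension (2 throughout the headline scenarios).
    printed_asymmetry:
        Compatibility switch.  The corrected asymmetric exponent is
        ``sum_kl b_kl (u_k - v_k) u_l`` which vanishes at ``u == v``; the
        switch restores the published index pattern
        ``sum_kl b_kl (u_k - v_l) u_l`` which does not.
    """

    carrying_kind: Literal["quartic", "radial"] = "quartic"
    sigma_alpha: float = 0.5
    b: NDArray[np.float64] | None = None
    r: float = 1.0
    d: int = 2
    printed_asymmetry: bool = False

    def __post_init__(self) -> None:
        if self.carrying_kind not in ("quartic", "radial"):
            raise ValueError(f"unknown carrying_kind {self.carrying_kind!r}")
        if not (self.sigma_alpha > 0):
            raise ValueError("sigma_alpha must be positive")
        if not (self.r > 0):
            raise ValueError("r must be positive")
        if self.d < 1:
            raise ValueError("d must be a positive integer")
        b = np.zeros((self.d, self.d)) if self.b is None else np.asarray(self.b, float)
        if b.shape != (self.d, self.d):
            raise ValueError(f"b must be {self.d}x{self.d}, got {b.shape}")
        if not np.all(np.isfinite(b)):
            raise ValueError("b entries must be finite")
        b = b.copy()
        b.setflags(write=False)
        object.__setattr__(self, "b", b)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelParams):
            return NotImplemented
        return (
            self.carrying_kind == other.carrying_kind
            and self.sigma_alpha == other.sigma_alpha
            and self.r == other.r
            and self.d == other.d
            and self.printed_asymmetry == other.printed_asymmetry
            and np.array_equal(self.b, other.b)
        )

    def __hash__(self) -> int:
        return hash(
            (self.carrying_kind, self.sigma_alpha, self.r, self.d,
             self.printed_asymmetry, self.b.tobytes())
        )

    @property
    def symmetric(self) -> bool:
        """True when competition is exchange-symmetric (all b entries 0)."""
        return bool(np.all(self.b == 0))


def _check_finite(z: NDArray, name: str) -> None:
    if not np.all(np.isfinite(z)):
        raise ValueError(f"{name} contains non-finite coordinates")


def _as_phenotypes(z: ArrayLike, d: int, name: str = "z") -> NDArray[np.float64]:
    arr = np.asarray(z, dtype=float)
    if arr.shape[-1:] != (d,):
        raise ValueError(f"{name} must have trailing dimension {d}, got shape {arr.shape}")
    _check_finite(arr, name)
    return arr


def log_carrying_capacity(z: ArrayLike, params: ModelParams) -> NDArray[np.float64]:
    """log K(z), vectorised over leading axes of ``z``."""
    zz = _as_phenotypes(z, params.d)
    if params.carrying_kind == "quartic":
        return -np.sum(zz**4, axis=-1) / 4.0
    s = np.sum(zz**2, axis=-1) / 2.0
    return -(s**2) / 2.0


def carrying_capacity(z: ArrayLike, params: ModelParams) -> NDArray[np.float64]:
    """Carrying capacity K(z) in (0, 1], peak 1 at the origin."""
    return np.exp(log_carrying_capacity(z, params))


def grad_log_carrying_capacity(z: ArrayLike, params: ModelParams) -> NDArray[np.float64]:
    """Gradient of log K, same shape as ``z``."""
    zz = _as_phenotypes(z, params.d)
    if params.carrying_kind == "quartic":
        return -(zz**3)
    s = np.sum(zz**2, axis=-1, keepdims=True) / 2.0
    return -s * zz


def log_competition(z_i: ArrayLike, z_j: ArrayLike, params: ModelParams) -> NDArray[np.float64]:
    """log alpha(z_i, z_j): effect of phenotype ``z_i`` on focal ``z_j``.

    Broadcasts over leading axes of both arguments.
    """
    u = _as_phenotypes(z_i, params.d, "z_i")
    v = _as_phenotypes(z_j, params.d, "z_j")
    diff = u - v
    gauss = -np.sum(diff**2, axis=-1) / (2.0 * params.sigma_alpha**2)
    if params.symmetric:
        return gauss
    if params.printed_asymmetry:
        # published index pattern: sum_kl b_kl (u_k - v_l) u_l
        col_sum = np.asarray(params.b).sum(axis=0)
        asym = np.einsum("kl,...k,...l->...", params.b, u, u) - np.sum(
            col_sum * v * u, axis=-1
        )
    else:
        # corrected: difference taken within trait k, so alpha(z, z) == 1
        asym = np.einsum("kl,...k,...l->...", params.b, diff, u)
    return asym + gauss


def competition(z_i: ArrayLike, z_j: ArrayLike, params: ModelParams) -> NDArray[np.float64]:
    """Competition kernel alpha(z_i, z_j); equals 1 when z_i == z_j."""
    return np.exp(log_competition(z_i, z_j, params))


def invasion_fitness_mono(
    z_r: ArrayLike, z_m: ArrayLike, params: ModelParams
) -> NDArray[np.float64]:
    """Invasion fitness of a rare mutant ``z_m`` against a monomorphic resident.

    ``f = 1 - alpha(z_r, z_m) K(z_r) / K(z_m)``, with the resident at its
    equilibrium density ``K(z_r)``.  ``f(z, z) == 0`` exactly; positive values
    mean the mutant can invade.  Underflowing ``K(z_m)`` yields a large
    negative fitness rather than inf.
    """
    log_a = log_competition(z_r, z_m, params)
    log_kr = log_carrying_capacity(z_r, params)
    log_km = log_carrying_capacity(z_m, params)
    expo = log_a + log_kr - log_km
    with np.errstate(over="ignore"):
        f = 1.0 - np.exp(expo)
    return np.where(log_km < _LOG_UNDERFLOW, _FITNESS_FLOOR, f)


def invasion_fitness_community(
    community: "Community", z_m: ArrayLike, params: ModelParams
) -> NDArray[np.float64]:
    """Per-capita growth rate of a rare mutant in an equilibrated community.

    ``f = 1 - sum_j alpha(z_j, z_m) N_j / K(z_m)``.  Vanishes at every
    resident phenotype when abundances are the exact ecological equilibrium;
    the empty community gives 1 (pure birth rate) everywhere.
    """
    zm = _as_phenotypes(z_m, params.d, "z_m")
    if community.size == 0:
        return np.ones(zm.shape[:-1]) if zm.ndim > 1 else np.float64(1.0)
    n = np.asarray(community.abundances, float)
    if np.any(n < 0):
        raise ValueError("community abundances must be nonnegative")
    log_km = log_carrying_capacity(zm, params)
    # alpha of each resident j on the mutant(s): shape (..., M)
    log_a = log_competition(community.phenotypes, zm[..., None, :], params)
    load = np.einsum("...j,j->...", np.exp(log_a), n)
    f = 1.0 - load * np.exp(-log_km)
    return np.where(log_km < _LOG_UNDERFLOW, _FITNESS_FLOOR, f)


def community_selection_gradients(
    community: "Community",
    params: ModelParams,
    interaction: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """Analytic selection gradients for every resident, shape (M, d).

    Row ``i`` is the gradient of mutant invasion fitness with respect to the
    mutant phenotype, evaluated at ``z_i`` with the community held at its
    supplied abundances.  ``interaction`` may pass a precomputed matrix with
    entry (i, j) = alpha(z_j, z_i) to avoid rebuilding it.
    """
    if params.printed_asymmetry:
        return np.stack(
            [
                _finite_difference_gradient(community, i, params)
                for i in range(community.size)
            ]
        )
    z = community.phenotypes
    n = np.asarray(community.abundances, float)
    if interaction is None:
        from nichepack.ecology import interaction_matrix

        interaction = interaction_matrix(community, params)
    k = carrying_capacity(z, params)
    w = interaction * n[None, :]  # w[i, j] = alpha(z_j, z_i) N_j
    s = w.sum(axis=1)  # competitive load on each resident
    sig2 = params.sigma_alpha**2
    # d/dv_p alpha(u, v) = alpha * (-(b v... ) ...): see log_competition
    term_b = w @ (z @ np.asarray(params.b).T)  # sum_j N_j a_ij (b z_j)_p
    term_g = (w @ z - s[:, None] * z) / sig2  # sum_j N_j a_ij (z_j - z_i)_p / sig2
    grad = (term_b - term_g) / k[:, None] + (s / k)[:, None] * grad_log_carrying_capacity(
        z, params
    )
    return grad


def _finite_difference_gradient(
    community: "Community", i: int, params: ModelParams, step: float = 1e-5
) -> NDArray[np.float64]:
    z_i = community.phenotypes[i]
    grad = np.empty(params.d)
    for p in range(params.d):
        zp = z_i.copy()
        zm = z_i.copy()
        zp[p] += step
        zm[p] -= step
        fp = invasion_fitness_community(community, zp, params)
        fm = invasion_fitness_community(community, zm, params)
        grad[p] = (fp - fm) / (2.0 * step)
    return grad


def selection_gradient(
    community: "Community",
    i: int,
    params: ModelParams,
    method: Literal["analytic", "finite_difference"] = "analytic",
) -> NDArray[np.float64]:
    """Selection gradient on resident ``i``: grad of invasion fitness at z_i."""
    if not 0 <= i < community.size:
        raise IndexError(f"species index {i} out of range for community of size {community.size}")
    if method == "finite_difference":
        return _finite_difference_gradient(community, i, params)
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    return community_selection_gradients(community, params)[i]
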