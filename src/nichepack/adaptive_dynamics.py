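"""Quasi-deterministic evolutionary engine.

Trait flow follows the canonical equation (rate proportional to equilibrium
abundance times the selection gradient) between stochastic mutation attempts;
branching, merging and extinction follow the seven-step loop: equilibrate,
prune, flow, merge, propose mutant, accept if it can invade, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

from nichepack.kernels import (
    ModelParams,
    carrying_capacity,
    community_selection_gradients,
    invasion_fitness_community,
)
from nichepack.ecology import (
    Community,
    EquilibriumError,
    ecological_equilibrium,
    interaction_matrix,
    prune_extinct,
)

__all__ = [
    "ADConfig",
    "ADTrajectory",
    "canonical_step",
    "canonical_flow",
    "merge_close",
    "propose_mutant",
    "attempt_branch",
    "run_ad",
]


@dataclass(frozen=True)
class ADConfig:
    """Run parameters for the adaptive-dynamics loop.

    ``sigma_mut == 0`` selects fixed-offset branching mutations of magnitude
    ``eps_mut`` in a uniformly random direction; ``sigma_mut > 0`` selects
    Gaussian offsets with per-axis scale ``sigma_mut``.
    """

    eps_mut: float = 0.02
    sigma_mut: float = 0.0
    delta_merge: float = 0.005
    min_viable: float = 1e-4
    epoch_time: float = 1.0
    n_attempts: int = 20_000
    kappa: float = 1.0
    seed: int = 0
    initial_n: int = 1
    initial_box: tuple[float, float] = (-2.0, 2.0)
    max_step: float = 0.02
    max_substeps: int = 50
    snapshot_every: int = 20
    esc_grad_tol: float = 1e-4
    esc_patience: int = 500
    eq_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.eps_mut <= 0:
            raise ValueError("eps_mut must be positive")
        if self.sigma_mut < 0:
            raise ValueError("sigma_mut must be nonnegative")
        if self.sigma_mut > 0 and self.sigma_mut < self.eps_mut:
            raise ValueError("Gaussian mode requires sigma_mut >= eps_mut")
        if not (0 < self.delta_merge < self.eps_mut):
            raise ValueError("delta_merge must lie in (0, eps_mut)")
        if self.min_viable <= 0 or self.epoch_time <= 0 or self.kappa <= 0:
            raise ValueError("min_viable, epoch_time and kappa must be positive")
        if self.initial_n < 1:
            raise ValueError("initial_n must be >= 1")


@dataclass
class ADTrajectory:
    """Time-ordered snapshots plus the branch/extinction/merge event log."""

    snapshots: list[tuple[float, Community]] = field(default_factory=list)
    events: list[tuple[float, str, tuple]] = field(default_factory=list)
    final: Community | None = None
    converged: bool = False
    attempts_used: int = 0
    config: ADConfig | None = None
    model: ModelParams | None = None

    def record(self, t: float, community: Community) -> None:
        if self.snapshots and t <= self.snapshots[-1][0]:
            t = np.nextafter(self.snapshots[-1][0], np.inf)
        self.snapshots.append((t, community.copy()))

    def log(self, t: float, kind: str, labels: tuple) -> None:
        self.events.append((t, kind, labels))


def canonical_step(
    community: Community,
    dt: float,
    params: ModelParams,
    kappa: float = 1.0,
    eq_tol: float = 1e-10,
) -> Community:
    """One explicit Euler step of the canonical trait flow.

    Each phenotype moves along ``dz_i/dt = kappa * N_i * g_i`` with the
    community re-equilibrated afterwards.  The caller is responsible for
    choosing ``dt`` small enough (see :func:`canonical_flow` for the adaptive
    driver that caps per-step displacement).
    """
    a = interaction_matrix(community, params)
    g = community_selection_gradients(community, params, interaction=a)
    v = kappa * community.abundances[:, None] * g
    out = community.copy()
    out.phenotypes = out.phenotypes + dt * v
    return ecological_equilibrium(out, params, tol=eq_tol)


def canonical_flow(
    community: Community,
    duration: float,
    params: ModelParams,
    kappa: float = 1.0,
    max_step: float = 0.02,
    max_substeps: int = 50,
    eq_tol: float = 1e-10,
) -> tuple[Community, NDArray[np.float64]]:
    """Integrate the canonical equation for ``duration`` time units.

    Adaptive explicit Euler: the substep is chosen so no phenotype moves more
    than ``max_step``, re-equilibrating after every substep (species that
    lose feasibility drop out).  Returns the evolved community and the last
    selection-gradient array (for stationarity tests).
    """
    state = ecological_equilibrium(community, params, tol=eq_tol)
    remaining = duration
    g = np.zeros_like(state.phenotypes)
    for _ in range(max_substeps):
        if state.size == 0 or remaining <= 0:
            break
        a = interaction_matrix(state, params)
        g = community_selection_gradients(state, params, interaction=a)
        v = kappa * state.abundances[:, None] * g
        speed = float(np.max(np.linalg.norm(v, axis=1))) if v.size else 0.0
        if speed == 0.0:
            break
        dt = min(remaining, max_step / speed)
        state = state.copy()
        state.phenotypes = state.phenotypes + dt * v
        state = ecological_equilibrium(state, params, tol=eq_tol)
        remaining -= dt
    return state, g


def merge_close(community: Community, delta_merge: float) -> Community:
    """Collapse transitively-close phenotypes (distance < delta_merge).

    Merged species get the abundance-weighted mean phenotype and summed
    abundance; total abundance is conserved exactly.  The smallest label in
    each merged group survives.
    """
    from nichepack.analysis import cluster_species

    if community.size <= 1:
        return community.copy()
    rep = cluster_species(community.phenotypes, delta_merge, weights=community.abundances)
    if rep.count == community.size:
        return community.copy()
    phen = rep.centroids
    ab = np.zeros(rep.count)
    labels = np.full(rep.count, np.iinfo(np.int64).max, dtype=np.int64)
    np.add.at(ab, rep.labels, community.abundances)
    np.minimum.at(labels, rep.labels, community.labels)
    return Community(phen, ab, labels)


def propose_mutant(
    community: Community, rng: np.random.Generator, config: ADConfig
) -> tuple[int, NDArray[np.float64]]:
    """Pick a uniform random parent and return (parent label, mutant phenotype).

    Fixed mode: offset of magnitude ``eps_mut`` in a direction uniform on the
    sphere.  Gaussian mode: independent per-axis Gaussian deviates of scale
    ``sigma_mut``.
    """
    if community.size == 0:
        raise ValueError("cannot propose a mutant in an empty community")
    i = int(rng.integers(community.size))
    parent = community.phenotypes[i]
    d = community.d
    if config.sigma_mut > 0:
        offset = rng.normal(0.0, config.sigma_mut, size=d)
    else:
        direction = rng.normal(size=d)
        norm = np.linalg.norm(direction)
        while norm == 0.0:  # pragma: no cover - probability zero
            direction = rng.normal(size=d)
            norm = np.linalg.norm(direction)
        offset = config.eps_mut * direction / norm
    return int(community.labels[i]), parent + offset


def attempt_branch(
    community: Community,
    parent: int,
    mutant: NDArray[np.float64],
    params: ModelParams,
    min_viable: float = 1e-4,
    eq_tol: float = 1e-10,
    next_label: int | None = None,
) -> tuple[Community, bool]:
    """Admit the mutant iff its invasion fitness is strictly positive.

    An admitted mutant enters at abundance ``min_viable`` and the community
    is re-equilibrated; otherwise the community is returned unchanged.
    """
    f = float(invasion_fitness_community(community, mutant, params))
    if not f > 0.0:
        return community, False
    if next_label is None:
        next_label = int(community.labels.max()) + 1 if community.size else 0
    grown = Community(
        np.vstack([community.phenotypes, mutant[None, :]]),
        np.concatenate([community.abundances, [min_viable]]),
        np.concatenate([community.labels, [next_label]]),
    )
    return ecological_equilibrium(grown, params, tol=eq_tol), True


def run_ad(
    model: ModelParams,
    config: ADConfig,
    initial: Community | None = None,
) -> ADTrajectory:
    """Run the full adaptive-dynamics loop.

    Per mutation attempt: equilibrate, prune below ``min_viable``, integrate
    the canonical flow for ``epoch_time``, merge phenotypes closer than
    ``delta_merge``, propose a mutant from a random parent, and admit it if
    its invasion fitness is positive.  Terminates early at an evolutionarily
    stable community (gradient norms below ``esc_grad_tol`` and no admitted
    mutant for ``esc_patience`` attempts) or after ``n_attempts``.
    """
    rng = np.random.default_rng(config.seed)
    seed_rng, mut_rng = rng.spawn(2)
    traj = ADTrajectory(config=config, model=model)
    if initial is None:
        lo, hi = config.initial_box
        z0 = seed_rng.uniform(lo, hi, size=(config.initial_n, model.d))
        community = Community(z0, np.full(config.initial_n, config.min_viable))
    else:
        community = initial.copy()
    next_label = int(community.labels.max()) + 1
    try:
        community = ecological_equilibrium(community, model, tol=config.eq_tol)
    except EquilibriumError:
        community = merge_close(community, config.delta_merge)
        community = ecological_equilibrium(community, model, tol=config.eq_tol)
    t = 0.0
    traj.record(t, community)
    last_accept = 0
    for attempt in range(1, config.n_attempts + 1):
        prev_labels = set(community.labels.tolist())
        pruned = prune_extinct(community, config.min_viable)
        if pruned.size == 0:
            traj.log(t, "extinction", tuple(sorted(prev_labels)))
            traj.final = pruned
            traj.attempts_used = attempt
            return traj
        if pruned.size < community.size:
            gone = prev_labels - set(pruned.labels.tolist())
            traj.log(t, "extinction", tuple(sorted(gone)))
        community = pruned
        community, grads = canonical_flow(
            community,
            config.epoch_time,
            model,
            kappa=config.kappa,
            max_step=config.max_step,
            max_substeps=config.max_substeps,
            eq_tol=config.eq_tol,
        )
        t += config.epoch_time
        if community.size == 0:
            traj.log(t, "extinction", tuple(sorted(prev_labels)))
            traj.final = community
            traj.attempts_used = attempt
            return traj
        lost = prev_labels - set(community.labels.tolist())
        if lost:
            traj.log(t, "extinction", tuple(sorted(lost)))
        merged = merge_close(community, config.delta_merge)
        if merged.size < community.size:
            gone = set(community.labels.tolist()) - set(merged.labels.tolist())
            traj.log(t, "merge", tuple(sorted(gone)))
            merged = ecological_equilibrium(merged, model, tol=config.eq_tol)
        community = merged
        parent, mutant = propose_mutant(community, mut_rng, config)
        community, accepted = attempt_branch(
            community,
            parent,
            mutant,
            model,
            min_viable=config.min_viable,
            eq_tol=config.eq_tol,
            next_label=next_label,
        )
        if accepted:
            traj.log(t, "branch", (parent, next_label))
            next_label += 1
            last_accept = attempt
        if attempt % config.snapshot_every == 0:
            traj.record(t, community)
        grad_norm = float(np.max(np.linalg.norm(grads, axis=1))) if grads.size else 0.0
        if (
            grad_norm < config.esc_grad_tol
            and attempt - last_accept >= config.esc_patience
        ):
            traj.converged = True
            traj.attempts_used = attempt
            break
    else:
        traj.attempts_used = config.n_attempts
    traj.record(t, community)
    traj.final = community
    return traj
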