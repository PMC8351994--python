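"""Individual-based birth-death simulator.

Individuals carry a phenotype; births occur at a fixed per-capita rate with
mutation at every birth, deaths at a frequency-dependent rate built from the
competition kernel and carrying capacity (scaled by ``k_max``).  The default
scheduler is exact Gillespie (continuous time, one rate-proportional event
per step); a discrete random-sequential scheduler is available behind a flag
for fidelity comparisons.

The hot loop is compiled with numba and keeps incremental competition-load
sums (one per individual) updated in O(N) per event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from numpy.typing import NDArray

from nichepack.kernels import ModelParams, carrying_capacity, competition

__all__ = [
    "IBMConfig",
    "PopulationOfIndividuals",
    "IBMTrajectory",
    "death_rate",
    "competition_load",
    "step_ibm",
    "run_ibm",
]


@dataclass(frozen=True)
class IBMConfig:
    """Run parameters for the individual-based simulation."""

    k_max: float = 200.0
    birth_rate: float = 1.0
    sigma_mut_ibm: float = 0.005
    seed: int = 0
    initial_individuals: int = 1
    initial_box: tuple[float, float] = (-2.0, 2.0)
    max_events: int = 1_000_000
    cluster_delta: float = 0.1
    snapshot_every: int = 1000
    include_self_competition: bool = True
    scheduler: str = "gillespie"  # or "random_sequential"

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.birth_rate <= 0 or self.sigma_mut_ibm <= 0:
            raise ValueError("rates and mutation scale must be strictly positive")
        if self.initial_individuals < 1:
            raise ValueError("initial_individuals must be >= 1")
        if self.scheduler not in ("gillespie", "random_sequential"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class PopulationOfIndividuals:
    """Multiset of individual phenotypes at a point in event time."""

    individuals: NDArray[np.float64]  # (N, d)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.individuals = np.atleast_2d(np.asarray(self.individuals, float))
        if self.time < 0:
            raise ValueError("time must be nonnegative")

    @property
    def size(self) -> int:
        return 0 if self.individuals.size == 0 else len(self.individuals)


@dataclass
class IBMTrajectory:
    times: NDArray[np.float64]
    sizes: NDArray[np.int64]
    snapshots: list[tuple[float, PopulationOfIndividuals]]
    cluster_counts: NDArray[np.int64]
    final: PopulationOfIndividuals
    extinct: bool
    config: IBMConfig
    model: ModelParams
    load_cache: NDArray[np.float64] | None = None

    def final_cluster_count(self, window: int = 200) -> float:
        """Median cluster count over the last ``window`` snapshots."""
        if len(self.cluster_counts) == 0:
            return 0.0
        return float(np.median(self.cluster_counts[-window:]))


def competition_load(population: PopulationOfIndividuals, model: ModelParams) -> NDArray:
    """Full O(N^2) competition sums: S_i = sum_j alpha(z_j, z_i), self included."""
    z = population.individuals
    if population.size == 0:
        return np.empty(0)
    a = competition(z[None, :, :], z[:, None, :], model)
    return a.sum(axis=1)


def death_rate(
    focal: int | NDArray,
    population: PopulationOfIndividuals,
    model: ModelParams,
    config: IBMConfig,
) -> float:
    """Frequency-dependent death rate of one individual.

    ``sum_j alpha(z_j, z_focal) / (k_max * K(z_focal))`` over the whole
    population, the focal individual's self-term (alpha = 1) included by
    default so the monomorphic birth-death balance sits at ``k_max * K``.
    ``focal`` may be an index into the population or a phenotype vector.
    """
    z = population.individuals
    if isinstance(focal, (int, np.integer)):
        zf = z[int(focal)]
        load = float(competition(z, zf[None, :], model).sum())
    else:
        zf = np.asarray(focal, float)
        load = float(competition(z, zf[None, :], model).sum()) + 1.0
    if not config.include_self_competition:
        load -= 1.0
    k = float(carrying_capacity(zf, model))
    return load / (config.k_max * k)


def step_ibm(
    population: PopulationOfIndividuals,
    rng: np.random.Generator,
    model: ModelParams,
    config: IBMConfig,
) -> tuple[PopulationOfIndividuals, str]:
    """One exact-Gillespie event (reference implementation, O(N^2)).

    Returns the new population and the event kind (``"birth"``/``"death"``).
    The numba production loop in :func:`run_ibm` is the fast path; this
    function is its behavioural specification and test oracle.
    """
    n = population.size
    if n == 0:
        raise ValueError("population is extinct")
    z = population.individuals
    k = carrying_capacity(z, model)
    loads = competition_load(population, model)
    if not config.include_self_competition:
        loads = loads - 1.0
    drates = loads / (config.k_max * k)
    total = n * config.birth_rate + drates.sum()
    dt = rng.exponential(1.0 / total)
    u = rng.uniform(0.0, total)
    if u < n * config.birth_rate:
        parent = min(int(u / config.birth_rate), n - 1)
        child = z[parent] + rng.normal(0.0, config.sigma_mut_ibm, size=z.shape[1])
        new_z = np.vstack([z, child[None, :]])
        kind = "birth"
    else:
        target = u - n * config.birth_rate
        victim = int(np.searchsorted(np.cumsum(drates), target, side="right"))
        victim = min(victim, n - 1)
        new_z = np.delete(z, victim, axis=0)
        kind = "death"
    return PopulationOfIndividuals(new_z, population.time + dt), kind


@njit(cache=True)
def _log_k(z, kind):
    s = 0.0
    if kind == 0:  # quartic
        for k in range(z.shape[0]):
            s += z[k] ** 4
        return -s / 4.0
    for k in range(z.shape[0]):
        s += z[k] ** 2
    s *= 0.5
    return -(s * s) / 2.0


@njit(cache=True)
def _alpha(u, v, b, inv2s2):
    """Competitive effect of phenotype u on focal v."""
    g = 0.0
    a = 0.0
    d = u.shape[0]
    for k in range(d):
        diff = u[k] - v[k]
        g += diff * diff
        for l in range(d):
            a += b[k, l] * diff * u[l]
    return np.exp(a - g * inv2s2)


@njit(cache=True)
def _run_core(
    z0,
    nmax,
    kind,
    sigma_alpha,
    b,
    k_max,
    birth_rate,
    sigma_mut,
    max_events,
    snap_every,
    include_self,
    scheduler,
    seed,
):
    np.random.seed(seed)
    d = z0.shape[1]
    n = z0.shape[0]
    z = np.zeros((nmax, d))
    z[:n] = z0
    inv2s2 = 1.0 / (2.0 * sigma_alpha * sigma_alpha)
    self_off = 0.0 if include_self else 1.0
    # per-individual caches: competition load (self included) and 1/(k_max K)
    load = np.zeros(nmax)
    inv_kk = np.zeros(nmax)
    for i in range(n):
        inv_kk[i] = 1.0 / (k_max * np.exp(_log_k(z[i], kind)))
        s = 0.0
        for j in range(n):
            s += _alpha(z[j], z[i], b, inv2s2)
        load[i] = s
    n_snaps = max_events // snap_every + 2
    snap_t = np.zeros(n_snaps)
    snap_n = np.zeros(n_snaps, np.int64)
    snap_z = np.zeros((n_snaps, nmax, d), np.float32)
    ev_t = np.zeros(max_events)
    ev_n = np.zeros(max_events, np.int64)
    t = 0.0
    isnap = 0
    status = 0  # 0 ok, 1 extinct, 2 capacity overflow
    events_done = 0
    for ev in range(max_events):
        drate_tot = 0.0
        for i in range(n):
            drate_tot += (load[i] - self_off) * inv_kk[i]
        if scheduler == 0:
            total = n * birth_rate + drate_tot
            t += np.random.exponential(1.0 / total)
            u = np.random.random() * total
            if u < n * birth_rate:
                birth = True
                idx = int(u / birth_rate)
                if idx >= n:
                    idx = n - 1
            else:
                birth = False
                target = u - n * birth_rate
                acc = 0.0
                idx = n - 1
                for i in range(n):
                    acc += (load[i] - self_off) * inv_kk[i]
                    if acc >= target:
                        idx = i
                        break
        else:
            # random-sequential: uniform individual, then birth vs death
            t += 1.0 / n
            idx = np.random.randint(0, n)
            di = (load[idx] - self_off) * inv_kk[idx]
            birth = np.random.random() * (birth_rate + di) < birth_rate
        if birth:
            if n >= nmax:
                status = 2
                events_done = ev
                break
            for k in range(d):
                z[n, k] = z[idx, k] + np.random.normal(0.0, sigma_mut)
            inv_kk[n] = 1.0 / (k_max * np.exp(_log_k(z[n], kind)))
            s = 0.0
            for i in range(n):
                load[i] += _alpha(z[n], z[i], b, inv2s2)
                s += _alpha(z[i], z[n], b, inv2s2)
            load[n] = s + 1.0  # self term
            n += 1
        else:
            for i in range(n):
                if i != idx:
                    load[i] -= _alpha(z[idx], z[i], b, inv2s2)
            last = n - 1
            if idx != last:
                for k in range(d):
                    z[idx, k] = z[last, k]
                load[idx] = load[last]
                inv_kk[idx] = inv_kk[last]
            n -= 1
            if n == 0:
                status = 1
                events_done = ev + 1
                ev_t[ev] = t
                ev_n[ev] = n
                break
        ev_t[ev] = t
        ev_n[ev] = n
        events_done = ev + 1
        if (ev + 1) % snap_every == 0:
            snap_t[isnap] = t
            snap_n[isnap] = n
            snap_z[isnap, :n] = z[:n]
            isnap += 1
    return (
        ev_t[:events_done],
        ev_n[:events_done],
        snap_t[:isnap],
        snap_n[:isnap],
        snap_z[:isnap],
        z[:n].copy(),
        load[:n].copy(),
        t,
        status,
    )


def run_ibm(
    model: ModelParams,
    config: IBMConfig,
    initial: PopulationOfIndividuals | None = None,
) -> IBMTrajectory:
    """Run the individual-based simulation for ``max_events`` events.

    Snapshots (phenotype clouds) are recorded every ``snapshot_every``
    events together with their clustered species counts at
    ``cluster_delta``.  Reproducible given the config seed.
    """
    from nichepack.analysis import cluster_species

    rng = np.random.default_rng(config.seed)
    if initial is None:
        lo, hi = config.initial_box
        z0 = rng.uniform(lo, hi, size=(config.initial_individuals, model.d))
    else:
        z0 = np.array(initial.individuals, float)
    nmax = int(12 * config.k_max + 16 * len(z0) + 500)
    core_seed = int(rng.integers(2**31 - 1))
    kind = 0 if model.carrying_kind == "quartic" else 1
    sched = 0 if config.scheduler == "gillespie" else 1
    (ev_t, ev_n, snap_t, snap_n, snap_z, z_final, load_final, t_final, status) = _run_core(
        np.ascontiguousarray(z0),
        nmax,
        kind,
        model.sigma_alpha,
        np.ascontiguousarray(np.asarray(model.b, float)),
        config.k_max,
        config.birth_rate,
        config.sigma_mut_ibm,
        config.max_events,
        config.snapshot_every,
        config.include_self_competition,
        sched,
        core_seed,
    )
    if status == 2:
        raise RuntimeError(
            f"population exceeded simulator capacity ({nmax}); increase k_max headroom"
        )
    snapshots = []
    counts = np.zeros(len(snap_t), np.int64)
    for i in range(len(snap_t)):
        pts = np.array(snap_z[i, : snap_n[i]], float)
        snapshots.append((float(snap_t[i]), PopulationOfIndividuals(pts, float(snap_t[i]))))
        counts[i] = cluster_species(pts, config.cluster_delta).count if len(pts) else 0
    final = PopulationOfIndividuals(z_final, t_final)
    return IBMTrajectory(
        times=ev_t,
        sizes=ev_n,
        snapshots=snapshots,
        cluster_counts=counts,
        final=final,
        extinct=(status == 1),
        config=config,
        model=model,
        load_cache=load_final,
    )
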