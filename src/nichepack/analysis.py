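"""Post-processing: species clustering, diversity series, fitness landscapes,
limit-cycle detection and metastability probing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.signal import find_peaks
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from nichepack.kernels import ModelParams, invasion_fitness_community
from nichepack.ecology import Community

__all__ = [
    "ClusterReport",
    "CycleReport",
    "MetastabilityReport",
    "cluster_species",
    "diversity_timeseries",
    "fitness_landscape",
    "detect_limit_cycle",
    "metastability_probe",
]

# defaults for species accounting: looser for IBM point clouds than for the
# already-merged adaptive-dynamics phenotypes
DEFAULT_IBM_DELTA = 0.1
DEFAULT_AD_DELTA = 0.05


@dataclass
class ClusterReport:
    labels: NDArray[np.int64]
    count: int
    centroids: NDArray[np.float64]
    linkage_delta: float


@dataclass
class CycleReport:
    is_cyclic: bool
    period: float | None
    direction: str  # clockwise | counterclockwise | mixed | none
    amplitude: NDArray[np.float64]
    winding: NDArray[np.float64] | None = None


@dataclass
class MetastabilityReport:
    returned: bool
    distance: float
    trace: NDArray[np.float64]
    tolerance: float


def cluster_species(
    points: ArrayLike, delta: float, weights: ArrayLike | None = None
) -> ClusterReport:
    """Single-linkage species clustering cut at ``delta``.

    Clusters are connected components of the graph with an edge wherever the
    Euclidean distance between two points is strictly below ``delta``.
    Centroids are (optionally weighted) cluster means.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    pts = np.atleast_2d(np.asarray(points, float))
    n = len(pts)
    if n == 0 or pts.size == 0:
        return ClusterReport(np.empty(0, np.int64), 0, np.empty((0, pts.shape[1] if pts.ndim == 2 else 0)), delta)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=delta, output_type="ndarray")
    if pairs.size:
        dist = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[dist < delta]  # strict inequality
    if pairs.size:
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        count, labels = connected_components(g, directed=False)
    else:
        count, labels = n, np.arange(n)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    centroids = np.empty((count, pts.shape[1]))
    for c in range(count):
        mask = labels == c
        centroids[c] = np.average(pts[mask], axis=0, weights=w[mask])
    # order clusters by first occurrence for stable labelling
    order = np.argsort([np.argmax(labels == c) for c in range(count)])
    remap = np.empty(count, np.int64)
    remap[order] = np.arange(count)
    return ClusterReport(remap[labels].astype(np.int64), count, centroids[order], delta)


def diversity_timeseries(
    trajectory, delta: float, window: int = 200
) -> pd.DataFrame:
    """Cluster counts per snapshot plus a trailing rolling-median smoothing.

    ``trajectory`` is any iterable of ``(time, points)`` pairs, or an object
    with a ``snapshots`` attribute of such pairs (points may be a Community,
    in which case its phenotypes are used).
    """
    snaps = getattr(trajectory, "snapshots", trajectory)
    times, counts = [], []
    for t, obj in snaps:
        pts = getattr(obj, "phenotypes", obj)
        times.append(t)
        counts.append(cluster_species(pts, delta).count if len(pts) else 0)
    counts_s = pd.Series(counts, dtype=float)
    smoothed = counts_s.rolling(window, min_periods=1).median()
    return pd.DataFrame(
        {"time": times, "count": counts, "smoothed": smoothed.to_numpy()}
    )


def fitness_landscape(
    community: Community,
    params: ModelParams,
    extent: tuple[float, float] = (-2.0, 2.0),
    n: int = 101,
) -> dict:
    """Invasion-fitness surface over a square grid in trait space.

    Returns a dict with ``x``, ``y``, ``fitness`` (n x n, row = y index),
    ``max`` and ``argmax`` (phenotype of the maximising node).
    """
    x = np.linspace(extent[0], extent[1], n)
    y = np.linspace(extent[0], extent[1], n)
    xx, yy = np.meshgrid(x, y)
    grid = np.stack([xx, yy], axis=-1)
    f = invasion_fitness_community(community, grid, params)
    imax = np.unravel_index(np.argmax(f), f.shape)
    return {
        "x": x,
        "y": y,
        "fitness": f,
        "max": float(f[imax]),
        "argmax": grid[imax],
    }


def _link_tracks(
    centroid_seq: list[NDArray], max_jump: float | None
) -> tuple[list[NDArray], bool]:
    """Greedy nearest-neighbour identity linking of centroids across snapshots.

    Returns (tracks, ok); each track is a (T, d) array.  Linking fails (ok
    False) when cluster counts change or a centroid jumps beyond ``max_jump``.
    """
    counts = {len(c) for c in centroid_seq}
    if len(counts) != 1:
        return [], False
    m = counts.pop()
    tracks = [centroid_seq[0]]
    for nxt in centroid_seq[1:]:
        prev = tracks[-1]
        dist = cdist(prev, nxt)
        assign = np.full(m, -1)
        used = np.zeros(m, bool)
        for _ in range(m):
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            assign[i] = j
            used[j] = True
            dist[i, :] = np.inf
            dist[:, j] = np.inf
        tracks.append(nxt[assign])
    arr = np.stack(tracks)  # (T, m, d)
    if max_jump is not None:
        jumps = np.linalg.norm(np.diff(arr, axis=0), axis=-1)
        if jumps.size and np.max(jumps) > max_jump:
            return [], False
    return [arr[:, i, :] for i in range(m)], True


def detect_limit_cycle(
    snapshots,
    delta: float = DEFAULT_AD_DELTA,
    min_revolutions: float = 1.5,
    monotone_fraction: float = 0.75,
    max_jump_factor: float = 3.0,
) -> CycleReport:
    """Detect Red Queen limit cycles in a trajectory window.

    Clusters every snapshot, links cluster centroids through time by greedy
    nearest-neighbour matching, and computes each track's winding angle about
    its own time-averaged position.  A track is cyclic when the winding is
    near-monotone and completes at least ``min_revolutions`` turns and its
    displacement autocorrelation shows a repeated peak; the period is the
    mean peak spacing.  Direction follows the winding sign (clockwise =
    negative winding in the (z1, z2) plane).
    """
    snaps = getattr(snapshots, "snapshots", snapshots)
    times = np.array([t for t, _ in snaps], float)
    centroid_seq = []
    for _, obj in snaps:
        pts = getattr(obj, "phenotypes", obj)
        centroid_seq.append(cluster_species(pts, delta).centroids)
    if len(centroid_seq) < 8:
        return CycleReport(False, None, "none", np.empty(0))
    disp = [
        np.median(np.linalg.norm(np.diff(np.sort(c, axis=0), axis=0), axis=-1))
        for c in centroid_seq
        if len(c) > 1
    ]
    med_step = np.median(
        [
            np.linalg.norm(b.mean(0) - a.mean(0))
            for a, b in zip(centroid_seq[:-1], centroid_seq[1:])
        ]
    )
    max_jump = max_jump_factor * max(med_step, 1e-6) + (np.median(disp) if disp else 0.0)
    tracks, ok = _link_tracks(centroid_seq, max_jump=max_jump)
    if not ok:
        return CycleReport(False, None, "mixed", np.empty(0))
    windings, periods, amplitudes, cyclic_flags = [], [], [], []
    dt = np.median(np.diff(times)) if len(times) > 1 else 1.0
    for tr in tracks:
        center = tr.mean(axis=0)
        rel = tr - center
        radius = np.linalg.norm(rel, axis=1)
        amplitudes.append(float(radius.mean()))
        if radius.mean() < delta:  # effectively stationary track
            windings.append(0.0)
            cyclic_flags.append(False)
            continue
        theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        dtheta = np.diff(theta)
        total = theta[-1] - theta[0]
        windings.append(float(total / (2 * np.pi)))
        if abs(total) < min_revolutions * 2 * np.pi:
            cyclic_flags.append(False)
            continue
        frac = np.mean(np.sign(dtheta) == np.sign(total)) if dtheta.size else 0.0
        if frac < monotone_fraction:
            cyclic_flags.append(False)
            continue
        # period from the autocorrelation of the x-displacement about center
        sig = rel[:, 0] - rel[:, 0].mean()
        ac = np.correlate(sig, sig, mode="full")[len(sig) - 1 :]
        # unbiased estimate: undo the triangular overlap envelope, which
        # otherwise drags peaks toward smaller lags
        ac = ac[: max(3, int(0.8 * len(sig)))]
        ac = ac / (len(sig) - np.arange(len(ac)))
        peaks, _ = find_peaks(ac)
        if peaks.size == 0:
            cyclic_flags.append(False)
            continue
        # sub-sample refinement: parabola through the peak and its neighbours
        refined = []
        for pk in peaks:
            if 0 < pk < len(ac) - 1:
                denom = ac[pk - 1] - 2 * ac[pk] + ac[pk + 1]
                shift = 0.5 * (ac[pk - 1] - ac[pk + 1]) / denom if denom != 0 else 0.0
                refined.append(pk + float(np.clip(shift, -0.5, 0.5)))
            else:
                refined.append(float(pk))
        lags = np.concatenate([[0.0], refined])
        spacing = np.diff(lags)
        periods.append(float(np.mean(spacing) * dt))
        cyclic_flags.append(True)
    amplitudes = np.asarray(amplitudes)
    windings_arr = np.asarray(windings)
    if not any(cyclic_flags):
        return CycleReport(False, None, "none", amplitudes, windings_arr)
    signs = {np.sign(w) for w, c in zip(windings, cyclic_flags) if c}
    if len(signs) > 1:
        direction = "mixed"
    else:
        direction = "counterclockwise" if signs.pop() > 0 else "clockwise"
    return CycleReport(True, float(np.mean(periods)), direction, amplitudes, windings_arr)


def metastability_probe(
    community: Community,
    perturbation_scale: float,
    params: ModelParams,
    probe_time: float,
    rng: np.random.Generator | None = None,
    reference: list[NDArray] | None = None,
    tolerance: float = 0.05,
    kappa: float = 1.0,
) -> MetastabilityReport:
    """Perturb a putative metastable state and let the canonical flow run.

    Phenotypes receive independent Gaussian offsets of scale
    ``perturbation_scale``; the canonical flow (no mutations) then runs for
    ``probe_time``.  The state "returned" when the Hausdorff distance between
    the final phenotype set and the reference configuration -- minimised over
    the snapshots of ``reference`` for cyclic states -- is below ``tolerance``.
    """
    from nichepack.adaptive_dynamics import canonical_flow

    rng = np.random.default_rng() if rng is None else rng
    ref_states = (
        [np.array(community.phenotypes, float)] if reference is None else reference
    )
    perturbed = community.copy()
    perturbed.phenotypes = perturbed.phenotypes + rng.normal(
        0.0, perturbation_scale, size=perturbed.phenotypes.shape
    )
    n_checks = 20
    trace = np.empty(n_checks)
    state = perturbed
    for i in range(n_checks):
        state, _ = canonical_flow(state, probe_time / n_checks, params, kappa=kappa)
        trace[i] = min(_hausdorff(state.phenotypes, ref) for ref in ref_states)
    return MetastabilityReport(bool(trace[-1] < tolerance), float(trace[-1]), trace, tolerance)


def _hausdorff(a: NDArray, b: NDArray) -> float:
    """Symmetric Hausdorff distance between two point sets."""
    if len(a) == 0 or len(b) == 0:
        return np.inf if len(a) != len(b) else 0.0
    d = cdist(a, b)
    return float(max(d.min(axis=0).max(), d.min(axis=1).max()))
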