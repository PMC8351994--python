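import numpy as np
import pytest
from numpy.testing import assert_allclose

from nichepack.adaptive_dynamics import (
    ADConfig,
    attempt_branch,
    canonical_flow,
    canonical_step,
    merge_close,
    propose_mutant,
    run_ad,
)
from nichepack.ecology import Community, ecological_equilibrium
from nichepack.kernels import ModelParams, carrying_capacity

from conftest import random_community


class TestADConfig:
    def test_gaussian_mode_needs_sigma_ge_eps(self):
        with pytest.raises(ValueError):
            ADConfig(eps_mut=0.05, sigma_mut=0.01)

    def test_merge_must_not_undo_branching(self):
        with pytest.raises(ValueError):
            ADConfig(eps_mut=0.02, delta_merge=0.05)


class TestCanonicalStep:
    def test_ess_unchanged(self, quartic):
        comm = ecological_equilibrium(Community([[0.0, 0.0]], [1.0]), quartic)
        out = canonical_step(comm, 0.5, quartic)
        assert_allclose(out.phenotypes, comm.phenotypes, atol=1e-12)

    def test_monomorphic_moves_toward_origin(self, quartic):
        comm = ecological_equilibrium(Community([[1.0, 1.0]], [0.5]), quartic)
        out, _ = canonical_flow(comm, 2.0, quartic)
        assert np.all(np.abs(out.phenotypes) < 1.0)
        assert np.all(out.phenotypes > 0.0)  # moves along the diagonal, no overshoot

    def test_flow_respects_max_step(self, quartic):
        comm = ecological_equilibrium(Community([[1.5, 1.5]], [0.1]), quartic)
        out = canonical_step(comm, 0.01, quartic)
        assert np.linalg.norm(out.phenotypes - comm.phenotypes) < 0.1


class TestMergeClose:
    def test_identity_when_far(self, rng):
        comm = random_community(rng, 5, min_spacing=0.4)
        out = merge_close(comm, 0.01)
        assert out.size == 5
        assert_allclose(np.sort(out.abundances), np.sort(comm.abundances))

    def test_coincident_merged(self):
        comm = Community([[0.3, 0.3], [0.3, 0.3]], [0.2, 0.3], labels=[7, 9])
        out = merge_close(comm, 0.01)
        assert out.size == 1
        assert out.abundances[0] == pytest.approx(0.5)
        assert out.labels[0] == 7  # smallest label survives

    def test_chain_is_transitive(self):
        # A-B and B-C within delta, A-C beyond: single species
        comm = Community([[0.0, 0.0], [0.008, 0.0], [0.016, 0.0]], [0.1, 0.2, 0.3])
        out = merge_close(comm, 0.01)
        assert out.size == 1

    def test_weighted_mean_and_mass_conservation(self, rng):
        for _ in range(10):
            comm = random_community(rng, 8)
            delta = rng.uniform(0.05, 1.0)
            out = merge_close(comm, delta)
            assert out.abundances.sum() == pytest.approx(comm.abundances.sum(), abs=1e-12)
        comm = Community([[0.0, 0.0], [0.01, 0.0]], [1.0, 3.0])
        out = merge_close(comm, 0.02)
        assert_allclose(out.phenotypes[0], [0.0075, 0.0])

    def test_matches_brute_force_components(self, rng):
        """Transitive closure equals brute-force union-find on all pairs."""
        for _ in range(20):
            m = int(rng.integers(2, 12))
            comm = random_community(rng, m, spread=0.5)
            delta = float(rng.uniform(0.05, 0.6))
            out = merge_close(comm, delta)
            parent = list(range(m))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(m):
                for j in range(i + 1, m):
                    if np.linalg.norm(comm.phenotypes[i] - comm.phenotypes[j]) < delta:
                        parent[find(i)] = find(j)
            n_components = len({find(i) for i in range(m)})
            assert out.size == n_components


class TestProposeMutant:
    def test_fixed_offset_magnitude_exact(self, rng):
        comm = Community([[0.5, -0.5]], [1.0])
        cfg = ADConfig(eps_mut=0.02)
        for _ in range(50):
            _, mutant = propose_mutant(comm, rng, cfg)
            assert np.linalg.norm(mutant - [0.5, -0.5]) == pytest.approx(0.02, rel=1e-12)

    def test_gaussian_offsets_have_right_sd(self, rng):
        comm = Community([[0.0, 0.0]], [1.0])
        cfg = ADConfig(eps_mut=0.02, sigma_mut=0.1)
        offsets = np.array([propose_mutant(comm, rng, cfg)[1] for _ in range(10_000)])
        sd = offsets.std(axis=0)
        assert np.all(np.abs(sd - 0.1) / 0.1 < 0.03)

    def test_single_species_is_parent(self, rng):
        comm = Community([[0.1, 0.2]], [1.0], labels=[42])
        parent, _ = propose_mutant(comm, rng, ADConfig())
        assert parent == 42

    def test_parent_uniform_over_species(self, rng):
        comm = Community([[0.0, 0.0], [1.0, 1.0], [-1.0, 1.0]], [0.1, 0.2, 0.3])
        parents = [propose_mutant(comm, rng, ADConfig())[0] for _ in range(3000)]
        counts = np.bincount(parents, minlength=3)
        assert np.all(np.abs(counts / 3000 - 1 / 3) < 0.05)


class TestAttemptBranch:
    def test_identical_mutant_rejected(self, quartic, rng):
        comm = random_community(rng, 3, params=quartic, equilibrate=True, min_spacing=0.4)
        out, accepted = attempt_branch(comm, 0, comm.phenotypes[0].copy(), quartic)
        assert not accepted
        assert out.size == comm.size

    def test_origin_fitness_minimum_admits_neighbors(self, quartic):
        comm = ecological_equilibrium(Community([[0.0, 0.0]], [1.0]), quartic)
        out, accepted = attempt_branch(comm, 0, np.array([0.02, 0.0]), quartic)
        assert accepted
        assert out.size == 2

    def test_negative_basin_rejected(self, quartic):
        comm = ecological_equilibrium(Community([[0.0, 0.0]], [1.0]), quartic)
        # very close to the resident but not at a fitness minimum gap: far
        # outside viable space the fitness is deeply negative
        out, accepted = attempt_branch(comm, 0, np.array([3.0, 3.0]), quartic)
        assert not accepted


class TestRunAD:
    def test_determinism_bit_identical(self, asymmetric):
        cfg = ADConfig(seed=77, n_attempts=60, initial_n=3, snapshot_every=10)
        t1 = run_ad(asymmetric, cfg)
        t2 = run_ad(asymmetric, cfg)
        assert t1.events == t2.events
        assert_allclose(t1.final.phenotypes, t2.final.phenotypes, rtol=0, atol=0)
        assert_allclose(t1.final.abundances, t2.final.abundances, rtol=0, atol=0)

    def test_snapshot_times_strictly_increasing(self, quartic):
        cfg = ADConfig(seed=3, n_attempts=80, snapshot_every=10)
        traj = run_ad(quartic, cfg)
        times = np.array([t for t, _ in traj.snapshots])
        assert np.all(np.diff(times) > 0)

    def test_snapshots_respect_min_viable_and_residual(self, quartic):
        from nichepack.ecology import interaction_matrix

        cfg = ADConfig(seed=5, n_attempts=120, snapshot_every=30)
        traj = run_ad(quartic, cfg)
        for _, comm in traj.snapshots[1:]:
            assert np.all(comm.abundances >= cfg.min_viable * 0.999)
            a = interaction_matrix(comm, quartic)
            k = carrying_capacity(comm.phenotypes, quartic)
            resid = np.abs(1.0 - (a @ comm.abundances) / k)
            assert resid.max() < 1e-7

    def test_events_reference_known_labels(self, quartic):
        cfg = ADConfig(seed=11, n_attempts=150)
        traj = run_ad(quartic, cfg)
        assert all(kind in ("branch", "extinction", "merge") for _, kind, _ in traj.events)
        branch_children = [labels[1] for _, kind, labels in traj.events if kind == "branch"]
        assert len(branch_children) == len(set(branch_children))

    def test_initial_seeding_inside_box(self, quartic):
        cfg = ADConfig(seed=2, n_attempts=1, initial_n=40)
        traj = run_ad(quartic, cfg)
        z0 = traj.snapshots[0][1].phenotypes
        # survivors of the first equilibration all came from the box
        assert np.all(z0 >= -2.0) and np.all(z0 <= 2.0)
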