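import numpy as np
import pytest

from sbskit.profiles import BindingProfile
from sbskit.simulate import (
    BinderSpec,
    SimulationBlowupError,
    SimulationParams,
    Conformation,
    build_initial_compact,
    build_initial_ordered,
    build_initial_saw,
    equilibrium_bond_length,
    ordered_binder_capacity,
    potential_energy,
    read_xyz,
    run_ensemble,
    simulate_trajectory,
    write_xyz,
)


def homopolymer(n):
    return BindingProfile(np.ones((1, n), dtype=np.int64))


def bare_chain(n):
    return BindingProfile(np.zeros((1, n), dtype=np.int64))


class TestInitialStructures:
    def test_single_bead_at_box_centre(self):
        c = build_initial_saw(bare_chain(1), seed=0)
        assert c.n_beads == 1 and np.isfinite(c.bead_positions).all()

    def test_saw_determinism(self):
        a = build_initial_saw(bare_chain(50), seed=4)
        b = build_initial_saw(bare_chain(50), seed=4)
        assert np.array_equal(a.bead_positions, b.bead_positions)

    def test_saw_excluded_volume_brute_force(self):
        c = build_initial_saw(bare_chain(50), seed=1)
        pos = c.bead_positions
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        iu = np.triu_indices(50, k=2)  # non-consecutive pairs
        assert d[iu].min() >= 0.8
        bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.allclose(bonds, 1.0, atol=1e-9)

    @pytest.mark.parametrize("builder", [build_initial_compact, build_initial_ordered])
    def test_compact_builders_respect_bond_limits(self, builder):
        prof = homopolymer(64)
        binders = BinderSpec(np.array([ordered_binder_capacity(64)]), np.array([4.0]))
        c = builder(prof, seed=0, binders=binders)
        assert c.bond_lengths().max() < 1.4
        assert c.n_binders == binders.n_binders

    def test_binder_placement_fails_in_tiny_box(self):
        binders = BinderSpec(np.array([300]), np.array([1.0]))
        with pytest.raises(RuntimeError, match="box_side"):
            build_initial_saw(bare_chain(5), seed=0, binders=binders, box_side=4.0)


class TestDynamics:
    def test_zero_temperature_rest_geometry_is_stationary(self):
        """Two beads at the force-free bond length under T=0 dynamics stay put."""
        r0 = equilibrium_bond_length()
        prof = bare_chain(2)
        start = Conformation(
            np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]]) + 10.0,
            np.zeros((0, 3)),
            np.zeros(0, dtype=int),
            box_side=20.0,
        )
        params = SimulationParams(n_steps=100, save_stride=10, temperature=0.0, seed=0)
        traj = simulate_trajectory(start, prof, BinderSpec.none(1), params)
        drift = np.abs(traj.bead_frames[-1] - traj.bead_frames[0]).max()
        assert drift < 1e-9

    def test_same_seed_bitwise_identical(self):
        prof = homopolymer(20)
        binders = BinderSpec(np.array([10]), np.array([2.0]))
        runs = []
        for _ in range(2):
            start = build_initial_saw(prof, seed=5, binders=binders)
            params = SimulationParams(n_steps=2000, save_stride=200, seed=5)
            runs.append(simulate_trajectory(start, prof, binders, params))
        assert np.array_equal(runs[0].bead_frames, runs[1].bead_frames)
        assert np.array_equal(runs[0].binder_frames, runs[1].binder_frames)

    def test_bond_invariant_on_every_saved_frame(self):
        prof = homopolymer(32)
        binders = BinderSpec(np.array([16]), np.array([4.0]))
        start = build_initial_saw(prof, seed=2, binders=binders)
        traj = simulate_trajectory(start, prof, binders, SimulationParams(n_steps=5000, save_stride=250, seed=2))
        for f in range(traj.n_frames):
            bonds = np.linalg.norm(np.diff(traj.bead_frames[f], axis=0), axis=1)
            assert bonds.max() < 1.5

    def test_blowup_reports_step_and_advises_timestep(self):
        prof = bare_chain(16)
        start = build_initial_saw(prof, seed=0)
        params = SimulationParams(timestep=0.2, n_steps=5000, save_stride=100, seed=0)
        with pytest.raises(SimulationBlowupError, match="smaller timestep"):
            simulate_trajectory(start, prof, params=params, binders=BinderSpec.none(1))

    def test_energy_terms_finite_on_saved_frames(self):
        prof = homopolymer(24)
        binders = BinderSpec(np.array([12]), np.array([3.0]))
        start = build_initial_saw(prof, seed=3, binders=binders)
        traj = simulate_trajectory(start, prof, binders, SimulationParams(n_steps=3000, save_stride=500, seed=3))
        for f in (0, traj.n_frames - 1):
            energies = potential_energy(traj.frame(f), prof, binders)
            assert all(np.isfinite(v) for v in energies.values())


class TestEnsembles:
    def test_replicas_differ_and_match_seed_order(self):
        prof = bare_chain(24)
        params = SimulationParams(n_steps=2000, save_stride=500)
        t12 = run_ensemble(prof, BinderSpec.none(1), params, 2, [1, 2])
        t21 = run_ensemble(prof, BinderSpec.none(1), params, 2, [2, 1])
        assert not np.array_equal(t12[0].bead_frames[-1], t12[1].bead_frames[-1])
        # permutation equivariance: swapping seeds swaps outputs
        assert np.array_equal(t12[0].bead_frames, t21[1].bead_frames)
        assert np.array_equal(t12[1].bead_frames, t21[0].bead_frames)

    def test_single_replica_reproduces_direct_call(self):
        prof = bare_chain(16)
        params = SimulationParams(n_steps=1000, save_stride=250, seed=7)
        [ens] = run_ensemble(prof, BinderSpec.none(1), params, 1, [7])
        start = build_initial_saw(prof, seed=7, binders=BinderSpec.none(1), box_side=params.box_side)
        direct = simulate_trajectory(start, prof, BinderSpec.none(1), params)
        assert np.array_equal(ens.bead_frames, direct.bead_frames)

    def test_duplicate_seeds_rejected(self):
        prof = bare_chain(8)
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            run_ensemble(prof, BinderSpec.none(1), SimulationParams(n_steps=10), 2, [3, 3])


class TestSpecsAndIO:
    def test_binder_spec_validation(self):
        with pytest.raises(ValueError):
            BinderSpec(np.array([5]), np.array([-1.0]))
        with pytest.raises(ValueError):
            BinderSpec(np.array([5]), np.array([1.0]), interaction_range=0.9)
        with pytest.raises(ValueError):
            BinderSpec(np.array([5, 2]), np.array([1.0]))

    def test_xyz_roundtrip(self, tmp_path):
        prof = homopolymer(10)
        binders = BinderSpec(np.array([4]), np.array([2.0]))
        start = build_initial_saw(prof, seed=1, binders=binders)
        traj = simulate_trajectory(start, prof, binders, SimulationParams(n_steps=1000, save_stride=500, seed=1))
        path = tmp_path / "traj.xyz"
        write_xyz(traj, path)
        back = read_xyz(path)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.bead_frames, traj.bead_frames, atol=1e-4)
        assert np.array_equal(back.binder_types, traj.binder_types)
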