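import numpy as np
import pytest

from sbskit.contacts import ContactMap
from sbskit.observables import (
    classify_phase,
    contact_map_from_ensemble,
    contact_curve_slope,
    fit_scaling_exponent,
    gyration_radius,
    internal_distance_exponent,
    is_equilibrated,
    rg_series,
    steinhardt_q6,
)
from sbskit.profiles import BindingProfile
from sbskit.simulate import (
    BinderSpec,
    SimulationParams,
    Trajectory,
    build_initial_saw,
    simulate_trajectory,
)
from sbskit.contacts import ContactCurve


def make_trajectory(frames, times=None):
    frames = np.asarray(frames, dtype=float)
    n_frames = frames.shape[0]
    return Trajectory(
        times=np.arange(n_frames, dtype=float) if times is None else np.asarray(times, float),
        bead_frames=frames,
        binder_frames=np.zeros((n_frames, 0, 3)),
        binder_types=np.zeros(0, dtype=int),
        box_side=1e6,
    )


class TestGyrationRadius:
    def test_single_bead_is_zero(self):
        assert gyration_radius(np.zeros((1, 3))) == 0.0

    def test_two_beads_give_half_distance(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert gyration_radius(pos) == pytest.approx(1.5)

    def test_three_collinear_beads(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        assert gyration_radius(pos) == pytest.approx(np.sqrt(2.0 / 3.0))


class TestContactMapFromEnsemble:
    def test_collinear_frame_contacts(self):
        pos = np.array([[[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]])
        cmap = contact_map_from_ensemble([make_trajectory(pos)], threshold=1.1, discard_fraction=0.0)
        expected = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        assert np.array_equal(cmap.matrix, expected)

    def test_infinite_threshold_saturates(self, rng):
        pos = rng.random((3, 7, 3)) * 5
        cmap = contact_map_from_ensemble([make_trajectory(pos)], threshold=1e9, discard_fraction=0.0)
        assert np.all(cmap.matrix == 1.0)

    def test_matches_double_loop_counting_oracle(self, rng):
        frames = rng.random((6, 20, 3)) * 4
        threshold = 1.7
        cmap = contact_map_from_ensemble([make_trajectory(frames)], threshold=threshold, discard_fraction=0.0)
        n = 20
        expected = np.zeros((n, n))
        for f in range(6):
            for i in range(n):
                for j in range(n):
                    d = np.sqrt(np.sum((frames[f, i] - frames[f, j]) ** 2))
                    expected[i, j] += 1.0 if d <= threshold else 0.0
        expected /= 6
        np.fill_diagonal(expected, 1.0)
        assert np.array_equal(cmap.matrix, expected)

    def test_symmetry_by_construction(self, rng):
        frames = rng.random((4, 15, 3)) * 3
        cmap = contact_map_from_ensemble([make_trajectory(frames)], discard_fraction=0.25)
        assert np.array_equal(cmap.matrix, cmap.matrix.T)

    def test_empty_after_discard_rejected(self):
        pos = np.zeros((1, 3, 3))
        with pytest.raises(ValueError):
            contact_map_from_ensemble([make_trajectory(pos)], discard_fraction=0.99)


class TestScalingHelpers:
    def test_fit_scaling_exponent_recovers_power_law(self):
        n = np.array([16, 32, 64, 128])
        rg = 0.5 * n**0.61
        nu, logpre = fit_scaling_exponent(n, rg)
        assert nu == pytest.approx(0.61, abs=1e-12)
        assert np.exp(logpre) == pytest.approx(0.5)

    def test_contact_slope_recovers_power_law(self):
        s = np.arange(1.0, 65.0)
        curve = ContactCurve(s, 0.8 * s**-2.1)
        assert contact_curve_slope(curve, 2, 32) == pytest.approx(-2.1, abs=1e-9)

    def test_internal_exponent_on_straight_chain_is_one(self):
        pos = np.zeros((2, 64, 3))
        pos[:, :, 0] = np.arange(64)
        traj = make_trajectory(pos)
        assert internal_distance_exponent(traj, discard_fraction=0.0) == pytest.approx(1.0, abs=1e-9)


class TestEquilibration:
    def test_stationary_noise_is_equilibrated(self, rng):
        n = 30
        base = build_initial_saw(BindingProfile(np.zeros((1, 20), dtype=int)), seed=0).bead_positions
        frames = base[None] + rng.normal(0, 0.01, size=(n, 20, 3))
        assert is_equilibrated(make_trajectory(frames))

    def test_monotone_collapse_is_not_equilibrated(self):
        base = build_initial_saw(BindingProfile(np.zeros((1, 20), dtype=int)), seed=0).bead_positions
        frames = np.array([base * (1.0 - 0.025 * k) for k in range(30)])
        assert not is_equilibrated(make_trajectory(frames))


class TestPhaseClassification:
    def test_coil_label_without_binders(self):
        prof = BindingProfile(np.zeros((1, 48), dtype=int))
        start = build_initial_saw(prof, seed=11)
        traj = simulate_trajectory(
            start, prof, BinderSpec.none(1), SimulationParams(n_steps=40000, save_stride=500, seed=11)
        )
        label = classify_phase(traj, BinderSpec.none(1))
        assert label.label == "coil"
        assert label.nu_estimate > 0.5
        assert label.binder_order_parameter == 0.0

    def test_q6_high_on_fcc_crystal_low_on_random_gas(self):
        """The order parameter itself: fcc packing scores far above a random
        arrangement of the same density."""
        # build a small fcc lattice of "binders" around one "bead"
        a = 2**(1.0 / 6.0) * np.sqrt(2)  # fcc lattice constant with nn at the 12-6 minimum
        cells = range(3)
        base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        pts = np.array([(base + [i, j, k]) * a for i in cells for j in cells for k in cells]).reshape(-1, 3)
        binder_pos = pts
        bead_pos = pts[:1] + [0.0, 0.0, 2**(1.0 / 6.0)]
        binders = BinderSpec(np.array([len(binder_pos)]), np.array([5.0]))
        conf_fcc = type("C", (), {})
        from sbskit.simulate import Conformation

        conf = Conformation(bead_pos, binder_pos, np.zeros(len(binder_pos), dtype=int), box_side=1e3)
        q6_fcc = steinhardt_q6(conf, binders)
        rng = np.random.default_rng(0)
        conf_rand = Conformation(
            bead_pos, rng.random((len(binder_pos), 3)) * a * 3, np.zeros(len(binder_pos), dtype=int), box_side=1e3
        )
        q6_rand = steinhardt_q6(conf_rand, binders)
        # finite-cluster surfaces depress q6-bar below the bulk fcc value
        assert q6_fcc > 0.45
        assert q6_rand < 0.35
        assert q6_fcc > 2 * q6_rand
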