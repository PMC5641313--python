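import numpy as np
import pytest

from sbskit.contacts import ContactMap
from sbskit.inference import (
    AnnealParams,
    BindingDomainAnnealer,
    ForwardParams,
    forward_contact_model,
    infer_binding_profile,
    inference_cost,
    jaccard_per_type,
    match_types,
)
from sbskit.profiles import BindingProfile, make_block_profile


class TestForwardModel:
    def test_zero_profile_is_pure_backbone(self):
        p = BindingProfile(np.zeros((1, 12), dtype=int))
        m = forward_contact_model(p, ForwardParams(decay_exponent=1.5, enrichment=1.0, saturation=5.0)).matrix
        s = np.abs(np.subtract.outer(np.arange(12), np.arange(12))).astype(float)
        with np.errstate(divide="ignore"):
            expected = s**-1.5
        np.fill_diagonal(expected, 1.0)
        assert np.allclose(m, expected)

    def test_shared_type_doubles_backbone(self):
        p = BindingProfile(np.array([[1, 0, 0, 0, 1]]))
        m = forward_contact_model(p, ForwardParams(1.0, 1.0, 10.0)).matrix
        assert m[0, 4] == pytest.approx(2.0 * 4.0**-1.0)

    def test_four_bead_two_block_matrix_matches_hand_oracle(self):
        p = BindingProfile(np.array([[1, 1, 0, 0], [0, 0, 1, 1]]))
        m = forward_contact_model(p, ForwardParams(1.0, 1.0, 10.0)).matrix
        # hand evaluation of min(10, s^-1 (1 + overlap)) at the six pairs
        expected = np.array(
            [
                [1.0, 1 * 2, 0.5 * 1, (1 / 3) * 1],
                [2.0, 1.0, 1 * 1, 0.5 * 1],
                [0.5, 1.0, 1.0, 1 * 2],
                [1 / 3, 0.5, 2.0, 1.0],
            ]
        )
        assert np.allclose(m, expected)

    def test_saturation_caps_entries(self):
        p = BindingProfile(np.array([[3, 3]]))
        m = forward_contact_model(p, ForwardParams(1.0, 1.0, 1.0)).matrix
        assert m[0, 1] == 1.0  # would be 10x backbone without the cap


class TestInferenceCost:
    def test_identical_maps_zero_cost(self, toy_block_profile):
        m = forward_contact_model(toy_block_profile, ForwardParams())
        assert inference_cost(m, m, toy_block_profile, 0.0) == 0.0

    def test_penalty_isolated_on_identical_maps(self, toy_block_profile):
        m = forward_contact_model(toy_block_profile, ForwardParams())
        lam = 0.01
        expected = lam * toy_block_profile.abundance.sum() / toy_block_profile.n_beads
        assert inference_cost(m, m, toy_block_profile, lam) == pytest.approx(expected)

    def test_matches_elementwise_oracle(self, rng, toy_block_profile):
        def rand_map(seed):
            r = np.random.default_rng(seed)
            m = r.random((40, 40)) + 0.1
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            return ContactMap(m)

        a, b = rand_map(1), rand_map(2)
        lam = 0.004
        n = 40
        # oracle: scale each to unit off-diagonal mean, mean |diff| off-diagonal
        sa = a.matrix / (np.sum(a.matrix - np.diag(np.diag(a.matrix))) / (n * (n - 1)))
        sb = b.matrix / (np.sum(b.matrix - np.diag(np.diag(b.matrix))) / (n * (n - 1)))
        acc = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    acc += abs(sa[i, j] - sb[i, j])
        expected = acc / (n * (n - 1)) + lam * toy_block_profile.abundance.sum() / n
        assert inference_cost(a, b, toy_block_profile, lam) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self, toy_block_profile):
        a = ContactMap(np.eye(4))
        b = ContactMap(np.eye(5))
        with pytest.raises(ValueError, match="mismatch"):
            inference_cost(a, b, toy_block_profile, 0.0)


class TestAnnealer:
    def test_planted_two_block_recovery(self, toy_block_profile):
        fwd = ForwardParams(1.0, 1.0, 1.0)
        data = forward_contact_model(toy_block_profile, fwd)
        res = infer_binding_profile(
            data, 2, fwd, AnnealParams(n_sweeps=300, n_restarts=3, seed=0)
        )
        assert res.pearson_r >= 0.95
        assert jaccard_per_type(res.profile, toy_block_profile).min() >= 0.9

    def test_single_type_uniform_block(self):
        p = BindingProfile(np.ones((1, 12), dtype=int))
        data = forward_contact_model(p, ForwardParams())
        res = infer_binding_profile(data, 1, ForwardParams(), AnnealParams(n_sweeps=150, n_restarts=1, seed=1))
        assert res.profile.abundance.sum() >= 11  # essentially every bead assigned

    def test_cost_trace_non_increasing(self, toy_block_profile):
        data = forward_contact_model(toy_block_profile, ForwardParams())
        for seed in (0, 1, 2):
            res = infer_binding_profile(
                data, 2, ForwardParams(), AnnealParams(n_sweeps=60, n_restarts=1, seed=seed)
            )
            assert np.all(np.diff(res.cost_trace) <= 1e-12)

    def test_type_permutation_leaves_scores_unchanged(self, toy_block_profile):
        fwd = ForwardParams()
        permuted = BindingProfile(toy_block_profile.abundance[::-1].copy())
        a = forward_contact_model(toy_block_profile, fwd)
        b = forward_contact_model(permuted, fwd)
        assert np.array_equal(a.matrix, b.matrix)

    def test_deterministic_given_seed(self, toy_block_profile):
        data = forward_contact_model(toy_block_profile, ForwardParams())
        r1 = infer_binding_profile(data, 2, ForwardParams(), AnnealParams(n_sweeps=40, n_restarts=2, seed=9))
        r2 = infer_binding_profile(data, 2, ForwardParams(), AnnealParams(n_sweeps=40, n_restarts=2, seed=9))
        assert np.array_equal(r1.profile.abundance, r2.profile.abundance)
        assert r1.final_cost == r2.final_cost

    def test_all_zero_map_rejected(self):
        est = BindingDomainAnnealer(n_types=1)
        with pytest.raises(ValueError, match="all-zero|nothing"):
            est.fit(ContactMap(np.eye(8)))

    def test_sklearn_params_roundtrip(self):
        est = BindingDomainAnnealer(n_types=3, n_sweeps=17)
        params = est.get_params()
        assert params["n_types"] == 3 and params["n_sweeps"] == 17
        est2 = BindingDomainAnnealer(**params)
        assert est2.get_params() == params


class TestTypeMatching:
    def test_hungarian_matching_inverts_known_permutation(self, toy_block_profile):
        permuted = BindingProfile(toy_block_profile.abundance[[1, 0]].copy())
        perm = match_types(permuted, toy_block_profile)
        assert perm.tolist() == [1, 0]
        assert jaccard_per_type(permuted, toy_block_profile).min() == 1.0
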