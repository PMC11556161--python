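"""Symmetry contracts and structural behavior of the score networks."""

import numpy as np
import pytest

from molsde.autodiff import Tensor
from molsde.nets import EGCL, NetworkConfig, ScoreModel, adjacency_powers
from molsde.selftest import equivariance_battery, random_orthogonal, random_state


@pytest.fixture
def egcl():
    return EGCL(in_dim=4, hidden=16, rng=np.random.default_rng(3))


def _random_inputs(rng, n=5, h=4):
    x = rng.standard_normal((1, n, h))
    p = rng.standard_normal((1, n, 3))
    p -= p.mean(axis=1, keepdims=True)
    a = rng.standard_normal((1, n, n))
    a = np.triu(a, 1) + np.triu(a, 1).swapaxes(1, 2)
    mask = np.ones((1, n))
    return x, p, a, mask


class TestEGCL:
    def test_rotation_reflection_equivariance(self, egcl, rng):
        x, p, a, mask = _random_inputs(rng)
        x1, p1 = egcl(x, p, a, mask)
        for reflect in (False, True):
            R = random_orthogonal(np.random.default_rng(7), reflect=reflect)
            x2, p2 = egcl(x, p @ R, a, mask)
            assert np.max(np.abs(x2.data - x1.data)) < 1e-10  # invariant features
            assert np.max(np.abs(p2.data - p1.data @ R)) < 1e-10

    def test_permutation_equivariance(self, egcl, rng):
        x, p, a, mask = _random_inputs(rng, n=4)
        perm = np.array([2, 0, 3, 1])
        x1, p1 = egcl(x, p, a, mask)
        x2, p2 = egcl(x[:, perm], p[:, perm], a[:, perm][:, :, perm], mask)
        assert np.allclose(x2.data, x1.data[:, perm])
        assert np.allclose(p2.data, p1.data[:, perm])

    def test_cosine_feature_geometry(self):
        from molsde.nets import _pair_geometry

        p = Tensor(np.array([[[1.0, 0, 0], [0, 1.0, 0], [2.0, 0, 0]]]))
        _, _, _, cos = _pair_geometry(p, use_cosine=True)
        assert cos.data[0, 0, 1, 0] == pytest.approx(0.0, abs=1e-7)  # orthogonal
        assert cos.data[0, 0, 2, 0] == pytest.approx(1.0, abs=1e-7)  # parallel

    def test_asymmetric_adjacency_rejected(self, egcl, rng):
        x, p, a, mask = _random_inputs(rng)
        a[0, 0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            egcl(x, p, a, mask)

    def test_nan_input_reported_with_layer_index(self, egcl, rng):
        x, p, a, mask = _random_inputs(rng)
        x[0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="layer 3"):
            egcl(x, p, a, mask, layer_index=3)


class TestAdjacencyPowers:
    def test_two_hop_connectivity_on_path_graph(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        powers = adjacency_powers(A, 2)
        a2 = powers[1].data
        # (A^2)_13 = 1 before rescaling; max entry of A^2 is 2 (node 2 degree)
        assert a2[0, 2] == pytest.approx(1.0 / (2.0 + 1e-8))
        assert a2[1, 1] == pytest.approx(2.0 / (2.0 + 1e-8))

    def test_k1_returns_scaled_input(self, rng):
        A = np.abs(np.triu(rng.standard_normal((4, 4)), 1))
        A = A + A.T
        (p1,) = adjacency_powers(A, 1)
        assert np.allclose(p1.data, A / (np.abs(A).max() + 1e-8))

    def test_powers_commute_with_permutation(self, rng):
        A = np.triu(rng.standard_normal((5, 5)), 1)
        A = A + A.T
        perm = np.array([4, 2, 0, 1, 3])
        pows = adjacency_powers(A, 3)
        pows_perm = adjacency_powers(A[perm][:, perm], 3)
        # oracle: explicit matrix multiplication, then permute
        M = np.eye(5)
        for c in range(3):
            M = M @ A
            scale = np.abs(M).max() + 1e-8
            assert np.allclose(pows[c].data, M / scale)
            assert np.allclose(pows_perm[c].data, (M / scale)[perm][:, perm])

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            adjacency_powers(np.zeros((2, 2)), 0)


class TestScoreNetworkContracts:
    def test_full_equivariance_battery(self, small_model):
        errs = equivariance_battery(small_model, n_trials=25, seed=1)
        assert all(v < 1e-5 for v in errs.values()), errs

    def test_score_p_output_is_com_free(self, small_model, rng):
        state = random_state(rng, n_atoms=6)
        scores = small_model(state)
        assert np.max(np.abs(scores.P.sum(axis=1))) < 1e-9

    def test_score_a_output_symmetric_zero_diagonal(self, small_model, rng):
        state = random_state(rng, n_atoms=5)
        scores = small_model(state)
        assert np.array_equal(scores.A, np.swapaxes(scores.A, 1, 2))
        assert np.all(np.diagonal(scores.A, axis1=1, axis2=2) == 0)

    def test_time_conditioning_is_live(self, small_model, rng):
        state1 = random_state(rng, n_atoms=4, t=0.2)
        state2 = state1.copy()
        state2.t = np.array([0.8])
        s1, s2 = small_model(state1), small_model(state2)
        assert np.max(np.abs(s1.X - s2.X)) > 1e-8
        assert np.max(np.abs(s1.P - s2.P)) > 1e-8
        assert np.max(np.abs(s1.A - s2.A)) > 1e-8

    def test_score_p_rejects_uncentered_coordinates(self, small_model, rng):
        state = random_state(rng, n_atoms=4)
        state.P = state.P + 1.0
        with pytest.raises(ValueError, match="CoM"):
            small_model(state)

    def test_non_equivariant_ablation_fails_battery(self, spec):
        cfg = NetworkConfig(l_h=2, l_r=2, l_a=2, k_power=2, heads=2, hidden=32,
                            use_equivariant=False)
        model = ScoreModel(cfg, k=5, spec=spec, seed=0)
        errs = equivariance_battery(model, n_trials=10, seed=2)
        assert errs["p_equivariance"] > 1e-3

    def test_without_cosine_battery_still_passes(self, spec):
        cfg = NetworkConfig(l_h=2, l_r=2, l_a=2, k_power=2, heads=2, hidden=32,
                            use_cosine=False)
        model = ScoreModel(cfg, k=5, spec=spec, seed=0)
        errs = equivariance_battery(model, n_trials=10, seed=3)
        assert all(v < 1e-5 for v in errs.values())

    def test_fused_variant_shares_one_stack(self, spec, rng):
        cfg = NetworkConfig(l_h=2, l_r=2, l_a=2, k_power=2, heads=2, hidden=32,
                            fused_xp_network=True)
        model = ScoreModel(cfg, k=5, spec=spec, seed=0)
        assert hasattr(model, "fused") and not hasattr(model, "net_x")
        state = random_state(rng, n_atoms=4)
        scores = model(state)
        assert scores.X.shape == state.X.shape
        assert scores.P.shape == state.P.shape
        errs = equivariance_battery(model, n_trials=10, seed=4)
        assert all(v < 1e-5 for v in errs.values())

    def test_masked_nodes_produce_zero_scores(self, small_model, rng):
        state = random_state(rng, n_atoms=6)
        state.mask[0, 4:] = 0.0
        state.X[0, 4:] = 0.0
        state.A[0, 4:, :] = 0.0
        state.A[0, :, 4:] = 0.0
        state.P[0, 4:] = 0.0
        state.P[0, :4] -= state.P[0, :4].mean(axis=0)
        scores = small_model(state)
        assert np.all(scores.X[0, 4:] == 0)
        assert np.all(scores.P[0, 4:] == 0)
        assert np.all(scores.A[0, 4:, :] == 0)


def test_network_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(l_h=0)
    with pytest.raises(ValueError):  # hidden width not divisible by heads
        ScoreModel(NetworkConfig(hidden=30, heads=4), k=5, seed=0)
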