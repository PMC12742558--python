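"""Similarity terms, regularizers and the two training objectives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cptmorph as cm
from cptmorph.core import voxel_to_normalized
from cptmorph.objectives import (
    LossWeights,
    VoxelBatch,
    jacobian_determinants,
    loss_e2e,
    loss_ldd,
    ncc,
    vvf_l2_penalty,
)

from conftest import zero_last_layer


class TestNCC:
    def test_self_correlation_is_one(self):
        a = np.array([1.0, 2.0, 5.0, -3.0])
        assert ncc(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelation_is_minus_one(self):
        a = np.array([1.0, 2.0, 5.0, -3.0])
        assert ncc(a, -a) == pytest.approx(-1.0, abs=1e-6)

    def test_positive_affine_relation(self):
        assert ncc([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.5, 4.0),
        st.floats(-3.0, 3.0),
    )
    def test_invariance_under_positive_affine_transforms(self, seed, slope, offset):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0, 1, 1000)
        assert ncc(a, slope * b + offset) == pytest.approx(ncc(a, b), abs=1e-10)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            ncc([1.0], [2.0])


class TestJacobianDeterminants:
    def test_identity_map(self):
        pts = np.random.default_rng(0).uniform(2, 10, (20, 3))
        np.testing.assert_allclose(jacobian_determinants(lambda p: p, pts), 1.0, rtol=1e-10)

    def test_uniform_scaling(self):
        pts = np.random.default_rng(1).uniform(2, 10, (20, 3))
        det = jacobian_determinants(lambda p: 1.2 * p, pts)
        np.testing.assert_allclose(det, 1.728, rtol=1e-10)

    def test_random_affine_map_matches_matrix_determinant(self):
        rng = np.random.default_rng(2)
        A = rng.normal(0, 1, (3, 3)) + np.eye(3)
        b = rng.normal(0, 5, 3)
        pts = rng.uniform(2, 10, (20, 3))
        det = jacobian_determinants(lambda p: p @ A.T + b, pts, h=1e-3)
        np.testing.assert_allclose(det, np.linalg.det(A), rtol=1e-8)

    def test_finite_difference_agrees_with_exact_network_jacobian(self):
        cfg = cm.SirenConfig(n_hidden_layers=2, width=16, omega0=6.0)
        f = cm.SirenField(cfg, seed=3)
        shape = (24, 24, 24)
        pts = np.random.default_rng(3).uniform(4, 20, (15, 3))

        def net_map(p):
            return p + f.eval_displacement(voxel_to_normalized(p, shape))

        fd = jacobian_determinants(net_map, pts, h=1e-3)
        J_in = f.input_jacobian(voxel_to_normalized(pts, shape))
        dnorm = 2.0 / (np.asarray(shape) - 1.0)
        exact = np.linalg.det(np.eye(3) + J_in * dnorm[None, None, :])
        np.testing.assert_allclose(fd, exact, rtol=1e-4, atol=1e-6)

    def test_nonpositive_h_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinants(lambda p: p, np.zeros((1, 3)), h=0.0)


class TestVVFPenalty:
    def test_zero_velocities(self):
        assert vvf_l2_penalty([np.zeros((10, 3))] * 4) == 0.0

    def test_unit_velocity_sums_over_steps(self):
        v = np.array([[1.0, 0.0, 0.0]])
        assert vvf_l2_penalty([v] * 5) == pytest.approx(5.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(4)
        vs = [rng.normal(size=(8, 3)) for _ in range(3)]
        assert vvf_l2_penalty([2 * v for v in vs]) == pytest.approx(
            4 * vvf_l2_penalty(vs)
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vvf_l2_penalty([])


def _batch_from(vol, n, seed, shape):
    rng = np.random.default_rng(seed)
    ijk = np.stack(
        [rng.integers(0, s, n) for s in shape], axis=-1
    ).astype(float)
    vals = vol.voxels[tuple(ijk.astype(int).T)]
    return VoxelBatch(voxel_to_normalized(ijk, shape), vals)


class TestLossE2E:
    def test_perfect_alignment_gives_minus_one(self, smooth_pair):
        fixed, _ = smooth_pair
        f = zero_last_layer(
            cm.SirenField(cm.SirenConfig(n_hidden_layers=2, width=8, omega0=4.0), seed=0)
        )
        batch = _batch_from(fixed, 200, 0, fixed.shape)
        loss = loss_e2e(f, fixed, fixed, batch, LossWeights(0, 0, 0))
        assert loss == pytest.approx(-1.0, abs=1e-6)

    def test_identity_map_has_zero_folding_penalty(self, smooth_pair):
        fixed, moving = smooth_pair
        f = zero_last_layer(
            cm.SirenField(cm.SirenConfig(n_hidden_layers=2, width=8, omega0=4.0), seed=0)
        )
        batch = _batch_from(fixed, 100, 1, fixed.shape)
        base = loss_e2e(f, fixed, moving, batch, LossWeights(0.0, 0, 0))
        with_jac = loss_e2e(f, fixed, moving, batch, LossWeights(5.0, 0, 0))
        assert with_jac == pytest.approx(base, abs=1e-12)

    def test_gradients_match_finite_differences(self, smooth_pair):
        fixed, moving = smooth_pair
        f = cm.SirenField(cm.SirenConfig(n_hidden_layers=2, width=12, omega0=6.0), seed=5)
        batch = _batch_from(fixed, 60, 2, fixed.shape)
        wts = LossWeights(0.5, 0.0, 1e-3)
        _, grads = loss_e2e(f, fixed, moving, batch, wts, want_grads=True)
        rng = np.random.default_rng(6)
        h = 1e-6
        for i_p in (0, 2, 4, 5):
            flat = f.params[i_p].reshape(-1)
            j = rng.integers(flat.size)
            flat[j] += h
            up = loss_e2e(f, fixed, moving, batch, wts)
            flat[j] -= 2 * h
            down = loss_e2e(f, fixed, moving, batch, wts)
            flat[j] += h
            np.testing.assert_allclose(
                grads[i_p].reshape(-1)[j], (up - down) / (2 * h), rtol=1e-4, atol=1e-8
            )

    def test_rejects_time_dependent_field(self, smooth_pair):
        fixed, moving = smooth_pair
        f = cm.SirenField(
            cm.SirenConfig(n_hidden_layers=1, width=4, time_dependent=True), seed=0
        )
        batch = _batch_from(fixed, 10, 3, fixed.shape)
        with pytest.raises(ValueError):
            loss_e2e(f, fixed, moving, batch)

    def test_a_few_descent_steps_reduce_the_loss(self, smooth_pair):
        fixed, moving = smooth_pair
        f = cm.SirenField(cm.SirenConfig(n_hidden_layers=2, width=16, omega0=6.0), seed=7)
        batch = _batch_from(fixed, 300, 4, fixed.shape)
        wts = LossWeights(0, 0, 0)
        start = loss_e2e(f, fixed, moving, batch, wts)
        for _ in range(30):
            _, grads = loss_e2e(f, fixed, moving, batch, wts, want_grads=True)
            for p, g in zip(f.params, grads):
                p -= 0.01 * g
        assert loss_e2e(f, fixed, moving, batch, wts) < start


class TestLossLDD:
    def _zero_field(self):
        return zero_last_layer(
            cm.SirenField(
                cm.SirenConfig(n_hidden_layers=2, width=8, omega0=4.0, time_dependent=True),
                seed=0,
            )
        )

    def test_perfect_alignment_both_directions(self, smooth_pair):
        fixed, _ = smooth_pair
        f = self._zero_field()
        b1 = _batch_from(fixed, 200, 0, fixed.shape)
        b2 = _batch_from(fixed, 200, 1, fixed.shape)
        loss = loss_ldd(f, fixed, fixed, b1, b2, 4, LossWeights(0, 0, 0))
        assert loss == pytest.approx(-2.0, abs=1e-6)

    def test_zero_field_regularizer_contributes_exactly_zero(self, smooth_pair):
        fixed, moving = smooth_pair
        f = self._zero_field()
        b1 = _batch_from(fixed, 100, 0, fixed.shape)
        b2 = _batch_from(moving, 100, 1, fixed.shape)
        without = loss_ldd(f, fixed, moving, b1, b2, 4, LossWeights(0, 0.0, 0))
        with_reg = loss_ldd(f, fixed, moving, b1, b2, 4, LossWeights(0, 10.0, 0))
        assert with_reg == without

    def test_gradients_match_finite_differences(self, smooth_pair):
        fixed, moving = smooth_pair
        f = cm.SirenField(
            cm.SirenConfig(n_hidden_layers=2, width=12, omega0=6.0, time_dependent=True),
            seed=9,
        )
        b1 = _batch_from(fixed, 50, 2, fixed.shape)
        b2 = _batch_from(moving, 50, 3, fixed.shape)
        wts = LossWeights(0.2, 1e-2, 1e-3)
        _, grads = loss_ldd(f, fixed, moving, b1, b2, 3, wts, want_grads=True)
        rng = np.random.default_rng(10)
        h = 1e-6
        for i_p in (0, 3, 4):
            flat = f.params[i_p].reshape(-1)
            j = rng.integers(flat.size)
            flat[j] += h
            up = loss_ldd(f, fixed, moving, b1, b2, 3, wts)
            flat[j] -= 2 * h
            down = loss_ldd(f, fixed, moving, b1, b2, 3, wts)
            flat[j] += h
            np.testing.assert_allclose(
                grads[i_p].reshape(-1)[j], (up - down) / (2 * h), rtol=1e-4, atol=1e-8
            )

    def test_loss_is_deterministic(self, smooth_pair):
        fixed, moving = smooth_pair
        f = cm.SirenField(
            cm.SirenConfig(n_hidden_layers=2, width=8, omega0=4.0, time_dependent=True),
            seed=1,
        )
        b1 = _batch_from(fixed, 80, 4, fixed.shape)
        b2 = _batch_from(moving, 80, 5, fixed.shape)
        l1 = loss_ldd(f, fixed, moving, b1, b2, 4)
        l2 = loss_ldd(f, fixed, moving, b1, b2, 4)
        assert l1 == l2


class TestLossWeights:
    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda1=-0.1)

    def test_batch_point_bounds_enforced(self):
        with pytest.raises(ValueError):
            VoxelBatch(np.array([[1.5, 0, 0]]), np.array([1.0]))
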