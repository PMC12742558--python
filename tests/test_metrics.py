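"""Evaluation metrics against brute-force and independent-formula oracles."""

import numpy as np
import pytest

import cptmorph as cm
from cptmorph.core import voxel_grid_points
from cptmorph.integration import DenseDVF
from cptmorph.metrics import (
    dice,
    mae,
    ncc_metric,
    neg_jacdet_ratio,
    nmse,
    psnr,
    ssim,
    tre,
    warp_mask,
)


@pytest.fixture
def random_pair():
    rng = np.random.default_rng(0)
    a = cm.ImageVolume(rng.uniform(-1000, 500, (16, 16, 16)))
    b = cm.ImageVolume(a.voxels + rng.normal(0, 50, (16, 16, 16)))
    return a, b


class TestTRE:
    def test_exact_map_gives_zero(self):
        pts = np.random.default_rng(1).uniform(5, 50, (20, 3))
        fixed = cm.LandmarkSet(pts)
        moving = cm.LandmarkSet(pts + 3.0)
        d, mean, sd = tre(fixed, moving, pts + 3.0, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(d, 0.0)
        assert mean == 0.0

    def test_single_voxel_offset_with_anisotropic_spacing(self):
        fixed = cm.LandmarkSet([[10, 10, 10]])
        moving = cm.LandmarkSet([[11, 10, 10]])
        _, mean, _ = tre(fixed, moving, fixed.points, (0.97, 0.97, 2.5))
        assert mean == pytest.approx(0.97)

    def test_matches_per_landmark_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(5, 50, (30, 3))
        mapped = pts + rng.normal(0, 2, (30, 3))
        target = pts + rng.normal(0, 2, (30, 3))
        spacing = np.array([0.8, 1.1, 2.5])
        d, _, _ = tre(cm.LandmarkSet(pts), cm.LandmarkSet(target), mapped, spacing)
        brute = [
            np.sqrt(sum(((mapped[i, k] - target[i, k]) * spacing[k]) ** 2 for k in range(3)))
            for i in range(30)
        ]
        np.testing.assert_allclose(d, brute, rtol=1e-10)

    def test_unpaired_sets_rejected(self):
        with pytest.raises(ValueError):
            tre(cm.LandmarkSet([[0, 0, 0]]), cm.LandmarkSet([[0, 0, 0], [1, 1, 1]]),
                np.zeros((1, 3)), (1, 1, 1))


class TestImageSimilarity:
    def test_mae_trivial_and_offset(self, random_pair):
        a, _ = random_pair
        assert mae(a, a) == 0.0
        b = cm.ImageVolume(a.voxels + 5.0)
        assert mae(a, b) == pytest.approx(5.0)

    def test_mae_matches_direct_sum(self, random_pair):
        a, b = random_pair
        assert mae(a, b) == pytest.approx(np.abs(a.voxels - b.voxels).sum() / a.voxels.size, rel=1e-12)

    def test_mae_respects_mask_and_rejects_empty(self, random_pair):
        a, b = random_pair
        sel = np.zeros(a.shape, bool)
        sel[:4] = True
        m = cm.RegionMask(sel)
        assert mae(a, b, m) == pytest.approx(np.abs(a.voxels - b.voxels)[sel].mean())
        with pytest.raises(ValueError):
            mae(a, b, cm.RegionMask(np.zeros(a.shape, bool)))

    def test_psnr_logarithm_identities(self):
        a = cm.ImageVolume(np.zeros((8, 8, 8)) + 100.0)
        b = cm.ImageVolume(a.voxels + 50.0)  # MSE = peak^2 with peak=50
        assert psnr(a, b, peak=50.0) == pytest.approx(0.0, abs=1e-12)
        c = cm.ImageVolume(a.voxels + 5.0)  # MSE = peak^2/100
        assert psnr(a, c, peak=50.0) == pytest.approx(20.0, abs=1e-12)
        assert psnr(a, a, peak=50.0) == np.inf
        with pytest.raises(ValueError):
            psnr(a, b, peak=0.0)

    def test_identical_inputs_are_perfect(self, random_pair):
        a, _ = random_pair
        assert ssim(a, a) == pytest.approx(1.0)
        assert nmse(a, a) == 0.0
        assert ncc_metric(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_zero_mean_scaling_identities(self):
        rng = np.random.default_rng(3)
        av = rng.normal(0, 100, (12, 12, 12))
        av -= av.mean()
        a, b = cm.ImageVolume(av), cm.ImageVolume(2 * av)
        assert ncc_metric(a, b) == pytest.approx(1.0, abs=1e-9)
        assert nmse(a, b) == pytest.approx(1.0, rel=1e-12)  # sum(av^2)/sum(av^2)

    def test_ssim_matches_independent_gaussian_window_formula(self, random_pair):
        """Oracle: direct transcription of the Gaussian-weighted SSIM formula."""
        from scipy.ndimage import gaussian_filter

        a, b = random_pair
        x, y = a.voxels, b.voxels
        dr = float(x.max() - x.min())
        C1, C2 = (0.01 * dr) ** 2, (0.03 * dr) ** 2
        opts = dict(sigma=1.5, truncate=3.5, mode="nearest")
        mx, my = gaussian_filter(x, **opts), gaussian_filter(y, **opts)
        vx = gaussian_filter(x * x, **opts) - mx * mx
        vy = gaussian_filter(y * y, **opts) - my * my
        cxy = gaussian_filter(x * y, **opts) - mx * my
        smap = ((2 * mx * my + C1) * (2 * cxy + C2)) / (
            (mx * mx + my * my + C1) * (vx + vy + C2)
        )
        pad = 5  # skimage crops the filter radius border before averaging
        oracle = smap[pad:-pad, pad:-pad, pad:-pad].mean()
        assert ssim(a, b, sigma=1.5, data_range=dr) == pytest.approx(oracle, abs=1e-6)

    def test_nmse_reference_convention(self, random_pair):
        a, b = random_pair
        expected = np.sum((a.voxels - b.voxels) ** 2) / np.sum(a.voxels**2)
        assert nmse(a, b) == pytest.approx(expected, rel=1e-12)


class TestDice:
    def test_identical_nonempty(self):
        m = cm.RegionMask(np.random.default_rng(4).uniform(0, 1, (8, 8, 8)) > 0.5)
        assert dice(m, m) == 1.0

    def test_disjoint_and_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        assert dice(cm.RegionMask(a), cm.RegionMask(b)) == 0.0
        a2 = np.zeros((4, 4, 4), bool)
        b2 = np.zeros((4, 4, 4), bool)
        a2.reshape(-1)[:8] = True
        b2.reshape(-1)[4:12] = True
        assert dice(cm.RegionMask(a2), cm.RegionMask(b2)) == 0.5

    def test_both_empty_convention(self):
        e = cm.RegionMask(np.zeros((4, 4, 4), bool))
        assert dice(e, e) == 1.0


class TestNegJacDet:
    def test_zero_dvf(self):
        dvf = DenseDVF(np.zeros((8, 8, 8, 3)), 0.0, 1.0, 4)
        assert neg_jacdet_ratio(dvf) == 0.0

    def test_reflection_is_fully_folded(self):
        shape = (8, 8, 8)
        grid = voxel_grid_points(shape).reshape(*shape, 3)
        dvf = DenseDVF(-2.0 * grid, 0.0, 1.0, 4)  # map x -> -x
        assert neg_jacdet_ratio(dvf) == 100.0

    def test_constant_displacement_invariance(self):
        rng = np.random.default_rng(5)
        vecs = 0.1 * rng.normal(size=(10, 10, 10, 3))
        a = neg_jacdet_ratio(DenseDVF(vecs, 0, 1, 4))
        b = neg_jacdet_ratio(DenseDVF(vecs + np.array([3.0, -2.0, 7.0]), 0, 1, 4))
        assert a == b

    def test_folding_bump_matches_brute_force_count(self):
        """Oracle: per-voxel 3x3 central-difference determinants in loops."""
        shape = (12, 12, 12)
        grid = voxel_grid_points(shape).reshape(*shape, 3)
        c = np.array([5.5, 5.5, 5.5])
        r2 = np.sum((grid - c) ** 2, axis=-1)
        vecs = -2.0 * np.exp(-r2 / 8.0)[..., None] * (grid - c)
        dvf = DenseDVF(vecs, 0, 1, 4)
        mapped = grid + vecs
        count, total = 0, 0
        for i in range(1, 11):
            for j in range(1, 11):
                for k in range(1, 11):
                    J = np.empty((3, 3))
                    J[:, 0] = (mapped[i + 1, j, k] - mapped[i - 1, j, k]) / 2
                    J[:, 1] = (mapped[i, j + 1, k] - mapped[i, j - 1, k]) / 2
                    J[:, 2] = (mapped[i, j, k + 1] - mapped[i, j, k - 1]) / 2
                    count += np.linalg.det(J) <= 0
                    total += 1
        assert count > 0  # the bump does fold
        assert neg_jacdet_ratio(dvf) == pytest.approx(100.0 * count / total, rel=1e-12)

    def test_thin_grid_rejected(self):
        with pytest.raises(ValueError):
            neg_jacdet_ratio(DenseDVF(np.zeros((2, 8, 8, 3)), 0, 1, 4))


class TestWarpMask:
    def _grid(self, shape):
        return voxel_grid_points(shape).reshape(*shape, 3)

    def test_identity_preserves_mask(self):
        m = cm.RegionMask(np.random.default_rng(6).uniform(0, 1, (8, 8, 8)) > 0.6)
        out = warp_mask(m, self._grid((8, 8, 8)))
        np.testing.assert_array_equal(out.voxels, m.voxels)
        assert dice(m, out) == 1.0

    def test_integer_shift_matches_index_shift(self):
        vox = np.zeros((8, 8, 8), bool)
        vox[3:5, 3:5, 3:5] = True
        m = cm.RegionMask(vox)
        mapped = self._grid((8, 8, 8)) + np.array([1.0, 0.0, 0.0])
        out = warp_mask(m, mapped)
        np.testing.assert_array_equal(out.voxels[:-1], m.voxels[1:])

    def test_empty_stays_empty(self):
        m = cm.RegionMask(np.zeros((6, 6, 6), bool))
        out = warp_mask(m, self._grid((6, 6, 6)) + 0.3)
        assert not out.voxels.any()
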