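"""Dice-Sorensen overlap and the voxel-wise bias metric."""

import numpy as np
import pytest

from aphasiamap import (
    GridGeometry,
    TMap,
    bias_map,
    dice_coefficient,
    dsc_bootstrap_ci,
    multivariate_overlap,
)


def _box(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


class TestDice:
    def test_identical_masks_give_one(self):
        m = _box((4, 4, 4), np.s_[1:3, 1:3, 1:3])
        assert dice_coefficient(m, m).dsc == 1.0

    def test_disjoint_masks_give_zero(self):
        a = _box((4, 4, 4), np.s_[0:1, :, :])
        b = _box((4, 4, 4), np.s_[3:4, :, :])
        assert dice_coefficient(a, b).dsc == 0.0

    def test_hand_counted_example(self):
        a = np.zeros((5, 1, 1), bool); a[:2] = True          # |A| = 2
        b = np.zeros((5, 1, 1), bool); b[:3] = True          # |B| = 3, inter = 2
        res = dice_coefficient(a, b)
        assert res.dsc == pytest.approx(0.8)
        assert res.overlap.sum() == 2
        assert res.only_a.sum() == 0 and res.only_b.sum() == 1

    def test_symmetry_and_empty_error(self):
        rng = np.random.default_rng(0)
        a = rng.random((6, 6, 6)) < 0.3
        b = rng.random((6, 6, 6)) < 0.3
        assert dice_coefficient(a, b).dsc == dice_coefficient(b, a).dsc
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((3, 3, 3), bool), np.zeros((3, 3, 3), bool))

    def test_shrinking_intersection_never_raises_dsc(self):
        rng = np.random.default_rng(1)
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        if not (a.any() and b.any() and (a & b).any()):
            pytest.skip("degenerate draw")
        d_full = dice_coefficient(a, b).dsc
        b2 = b.copy()
        inter = np.argwhere(a & b)
        b2[tuple(inter[0])] = False
        if b2.any():
            assert dice_coefficient(a, b2).dsc <= d_full


class TestDscBootstrap:
    def test_identical_masks_ci_collapses(self):
        m = _box((6, 6, 6), np.s_[1:4, 1:4, 1:4])
        with pytest.warns(UserWarning):
            res = dsc_bootstrap_ci(m, m, n_iter=200, seed=0)
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)

    def test_point_estimate_inside_ci_over_random_pairs(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 50:
            a = rng.random((6, 6, 6)) < 0.35
            b = rng.random((6, 6, 6)) < 0.35
            if (a | b).sum() < 8 or not (a.any() and b.any()):
                continue
            res = dsc_bootstrap_ci(a, b, n_iter=200, seed=checked)
            assert res.ci_low - 1e-12 <= res.dsc <= res.ci_high + 1e-12
            checked += 1

    def test_ci_width_close_to_percentile_oracle(self):
        """BCa width within ±20% of a plain percentile bootstrap on
        half-overlapping 200-voxel blocks."""
        shape = (20, 5, 4)
        a = _box(shape, np.s_[0:10, :, :])     # 200 voxels
        b = _box(shape, np.s_[5:15, :, :])     # 200 voxels, 100 shared
        res = dsc_bootstrap_ci(a, b, n_iter=2000, seed=7)
        # percentile-bootstrap oracle over union voxels
        rng = np.random.default_rng(123)
        union = a | b
        ia, ib = a[union].astype(float), b[union].astype(float)
        n = union.sum()
        reps = np.empty(2000)
        for k in range(2000):
            idx = rng.integers(0, n, n)
            sa, sb = ia[idx].sum(), ib[idx].sum()
            reps[k] = 2 * (ia[idx] * ib[idx]).sum() / (sa + sb)
        lo, hi = np.quantile(reps, [0.025, 0.975])
        assert (res.ci_high - res.ci_low) == pytest.approx(hi - lo, rel=0.2)

    def test_tiny_union_rejected(self):
        a = np.zeros((3, 3, 3), bool); a[0, 0, 0] = True
        b = np.zeros((3, 3, 3), bool); b[0, 0, 1] = True
        with pytest.raises(ValueError):
            dsc_bootstrap_ci(a, b, n_iter=200)


class TestMultivariateOverlap:
    def test_four_identical_maps(self):
        m = _box((4, 4, 4), np.s_[1:3, 1:3, 1:3])
        dmat, mean, conj, dropped = multivariate_overlap([m] * 4)
        assert mean == 1.0
        np.testing.assert_array_equal(conj, m)
        assert not dropped

    def test_four_disjoint_maps(self):
        maps = [_box((8, 2, 2), np.s_[i * 2:i * 2 + 2, :, :]) for i in range(4)]
        _, mean, conj, _ = multivariate_overlap(maps)
        assert mean == 0.0 and not conj.any()

    def test_hand_enumerated_three_maps(self):
        shape = (4, 4, 1)
        a = _box(shape, np.s_[0:2, 0:2, :])  # 4 voxels
        b = _box(shape, np.s_[1:3, 0:2, :])  # 4 voxels, |a&b| = 2
        c = _box(shape, np.s_[0:2, 1:3, :])  # 4 voxels, |a&c| = 2, |b&c| = 1
        dmat, mean, conj, _ = multivariate_overlap([a, b, c])
        assert dmat[0, 1] == pytest.approx(0.5)
        assert dmat[0, 2] == pytest.approx(0.5)
        assert dmat[1, 2] == pytest.approx(0.25)
        assert mean == pytest.approx((0.5 + 0.5 + 0.25) / 3)
        assert conj.sum() == 1  # voxel (1,1,0)

    def test_mean_invariant_to_ordering(self):
        rng = np.random.default_rng(3)
        maps = [rng.random((5, 5, 5)) < 0.4 for _ in range(4)]
        _, m1, _, _ = multivariate_overlap(maps)
        _, m2, _, _ = multivariate_overlap(maps[::-1])
        assert m1 == pytest.approx(m2)

    def test_empty_map_excluded_with_warning(self):
        m = _box((4, 4, 4), np.s_[1:3, 1:3, 1:3])
        with pytest.warns(UserWarning, match="empty"):
            _, mean, _, dropped = multivariate_overlap(
                [m, m, np.zeros((4, 4, 4), bool)])
        assert dropped == [2] and mean == 1.0


def _tmap(grid, values):
    return TMap(grid, values, df=57, coverage=np.isfinite(values))


class TestBiasMap:
    def setup_method(self):
        self.grid = GridGeometry.isotropic((4, 4, 4), 2.0)

    def test_identical_maps_zero_bias(self):
        t = np.full(self.grid.shape, np.nan)
        mask = _box(self.grid.shape, np.s_[1:3, 1:3, 1:3])
        t[mask] = np.random.default_rng(0).normal(size=mask.sum()) + 4
        bm = bias_map(_tmap(self.grid, t), mask, _tmap(self.grid, t), mask)
        assert np.allclose(bm.bias[bm.overlap], 0.0)

    def test_swap_negates_bias(self):
        rng = np.random.default_rng(1)
        mask_a = _box(self.grid.shape, np.s_[0:3, :, :])
        mask_b = _box(self.grid.shape, np.s_[1:4, :, :])
        ta = np.where(mask_a, rng.normal(size=self.grid.shape) + 4, np.nan)
        tb = np.where(mask_b, rng.normal(size=self.grid.shape) + 4, np.nan)
        b1 = bias_map(_tmap(self.grid, ta), mask_a, _tmap(self.grid, tb), mask_b)
        b2 = bias_map(_tmap(self.grid, tb), mask_b, _tmap(self.grid, ta), mask_a)
        np.testing.assert_allclose(b1.bias[b1.overlap], -b2.bias[b2.overlap])

    def test_two_voxel_hand_ranks(self):
        mask = np.zeros(self.grid.shape, bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        ta = np.full(self.grid.shape, np.nan); ta[0, 0, 0] = 5.0; ta[0, 0, 1] = 1.0
        tb = np.full(self.grid.shape, np.nan); tb[0, 0, 0] = 1.0; tb[0, 0, 1] = 5.0
        bm = bias_map(_tmap(self.grid, ta), mask, _tmap(self.grid, tb), mask)
        assert bm.bias[0, 0, 0] == pytest.approx(100.0)
        assert bm.bias[0, 0, 1] == pytest.approx(-100.0)
        assert bm.peak_positive_index == (0, 0, 0)
        assert bm.peak_negative_index == (0, 0, 1)

    def test_invariant_to_monotone_transform_of_t(self):
        rng = np.random.default_rng(2)
        mask_a = _box(self.grid.shape, np.s_[0:3, :, :])
        mask_b = _box(self.grid.shape, np.s_[1:4, :, :])
        ta = np.where(mask_a, rng.normal(size=self.grid.shape) + 4, np.nan)
        tb = np.where(mask_b, rng.normal(size=self.grid.shape) + 4, np.nan)
        b1 = bias_map(_tmap(self.grid, ta), mask_a, _tmap(self.grid, tb), mask_b)
        b2 = bias_map(_tmap(self.grid, np.exp(ta / 2)), mask_a,
                      _tmap(self.grid, tb**3), mask_b)
        np.testing.assert_allclose(b1.bias[b1.overlap], b2.bias[b2.overlap])

    def test_constant_t_map_collapses_to_mid_rank(self):
        mask = _box(self.grid.shape, np.s_[0:2, 0:2, 0:2])
        ta = np.where(mask, 3.0, np.nan)
        rng = np.random.default_rng(3)
        tb = np.where(mask, rng.normal(size=self.grid.shape) + 4, np.nan)
        bm = bias_map(_tmap(self.grid, ta), mask, _tmap(self.grid, tb), mask)
        # A contributes 50 everywhere; bias spans [-50, 50]
        assert bm.bias[bm.overlap].max() <= 50.0 + 1e-9
        assert bm.bias[bm.overlap].min() >= -50.0 - 1e-9

    def test_gate_refuses_negligible_overlap(self):
        mask_a = _box(self.grid.shape, np.s_[0:2, 0:1, 0:4])
        mask_b = _box(self.grid.shape, np.s_[1:4, :, :])
        ta = np.where(mask_a, 4.0, np.nan)
        tb = np.where(mask_b, 4.0, np.nan)
        dsc = dice_coefficient(mask_a, mask_b).dsc
        assert dsc < 0.4
        with pytest.raises(ValueError, match="DSC"):
            bias_map(_tmap(self.grid, ta), mask_a, _tmap(self.grid, tb), mask_b)
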