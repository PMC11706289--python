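"""Voxel-wise GLM, cluster formation and permutation correction."""

from collections import deque

import numpy as np
import pytest

from aphasiamap import (
    GridGeometry,
    LesionVolumeImage,
    permutation_cluster_test,
    suprathreshold_clusters,
    voxel_glm_tmap,
)


def flood_fill_oracle(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Brute-force BFS connected components; returns voxel sets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return comps


class TestClusterLabeling:
    def test_face_adjacent_voxels_one_cluster(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = m[1, 1, 2] = True
        labels, sizes = suprathreshold_clusters(m, connectivity=6)
        assert len(sizes) == 1 and sizes[0] == 2

    def test_body_diagonal_depends_on_connectivity(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = m[2, 2, 2] = True
        _, sizes6 = suprathreshold_clusters(m, connectivity=6)
        _, sizes26 = suprathreshold_clusters(m, connectivity=26)
        assert len(sizes6) == 2
        assert len(sizes26) == 1 and sizes26[0] == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_mask_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        m = rng.random((8, 8, 8)) < 0.3
        labels, sizes = suprathreshold_clusters(m, connectivity)
        got = {frozenset(map(tuple, np.argwhere(labels == k)))
               for k in range(1, len(sizes) + 1)}
        assert got == set(flood_fill_oracle(m, connectivity))
        assert np.all(np.diff(sizes) <= 0)  # largest first

    def test_empty_mask(self):
        labels, sizes = suprathreshold_clusters(np.zeros((3, 3, 3), bool))
        assert sizes.size == 0 and labels.max() == 0


def _cohort_arrays(cohort, dimension="Paraphasia", latent=True):
    scores = (cohort.latent_scores if latent else cohort.observed_scores)
    return cohort.smoothed, scores[dimension].to_numpy(), cohort.total_cm3


class TestVoxelGLM:
    def test_planted_voxel_drives_top_t(self, null_cohort):
        """Scores proportional to one voxel's lesion value put the grid's
        maximum t at that voxel."""
        co = null_cohort
        include_any = np.stack([m.data for m in co.smoothed]).sum(0)
        vox = np.unravel_index(np.argmax(include_any), include_any.shape)
        y = 10.0 * np.array([m.data[vox] for m in co.smoothed])
        tmap, supra = voxel_glm_tmap(co.smoothed, y, np.zeros(len(y)))
        assert supra[vox]
        assert tmap.t[vox] == np.nanmax(tmap.t)
        assert tmap.df == len(y) - 3

    def test_negative_effect_not_suprathreshold_one_tailed(self, null_cohort):
        co = null_cohort
        include_any = np.stack([m.data for m in co.smoothed]).sum(0)
        vox = np.unravel_index(np.argmax(include_any), include_any.shape)
        y = -10.0 * np.array([m.data[vox] for m in co.smoothed])
        tmap, supra = voxel_glm_tmap(co.smoothed, y, np.zeros(len(y)))
        assert not supra[vox]
        assert tmap.t[vox] < 0

    def test_null_suprathreshold_fraction_matches_alpha(self, null_cohort):
        co = null_cohort
        rng = np.random.default_rng(0)
        alpha = 0.01
        fracs = []
        for _ in range(50):
            y = rng.normal(size=len(co.masks))
            _, supra = voxel_glm_tmap(co.smoothed, y, co.total_cm3,
                                      alpha_voxel=alpha)
            tmap, _ = voxel_glm_tmap(co.smoothed, y, co.total_cm3)
            fracs.append(supra.sum() / tmap.coverage.sum())
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - alpha) <= 3 * se + 1e-4

    def test_nan_outside_coverage(self, null_cohort):
        co = null_cohort
        tmap, _ = voxel_glm_tmap(*_cohort_arrays(co))
        assert np.isnan(tmap.t[~tmap.coverage]).all()
        assert np.isfinite(tmap.t[tmap.coverage]).all()


class TestPermutationClusterTest:
    def test_fixed_seed_bitwise_reproducible(self, planted_cohort):
        args = _cohort_arrays(planted_cohort)
        r1 = permutation_cluster_test(*args, n_perm=150, seed=5)
        r2 = permutation_cluster_test(*args, n_perm=150, seed=5)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        np.testing.assert_array_equal(r1.labeled, r2.labeled)
        assert [c.corrected_p for c in r1.clusters] == \
               [c.corrected_p for c in r2.clusters]
        assert [c.max_t for c in r1.clusters] == [c.max_t for c in r2.clusters]

    def test_smallest_attainable_p_is_add_one(self, planted_cohort):
        res = permutation_cluster_test(*_cohort_arrays(planted_cohort),
                                       n_perm=999, seed=1)
        assert res.clusters, "planted effect should yield a cluster"
        assert min(c.corrected_p for c in res.clusters) >= 1.0 / 1000
        big = res.clusters[0]
        if (res.null_max_sizes >= big.size_voxels).sum() == 0:
            assert big.corrected_p == pytest.approx(1.0 / 1000)

    def test_planted_cluster_significant_and_in_planted_region(self, planted_cohort):
        co = planted_cohort
        res = permutation_cluster_test(*_cohort_arrays(co), n_perm=500, seed=2)
        sig = [c for c in res.clusters if c.significant]
        assert sig
        main = sig[0]
        members = res.labeled == main.label
        temporal = co.roiset.labels == 3
        assert (members & temporal).sum() / members.sum() > 0.3
        assert main.volume_cm3 == pytest.approx(
            main.size_voxels * co.grid.voxel_volume_cm3)

    def test_cluster_table_internal_consistency(self, planted_cohort):
        res = permutation_cluster_test(*_cohort_arrays(planted_cohort),
                                       n_perm=150, seed=3)
        sizes = [c.size_voxels for c in res.clusters]
        assert sizes == sorted(sizes, reverse=True)
        for c in res.clusters:
            assert 0 < c.corrected_p <= 1
            assert res.tmap.t[c.peak_index] == pytest.approx(c.max_t)
            np.testing.assert_allclose(
                c.peak_mm, res.tmap.grid.voxel_to_world(np.array(c.peak_index)))

    def test_lowering_voxel_alpha_shrinks_suprathreshold_set(self, planted_cohort):
        args = _cohort_arrays(planted_cohort)
        _, supra_loose = voxel_glm_tmap(args[0], args[1], args[2], alpha_voxel=0.01)
        _, supra_tight = voxel_glm_tmap(args[0], args[1], args[2], alpha_voxel=0.001)
        assert not np.any(supra_tight & ~supra_loose)

    def test_corrected_p_invariant_to_participant_relabeling(self, planted_cohort):
        co = planted_cohort
        masks, y, tot = _cohort_arrays(co)
        perm = np.random.default_rng(0).permutation(len(y))
        r1 = permutation_cluster_test(masks, y, tot, n_perm=200, seed=9)
        r2 = permutation_cluster_test([masks[i] for i in perm], y[perm],
                                      tot[perm], n_perm=200, seed=9)
        assert [c.size_voxels for c in r1.clusters] == \
               [c.size_voxels for c in r2.clusters]

    def test_no_suprathreshold_returns_empty_with_null(self, null_cohort):
        co = null_cohort
        y = np.random.default_rng(1).normal(size=len(co.masks))
        res = permutation_cluster_test(co.smoothed, -np.abs(y) * 0 + 1e-9 * y,
                                       co.total_cm3, n_perm=120, seed=4,
                                       alpha_voxel=1e-6)
        assert res.null_max_sizes.shape == (120,)

    def test_freedman_lane_scheme_runs(self, planted_cohort):
        res = permutation_cluster_test(*_cohort_arrays(planted_cohort),
                                       n_perm=120, seed=6, scheme="freedman_lane")
        assert res.clusters
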