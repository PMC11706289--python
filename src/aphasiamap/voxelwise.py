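"""Mass-univariate voxel-wise lesion-symptom mapping with cluster-size
permutation correction.

At every voxel with adequate lesion coverage, the dimension score is
regressed on the voxel's (smoothed) lesion value with total lesion extent
as a controlling covariate. Voxels significant on a one-tailed t-test
(beta > 0, damage worsens the score) at the voxel-level alpha are grouped
into contiguous clusters; family-wise inference compares each observed
cluster's size against the distribution of the maximum cluster size over
permutations in which the behavioural scores are shuffled across
participants (masks and covariate pairing unchanged).

Implementation note: the covariates (intercept + total extent) are
residualized out of both the scores and the voxel regressors once
(Frisch–Waugh), which reduces each permutation to one matrix-vector
product over covered voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .imaging import GridGeometry, LesionVolumeImage, coverage_count

__all__ = [
    "TMap",
    "Cluster",
    "ClusterResult",
    "voxel_glm_tmap",
    "suprathreshold_clusters",
    "permutation_cluster_test",
    "connectivity_structure",
]


@dataclass
class TMap:
    """Voxel-wise t statistics (NaN outside the coverage mask)."""

    grid: GridGeometry
    t: np.ndarray
    df: int
    coverage: np.ndarray


@dataclass
class Cluster:
    label: int
    size_voxels: int
    volume_cm3: float
    max_t: float
    peak_index: tuple[int, int, int]
    peak_mm: np.ndarray
    corrected_p: float
    significant: bool


@dataclass
class ClusterResult:
    labeled: np.ndarray
    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    n_perm: int
    seed: int | None
    tmap: TMap
    alpha_voxel: float
    alpha_cluster: float
    connectivity: int
    n_dropped_zero_variance: int = 0


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D adjacency structure: 6 (faces), 18 (+edges) or 26 (+vertices)."""
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6, 18 or 26")


# ---------------------------------------------------------------------------
# Vectorized per-voxel GLM
# ---------------------------------------------------------------------------

def _stack_masks(masks: list[LesionVolumeImage]) -> tuple[GridGeometry, np.ndarray]:
    grid = masks[0].grid
    for m in masks:
        grid.require_match(m.grid)
    return grid, np.stack([m.data for m in masks])


class _VoxelGLM:
    """Precomputed state for repeated t-map evaluation under permutations."""

    def __init__(
        self,
        masks: list[LesionVolumeImage],
        total_extent: np.ndarray,
        fraction: float,
        binarize_at: float = 0.5,
        binary_regressor: bool = False,
    ):
        grid, data = _stack_masks(masks)
        n = data.shape[0]
        _, include, self.threshold = coverage_count(masks, fraction, binarize_at)
        vox = data.reshape(n, -1)[:, include.ravel()]
        if binary_regressor:
            vox = (vox >= binarize_at).astype(float)
        # covariate block: intercept + total lesion extent
        C = np.column_stack([np.ones(n), np.asarray(total_extent, dtype=float)])
        self.C = C
        self.proj = C @ np.linalg.pinv(C)
        M = vox - self.proj @ vox
        denom = (M ** 2).sum(axis=0)
        keep = denom > 1e-12
        self.n_dropped = int((~keep).sum())
        if self.n_dropped:
            warnings.warn(
                f"{self.n_dropped} covered voxels with zero regressor variance "
                "excluded", stacklevel=3,
            )
        flat_idx = np.flatnonzero(include.ravel())[keep]
        self.include = np.zeros(grid.shape, dtype=bool)
        self.include.ravel()[flat_idx] = True
        self.flat_idx = flat_idx
        self.M = M[:, keep]
        self.denom = denom[keep]
        self.grid = grid
        self.n = n
        self.df = n - 3  # intercept + voxel regressor + total-extent covariate
        if self.df <= 0:
            raise ValueError("need more than 3 participants")

    def tvalues(self, scores: np.ndarray) -> np.ndarray:
        """One-tailed-ready t statistics at the retained voxels."""
        y = np.asarray(scores, dtype=float)
        yr = y - self.proj @ y
        yty = float(yr @ yr)
        u = self.M.T @ yr
        rss = np.maximum(yty - u ** 2 / self.denom, 0.0)
        sigma2 = rss / self.df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (u / self.denom) / np.sqrt(sigma2 / self.denom)
        return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)

    def tmap(self, scores: np.ndarray) -> TMap:
        t3d = np.full(self.grid.shape, np.nan)
        t3d.ravel()[self.flat_idx] = self.tvalues(scores)
        return TMap(self.grid, t3d, self.df, self.include)


def voxel_glm_tmap(
    masks: list[LesionVolumeImage],
    scores: np.ndarray,
    total_extent: np.ndarray,
    alpha_voxel: float = 0.01,
    fraction: float = 0.05,
    binarize_at: float = 0.5,
    binary_regressor: bool = False,
) -> tuple[TMap, np.ndarray]:
    """Voxel-wise OLS t-map and the one-tailed suprathreshold mask.

    At each covered voxel the score is regressed on [intercept, voxel
    lesion value, total lesion extent]; suprathreshold voxels have a
    one-tailed p < ``alpha_voxel`` in the damage-worsens-score (beta > 0)
    direction.
    """
    glm = _VoxelGLM(masks, total_extent, fraction, binarize_at, binary_regressor)
    tmap = glm.tmap(np.asarray(scores, dtype=float))
    t_crit = stats.t.ppf(1.0 - alpha_voxel, glm.df)
    with np.errstate(invalid="ignore"):
        supra = np.nan_to_num(tmap.t, nan=-np.inf) > t_crit
    return tmap, supra


# ---------------------------------------------------------------------------
# Cluster formation
# ---------------------------------------------------------------------------

def suprathreshold_clusters(
    mask: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary mask, deterministically relabelled.

    Returns (labels, sizes): label 1 is the largest cluster; ties broken by
    the lexicographically smallest member voxel index. ``sizes[k]`` is the
    voxel count of label k+1.
    """
    mask = np.asarray(mask).astype(bool)
    raw, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    if n == 0:
        return raw, np.empty(0, dtype=int)
    sizes = np.bincount(raw.ravel())[1:]
    first_idx = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    # first (lexicographically smallest) flat index per raw label
    np.minimum.at(first_idx, flat[nz] - 1, nz)
    order = np.lexsort((first_idx, -sizes))
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[np.asarray(order) + 1] = np.arange(1, n + 1)
    return remap[raw], sizes[order]


def _max_cluster_size(mask: np.ndarray, structure: np.ndarray) -> int:
    raw, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(raw.ravel())[1:].max())


# ---------------------------------------------------------------------------
# Permutation cluster test
# ---------------------------------------------------------------------------

def permutation_cluster_test(
    masks: list[LesionVolumeImage],
    scores: np.ndarray,
    total_extent: np.ndarray,
    alpha_voxel: float = 0.01,
    fraction: float = 0.05,
    connectivity: int = 26,
    n_perm: int = 10_000,
    alpha_cluster: float = 0.05,
    seed: int | None = None,
    binarize_at: float = 0.5,
    binary_regressor: bool = False,
    scheme: str = "shuffle_scores",
) -> ClusterResult:
    """Cluster-size family-wise inference for the voxel-wise lesion GLM.

    The null distribution is the maximum suprathreshold cluster size per
    permutation of the behavioural scores across participants. A cluster's
    corrected p is the add-one estimator (1 + #{null >= observed size}) /
    (1 + n_perm); it is significant iff corrected_p < ``alpha_cluster``
    (clusters in the extreme right tail of the null). ``scheme`` may be
    "shuffle_scores" (plain score shuffling) or "freedman_lane" (shuffle
    covariate-residualized scores and add back the covariate fit).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if scheme not in ("shuffle_scores", "freedman_lane"):
        raise ValueError("scheme must be 'shuffle_scores' or 'freedman_lane'")
    y = np.asarray(scores, dtype=float)
    glm = _VoxelGLM(masks, total_extent, fraction, binarize_at, binary_regressor)
    t_crit = stats.t.ppf(1.0 - alpha_voxel, glm.df)
    structure = connectivity_structure(connectivity)

    def supra_from_t(tvals: np.ndarray) -> np.ndarray:
        m = np.zeros(glm.grid.shape, dtype=bool)
        m.ravel()[glm.flat_idx] = tvals > t_crit
        return m

    obs_t = glm.tvalues(y)
    obs_mask = supra_from_t(obs_t)
    labeled, sizes = suprathreshold_clusters(obs_mask, connectivity)

    rng = np.random.default_rng(seed)
    if scheme == "freedman_lane":
        fitted = glm.proj @ y
        resid = y - fitted
    null_sizes = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(glm.n)
        y_b = y[perm] if scheme == "shuffle_scores" else fitted + resid[perm]
        null_sizes[b] = _max_cluster_size(supra_from_t(glm.tvalues(y_b)), structure)

    tmap = TMap(glm.grid, np.full(glm.grid.shape, np.nan), glm.df, glm.include)
    tmap.t.ravel()[glm.flat_idx] = obs_t

    clusters: list[Cluster] = []
    vv = glm.grid.voxel_volume_cm3
    for k, size in enumerate(sizes, start=1):
        members = np.argwhere(labeled == k)
        t_members = tmap.t[tuple(members.T)]
        peak = members[int(np.argmax(t_members))]
        p_corr = float((1 + (null_sizes >= size).sum()) / (1 + n_perm))
        clusters.append(Cluster(
            label=k,
            size_voxels=int(size),
            volume_cm3=float(size) * vv,
            max_t=float(t_members.max()),
            peak_index=tuple(int(i) for i in peak),
            peak_mm=glm.grid.voxel_to_world(peak),
            corrected_p=p_corr,
            significant=p_corr < alpha_cluster,
        ))
    return ClusterResult(
        labeled=labeled,
        clusters=clusters,
        null_max_sizes=null_sizes,
        n_perm=n_perm,
        seed=seed,
        tmap=tmap,
        alpha_voxel=alpha_voxel,
        alpha_cluster=alpha_cluster,
        connectivity=connectivity,
        n_dropped_zero_variance=glm.n_dropped,
    )
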