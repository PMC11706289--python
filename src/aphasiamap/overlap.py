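"""Spatial overlap and bias analysis of cluster maps.

Pairwise spatial agreement between the significant-cluster maps of two
dimensions is quantified with the Dice-Sorensen coefficient,
DSC = 2|A∩B| / (|A| + |B|), with BCa bootstrap confidence intervals
(resampling voxels of the union); the DSC is interpreted on the same
qualitative bins as the interrater ICC. For pairs with non-negligible
overlap (DSC or its CI reaching 0.4), a voxel-wise bias map contrasts the
two t-maps inside the overlap after each is standardized to 0-100 by
percentile rank within its own significant voxels; bias = A - B, so
values far from zero mark voxels where one dimension's association
dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scoring import agreement_label, bca_ci
from .voxelwise import TMap

__all__ = [
    "OverlapResult",
    "BiasMap",
    "dice_coefficient",
    "dsc_bootstrap_ci",
    "multivariate_overlap",
    "bias_map",
]


@dataclass
class OverlapResult:
    dsc: float
    ci_low: float
    ci_high: float
    overlap: np.ndarray
    only_a: np.ndarray
    only_b: np.ndarray
    label: str


@dataclass
class BiasMap:
    bias: np.ndarray  # in [-100, 100] on the overlap, NaN elsewhere
    overlap: np.ndarray
    peak_positive_index: tuple[int, int, int] | None
    peak_negative_index: tuple[int, int, int] | None


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapResult:
    """Dice-Sorensen coefficient of two binary maps on a common grid."""
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty; DSC undefined")
    inter = np.logical_and(a, b)
    dsc = 2.0 * inter.sum() / (na + nb)
    return OverlapResult(float(dsc), np.nan, np.nan, inter,
                         np.logical_and(a, ~b), np.logical_and(b, ~a),
                         agreement_label(float(dsc)))


def dsc_bootstrap_ci(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    n_iter: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> OverlapResult:
    """DSC with a BCa bootstrap CI, resampling voxels of the union.

    Each replicate draws |A∪B| voxels of the union with replacement and
    recomputes DSC from the resampled membership counts.
    """
    res = dice_coefficient(mask_a, mask_b)
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    union = np.logical_or(a, b)
    n_union = int(union.sum())
    if n_union < 8:
        raise ValueError("union smaller than 8 voxels; resampling is meaningless")
    in_a = a[union].astype(float)
    in_b = b[union].astype(float)
    units = np.column_stack([in_a, in_b])  # per union voxel: (in A, in B)

    def stat(rows: np.ndarray) -> float:
        sa = rows[:, 0].sum()
        sb = rows[:, 1].sum()
        inter = (rows[:, 0] * rows[:, 1]).sum()
        return 2.0 * inter / (sa + sb) if (sa + sb) else 0.0

    lo, hi = bca_ci(stat, units, n_iter=n_iter, level=level, seed=seed)
    res.ci_low, res.ci_high = float(lo), float(hi)
    return res


def multivariate_overlap(
    maps: list[np.ndarray],
    names: list[str] | None = None,
) -> tuple[np.ndarray, float, np.ndarray, list[int]]:
    """Pairwise DSC matrix, mean pairwise DSC and the all-maps conjunction.

    Empty maps are excluded with a warning; their indices are returned so
    callers can annotate output. The mean is over the upper triangle of the
    retained maps' pairwise DSC matrix.
    """
    masks = [_as_bool(m) for m in maps]
    if len(masks) < 2:
        raise ValueError("need at least 2 maps")
    kept, dropped = [], []
    for i, m in enumerate(masks):
        (kept if m.any() else dropped).append(i)
    if dropped:
        nm = [names[i] if names else i for i in dropped]
        warnings.warn(f"empty maps excluded from overlap: {nm}", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("fewer than 2 non-empty maps")
    k = len(masks)
    dmat = np.full((k, k), np.nan)
    pair_values = []
    for ii, i in enumerate(kept):
        dmat[i, i] = 1.0
        for j in kept[ii + 1:]:
            d = dice_coefficient(masks[i], masks[j]).dsc
            dmat[i, j] = dmat[j, i] = d
            pair_values.append(d)
    conj = np.logical_and.reduce([masks[i] for i in kept])
    return dmat, float(np.mean(pair_values)), conj, dropped


# ---------------------------------------------------------------------------
# Voxel-wise bias metric
# ---------------------------------------------------------------------------

def _standardize_0_100(values: np.ndarray, method: str) -> np.ndarray:
    """Map a map's significant-voxel t values to 0-100."""
    if method == "rank":
        if len(values) == 1:
            return np.array([50.0])
        ranks = stats.rankdata(values, method="average")
        return (ranks - 1.0) / (len(values) - 1.0) * 100.0
    if method == "minmax":
        span = values.max() - values.min()
        if span == 0:
            return np.full(len(values), 50.0)
        return (values - values.min()) / span * 100.0
    raise ValueError("method must be 'rank' or 'minmax'")


def bias_map(
    tmap_a: TMap,
    clusters_a: np.ndarray,
    tmap_b: TMap,
    clusters_b: np.ndarray,
    method: str = "rank",
    dsc_gate: float = 0.4,
    precomputed: OverlapResult | None = None,
) -> BiasMap:
    """Voxel-wise bias between two significant-cluster t-maps.

    Within each map's significant voxels, t statistics are standardized to
    0-100 (percentile rank by default; constant maps collapse to 50); the
    bias is standardized(A) - standardized(B) on the overlap only, so
    swapping the arguments negates it. Refuses to run unless the pair shows
    non-negligible overlap (DSC, or its bootstrap CI when supplied via
    ``precomputed``, reaching ``dsc_gate``).
    """
    a, b = _as_bool(clusters_a), _as_bool(clusters_b)
    res = precomputed if precomputed is not None else dice_coefficient(a, b)
    gate_ok = res.dsc >= dsc_gate or (
        np.isfinite(res.ci_high) and res.ci_high >= dsc_gate
    )
    if not gate_ok:
        raise ValueError(
            f"spatial overlap below the bias-map gate (DSC = {res.dsc:.3f} "
            f"< {dsc_gate}); bias analysis not meaningful"
        )
    overlap = np.logical_and(a, b)
    if not overlap.any():
        raise ValueError("overlap is empty")
    out = np.full(a.shape, np.nan)
    std_a = np.full(a.shape, np.nan)
    std_b = np.full(b.shape, np.nan)
    std_a[a] = _standardize_0_100(tmap_a.t[a], method)
    std_b[b] = _standardize_0_100(tmap_b.t[b], method)
    out[overlap] = std_a[overlap] - std_b[overlap]
    members = np.argwhere(overlap)
    vals = out[overlap]
    peak_pos = tuple(int(i) for i in members[int(np.argmax(vals))]) if (vals > 0).any() else None
    peak_neg = tuple(int(i) for i in members[int(np.argmin(vals))]) if (vals < 0).any() else None
    return BiasMap(out, overlap, peak_pos, peak_neg)
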