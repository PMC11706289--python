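"""Synthetic cohort generation.

Generates complete, fully reproducible stand-in cohorts for the analysis
pipeline: a hemisphere-like vascular territory on a toy grid, irregular
lesions grown by random voxel accretion with right-skewed (log-normal)
volumes, four ROIs partitioning the territory, dimension scores driven
linearly by ROI lesion load plus correlated Gaussian noise, ordinal 0-4
feature ratings derived from the latent scores with controllable
interrater agreement, and eligibility attributes.

Everything flows from a single integer seed: two runs with equal configs
are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import (
    GridGeometry,
    LesionVolumeImage,
    ROISet,
    gaussian_smooth,
    mask_volume_cm3,
)
from .scoring import (
    DIMENSIONS,
    EligibilityRecord,
    FeatureDimensionMap,
    RatingProfile,
    default_feature_map,
    dimension_scores,
    eligibility_filter,
    roster_from_exclusion_counts,
)

__all__ = [
    "SimulationConfig",
    "Cohort",
    "territory_mask",
    "default_roiset",
    "simulate_lesions",
    "simulate_behaviour",
    "simulate_ratings",
    "build_cohort",
    "lognormal_params",
]

ROI_NAMES = ("Prefrontal", "Frontoparietal", "Temporal", "Other")

# Default linear lesion-load effects (score points per cm³ of ROI damage),
# qualitatively mirroring the study-scale pattern: paraphasia driven by
# temporal damage, the non-fluency dimensions by frontoparietal damage.
DEFAULT_BETAS = np.array([
    #  Paraphasia  Logopenia  Agrammatism  Motor speech
    [0.0, 0.2, 0.1, 0.0],    # Prefrontal
    [0.6, 1.7, 1.3, 2.7],    # Frontoparietal
    [0.9, 0.6, 0.2, 0.0],    # Temporal
    [0.0, 0.0, 0.0, 0.0],    # Other
])

DEFAULT_INTERCEPTS = (17.5, 28.3, 11.4, 22.3)

# Residual inter-dimension correlation: all positive, strongest among the
# three non-fluency dimensions (Logopenia, Agrammatism, Motor speech).
DEFAULT_NOISE_CORR = np.array([
    [1.0, 0.4, 0.3, 0.3],
    [0.4, 1.0, 0.6, 0.6],
    [0.3, 0.6, 1.0, 0.6],
    [0.3, 0.6, 0.6, 1.0],
])


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    n_participants: int = 118
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_mm: float = 4.0
    #: arithmetic mean / sd of the log-normal lesion-volume distribution (cm³)
    lesion_mean_cm3: float = 34.3
    lesion_sd_cm3: float = 38.2
    fwhm_mm: float = 8.0
    betas: np.ndarray = field(default_factory=lambda: DEFAULT_BETAS.copy())
    intercepts: tuple[float, ...] = DEFAULT_INTERCEPTS
    noise_sd: tuple[float, ...] = (12.0, 12.0, 12.0, 12.0)
    noise_corr: np.ndarray = field(default_factory=lambda: DEFAULT_NOISE_CORR.copy())
    rating_thresholds: tuple[float, ...] = (12.5, 37.5, 62.5, 87.5)
    feature_noise_sd: float = 5.0
    rater_agreement: float = 1.0
    rater_noise_sd: float = 15.0
    n_raters: int = 1
    exclusion_counts: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.noise_corr = np.asarray(self.noise_corr, dtype=float)
        if self.betas.shape != (4, 4):
            raise ValueError("betas must be a 4 ROI x 4 dimension matrix")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise sds must be non-negative")
        thr = np.asarray(self.rating_thresholds, dtype=float)
        if not (np.all(np.diff(thr) > 0) and thr[0] >= 0 and thr[-1] <= 100):
            raise ValueError("rating thresholds must be strictly increasing within [0, 100]")
        if not 0.0 <= self.rater_agreement <= 1.0:
            raise ValueError("rater_agreement must lie in [0, 1]")
        eig = np.linalg.eigvalsh(self.noise_corr)
        if eig.min() < -1e-9:
            raise ValueError("noise correlation matrix is not positive semi-definite")

    @classmethod
    def full_size(cls, **kw) -> "SimulationConfig":
        """The 64³ / 2 mm preset (study-scale grid resolution)."""
        kw.setdefault("grid_shape", (64, 64, 64))
        kw.setdefault("voxel_mm", 2.0)
        return cls(**kw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["betas"] = self.betas.tolist()
        payload["noise_corr"] = self.noise_corr.tolist()
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    """A simulated study sample with everything the pipeline consumes."""

    config: SimulationConfig
    grid: GridGeometry
    territory: np.ndarray
    roiset: ROISet
    masks: list[LesionVolumeImage]
    smoothed: list[LesionVolumeImage]
    total_cm3: np.ndarray
    roi_cm3: pd.DataFrame  # participants x ROI names
    latent_scores: pd.DataFrame  # participants x dimensions (unclipped model value)
    observed_scores: pd.DataFrame  # from the primary rater's ratings
    profiles: list[list[RatingProfile]]  # per participant, one per rater
    eligibility: list[EligibilityRecord]
    manifest: dict


# ---------------------------------------------------------------------------
# Geometry: territory and ROIs
# ---------------------------------------------------------------------------

def territory_mask(grid: GridGeometry) -> np.ndarray:
    """Hemisphere-like territory: a generous ellipsoid confined to the
    left half of the grid (x below midline), covering roughly 40% of it."""
    nx, ny, nz = grid.shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 4.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = nx / 3.2, ny / 1.85, nz / 1.85
    ell = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0
    return np.logical_and(ell, x < nx / 2.0)


def default_roiset(grid: GridGeometry, territory: np.ndarray | None = None) -> ROISet:
    """Partition the territory into Prefrontal / Frontoparietal / Temporal /
    Other by anterior-posterior (y) and dorsoventral (z) position."""
    territory = territory_mask(grid) if territory is None else territory
    _, ny, nz = grid.shape
    _, y, z = np.meshgrid(
        np.arange(grid.shape[0]), np.arange(ny), np.arange(nz), indexing="ij"
    )
    labels = np.zeros(grid.shape, dtype=np.int32)
    anterior = y >= 0.55 * ny
    posterior = y < 0.40 * ny
    superior = z >= 0.45 * nz
    labels[np.logical_and.reduce([territory, anterior, superior])] = 1  # Prefrontal
    labels[np.logical_and.reduce([territory, ~anterior, ~posterior, superior])] = 2
    labels[np.logical_and.reduce([territory, posterior, ~superior])] = 3  # Temporal
    labels[np.logical_and(territory, labels == 0)] = 4  # Other
    names = dict(zip((1, 2, 3, 4), ROI_NAMES))
    return ROISet(grid, labels, names)


# ---------------------------------------------------------------------------
# Lesion growth
# ---------------------------------------------------------------------------

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


_NEIGHBOURS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]
])


def _grow_one(
    territory: np.ndarray, start: tuple[int, int, int], n_target: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow a connected lesion by random accretion of frontier voxels."""
    shape = territory.shape
    lesion = np.zeros(shape, dtype=bool)
    lesion[start] = True
    frontier: list[tuple[int, int, int]] = []

    def push_neighbours(v: tuple[int, int, int]) -> None:
        for d in _NEIGHBOURS:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                    and 0 <= w[2] < shape[2]
                    and territory[w] and not lesion[w]):
                frontier.append(w)

    push_neighbours(start)
    grown = 1
    while grown < n_target and frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        v = frontier.pop()
        if lesion[v]:
            continue
        lesion[v] = True
        grown += 1
        push_neighbours(v)
    return lesion


def simulate_lesions(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    territory: np.ndarray | None = None,
    grid: GridGeometry | None = None,
) -> list[LesionVolumeImage]:
    """Draw target volumes from the configured log-normal and grow each
    lesion from a random seed voxel inside the territory."""
    grid = grid or GridGeometry.isotropic(config.grid_shape, config.voxel_mm)
    territory = territory_mask(grid) if territory is None else territory
    if not territory.any():
        raise ValueError("territory mask is empty")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mu, sigma = lognormal_params(config.lesion_mean_cm3, config.lesion_sd_cm3)
    vv = grid.voxel_volume_cm3
    cap = int(territory.sum())
    seeds_idx = np.argwhere(territory)
    out: list[LesionVolumeImage] = []
    clipped = 0
    for _ in range(config.n_participants):
        vol = float(rng.lognormal(mu, sigma))
        n_target = max(1, int(round(vol / vv)))
        if n_target > cap:
            n_target = cap
            clipped += 1
        start = tuple(seeds_idx[int(rng.integers(len(seeds_idx)))])
        lesion = _grow_one(territory, start, n_target, rng)
        out.append(LesionVolumeImage(grid, lesion.astype(float), kind="binary_mask"))
    if clipped:
        warnings.warn(f"{clipped} lesion target volumes exceeded the territory "
                      "and were clipped", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Behaviour and ratings
# ---------------------------------------------------------------------------

def simulate_behaviour(
    masks: list[LesionVolumeImage],
    roiset: ROISet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, float]:
    """Latent dimension scores from ROI lesion loads.

    latent_d = intercept_d + sum_r beta_{r,d} * volume_r + eps_d with eps
    multivariate Gaussian (configured sds and correlation); observed latent
    scores are clipped to [0, 100]. Returns (roi volumes, unclipped latent,
    clipped latent, clipping fraction).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for m in masks:
        per = mask_volume_cm3(m, roiset)
        rows.append([per[lab] for lab in roiset.label_ids])
    vols = pd.DataFrame(rows, columns=[roiset.names[i] for i in roiset.label_ids])
    D = np.diag(config.noise_sd)
    cov = D @ config.noise_corr @ D
    n = len(masks)
    noise = rng.multivariate_normal(np.zeros(4), cov, size=n, method="svd") \
        if np.any(cov) else np.zeros((n, 4))
    latent = np.asarray(config.intercepts) + vols.to_numpy() @ config.betas + noise
    clipped = np.clip(latent, 0.0, 100.0)
    frac = float(np.mean(latent != clipped))
    lat_df = pd.DataFrame(latent, columns=list(DIMENSIONS))
    clip_df = pd.DataFrame(clipped, columns=list(DIMENSIONS))
    return vols, lat_df, clip_df, frac


def simulate_ratings(
    latent_scores: pd.DataFrame,
    fmap: FeatureDimensionMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_raters: int | None = None,
) -> list[list[RatingProfile]]:
    """Ordinal 0-4 feature ratings from latent dimension scores.

    A feature's latent value is its (first) dimension's latent score plus
    feature noise; reverse-scored features are mirrored (100 - value)
    before thresholding; the rating is the count of thresholds below the
    value. Additional raters see the same feature latent perturbed by
    (1 - agreement) * rater_noise_sd Gaussian noise, so agreement = 1
    duplicates the first rater exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_raters = config.n_raters if n_raters is None else n_raters
    thr = np.asarray(config.rating_thresholds, dtype=float)
    feat_dim: dict[str, tuple[str, int]] = {}
    for f, d, s in fmap.entries:
        feat_dim.setdefault(f, (d, s))
    out: list[list[RatingProfile]] = []
    rater_sd = (1.0 - config.rater_agreement) * config.rater_noise_sd
    for i in range(len(latent_scores)):
        pid = f"p{i:04d}"
        base: dict[str, float] = {}
        for f, (d, s) in feat_dim.items():
            v = latent_scores.iloc[i][d] + rng.normal(0.0, config.feature_noise_sd) \
                if config.feature_noise_sd > 0 else latent_scores.iloc[i][d]
            base[f] = 100.0 - v if s == -1 else v
        raters = []
        for r in range(n_raters):
            ratings = {}
            for f, v in base.items():
                vr = v + rng.normal(0.0, rater_sd) if (r > 0 and rater_sd > 0) else v
                ratings[f] = int(np.searchsorted(thr, vr, side="right"))
            raters.append(RatingProfile(pid, f"rater{r+1}", ratings))
        out.append(raters)
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_cohort(
    config: SimulationConfig,
    fmap: FeatureDimensionMap | None = None,
    smooth: bool = True,
) -> Cohort:
    """Run the full generator: lesions -> smoothing -> volumetry ->
    behaviour -> ratings -> eligibility, with a reproducibility manifest."""
    fmap = fmap or default_feature_map()
    rng = np.random.default_rng(config.seed)
    grid = GridGeometry.isotropic(config.grid_shape, config.voxel_mm)
    territory = territory_mask(grid)
    roiset = default_roiset(grid, territory)
    masks = simulate_lesions(config, rng, territory, grid)
    smoothed = [gaussian_smooth(m, config.fwhm_mm) for m in masks] if smooth else []
    total = np.array([mask_volume_cm3(m) for m in masks])
    vols, latent, clipped, clip_frac = simulate_behaviour(masks, roiset, config, rng)
    profiles = simulate_ratings(clipped, fmap, config, rng)
    observed = pd.DataFrame(
        [dimension_scores(p[0], fmap) for p in profiles],
        columns=list(DIMENSIONS),
    )
    n = config.n_participants
    if config.exclusion_counts:
        n_excl = sum(config.exclusion_counts.values())
        if n_excl > n:
            raise ValueError("exclusion counts exceed the cohort size")
        roster = roster_from_exclusion_counts(n - n_excl, config.exclusion_counts)
    else:
        roster = roster_from_exclusion_counts(n, {})
    decisions = [eligibility_filter(r)[0] for r in roster]
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": n,
        "clip_fraction": clip_frac,
        "participants": pd.DataFrame({
            "participant_id": [f"p{i:04d}" for i in range(n)],
            "total_cm3": total,
            "included": [d == "included" for d in decisions],
        }),
    }
    return Cohort(
        config=config, grid=grid, territory=territory, roiset=roiset,
        masks=masks, smoothed=smoothed, total_cm3=total, roi_cm3=vols,
        latent_scores=latent, observed_scores=observed, profiles=profiles,
        eligibility=roster, manifest=manifest,
    )
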