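"""Volumetric image handling for lesion-symptom mapping.

All analyses operate on a common 3D grid in a standard stereotaxic space
(treated as an opaque labelled grid). This module provides the geometric
substrate: NIfTI-1 input/output, Gaussian smoothing of binary lesion masks,
ROI volumetry in cm³, and the lesion-coverage filter that restricts
voxel-wise statistics to adequately sampled voxels.

Conventions: voxel indices are 0-based; world coordinates are millimetres
via the affine (RAS+); volumes are reported in cm³.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "LesionVolumeImage",
    "ROISet",
    "read_volume",
    "write_volume",
    "read_roiset",
    "write_roiset",
    "gaussian_smooth",
    "mask_volume_cm3",
    "coverage_count",
    "FWHM_TO_SIGMA",
]

#: Conversion from a Gaussian full-width-at-half-maximum to its sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GridGeometry:
    """Shape + affine of a 3D sampling grid.

    ``voxel_volume_cm3`` is derived from the affine: |det| of the 3x3
    rotation/zoom block, converted from mm³ to cm³.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Voxel edge lengths along each axis (mm)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])) / 1000.0)

    def matches(self, other: "GridGeometry", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "GridGeometry") -> None:
        if not self.matches(other):
            raise ValueError("grid geometry mismatch between images")

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        homo = np.c_[idx, np.ones(len(idx))]
        out = homo @ self.affine.T
        return out[:, :3] if np.asarray(index).ndim > 1 else out[0, :3]

    @classmethod
    def isotropic(cls, shape: tuple[int, int, int], voxel_mm: float) -> "GridGeometry":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(shape, aff)


VALID_KINDS = ("binary_mask", "smoothed", "statistic")


@dataclass
class LesionVolumeImage:
    """A 3D volume tied to a grid.

    kind:
      * ``binary_mask`` — values in {0, 1} (a delineated lesion);
      * ``smoothed`` — values in [0, 1] (mask after Gaussian smoothing);
      * ``statistic`` — unconstrained real values (t-maps etc.).
    """

    grid: GridGeometry
    data: np.ndarray
    kind: str = "binary_mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 3D, got {self.data.ndim}D")
        if self.data.shape != self.grid.shape:
            raise ValueError("data shape does not match grid shape")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"kind must be one of {VALID_KINDS}")
        if self.kind in ("binary_mask", "smoothed") and np.isnan(self.data).any():
            raise ValueError("NaNs are not allowed in a mask")
        if self.kind == "binary_mask":
            if not np.isin(self.data, (0.0, 1.0)).all():
                raise ValueError("binary_mask values must be exactly 0 or 1")
        elif self.kind == "smoothed":
            if self.data.min() < -1e-9 or self.data.max() > 1.0 + 1e-9:
                raise ValueError("smoothed values must lie in [0, 1]")


@dataclass
class ROISet:
    """Mutually exclusive integer-labelled regions (0 = background)."""

    grid: GridGeometry
    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = self.labels
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("ROI labels must be integers")
            self.labels = np.round(lab).astype(np.int32)
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid shape")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"labels named but absent from the array: {sorted(missing)}")
        for lab in sorted(present - set(self.names)):
            self.names[lab] = f"roi_{lab}"

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.names)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, kind: str = "binary_mask") -> LesionVolumeImage:
    """Read a NIfTI-1 volume and wrap it with the declared kind.

    Raises if the file is missing, not 3D, or violates the kind's invariants
    (e.g. a declared binary mask containing fractional values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    grid = GridGeometry(data.shape, np.asarray(img.affine, dtype=float))
    return LesionVolumeImage(grid, data, kind=kind)


def write_volume(path: str | Path, image: LesionVolumeImage) -> None:
    """Write a volume as NIfTI-1 (float64 payload; lossless round trip)."""
    img = nib.Nifti1Image(image.data.astype(np.float64), image.grid.affine)
    nib.save(img, str(path))


def write_roiset(path: str | Path, roiset: ROISet) -> None:
    """Write an ROISet as an integer NIfTI plus a JSON label→name sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(roiset.labels.astype(np.int16), roiset.grid.affine)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps({str(k): v for k, v in roiset.names.items()}, indent=1))


def read_roiset(path: str | Path) -> ROISet:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    grid = GridGeometry(labels.shape, np.asarray(img.affine, dtype=float))
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + ".json")
    names: dict[int, str] = {}
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return ROISet(grid, labels, names)


# ---------------------------------------------------------------------------
# Smoothing, volumetry, coverage
# ---------------------------------------------------------------------------

def gaussian_smooth(image: LesionVolumeImage, fwhm_mm: float) -> LesionVolumeImage:
    """Smooth a binary lesion mask with a Gaussian kernel of given FWHM.

    The per-axis sigma is ``fwhm_mm / (edge_mm * 2*sqrt(2*ln 2))`` so
    anisotropic voxels are handled correctly. Boundary handling is
    zero-padding: lesions touching the grid edge lose a little mass.
    """
    if image.kind != "binary_mask":
        raise ValueError("gaussian_smooth expects a binary_mask image")
    if not fwhm_mm > 0:
        raise ValueError("fwhm_mm must be positive")
    edges = image.grid.voxel_sizes_mm
    if fwhm_mm < edges.max() / 2:
        warnings.warn(
            f"fwhm {fwhm_mm} mm is smaller than half a voxel edge; "
            "smoothing will be nearly a no-op",
            stacklevel=2,
        )
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / edges
    out = ndimage.gaussian_filter(image.data, sigma=sigma_vox, mode="constant", cval=0.0)
    out = np.clip(out, 0.0, 1.0)
    return LesionVolumeImage(image.grid, out, kind="smoothed")


def mask_volume_cm3(
    mask: LesionVolumeImage,
    roiset: ROISet | None = None,
    binarize_at: float = 0.5,
) -> dict[int, float] | float:
    """Lesion volume in cm³, total or per ROI label.

    Smoothed masks are binarized at ``binarize_at`` first. With a roiset the
    returned dict covers every named label plus 0 (background); values sum
    exactly to the total because labels are mutually exclusive.
    """
    if mask.kind == "binary_mask":
        binary = mask.data > 0.5
    elif mask.kind == "smoothed":
        binary = mask.data >= binarize_at
    else:
        raise ValueError("mask_volume_cm3 expects a mask, not a statistic image")
    vv = mask.grid.voxel_volume_cm3
    if roiset is None:
        return float(binary.sum()) * vv
    mask.grid.require_match(roiset.grid)
    out: dict[int, float] = {}
    for lab in [0] + roiset.label_ids:
        out[lab] = float(np.logical_and(binary, roiset.labels == lab).sum()) * vv
    return out


def coverage_count(
    masks: list[LesionVolumeImage],
    fraction: float = 0.05,
    binarize_at: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-voxel lesion counts and the minimum-coverage inclusion mask.

    Voxels lesioned in fewer than ``ceil(fraction * n)`` participants are
    excluded from voxel-wise statistics to avoid spurious associations
    driven by a handful of lesions. Returns (count image, boolean inclusion
    mask, integer threshold).
    """
    if len(masks) < 2:
        raise ValueError("coverage_count requires at least 2 masks")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    grid = masks[0].grid
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        grid.require_match(m.grid)
        binary = m.data > 0.5 if m.kind == "binary_mask" else m.data >= binarize_at
        counts += binary.astype(np.int32)
    threshold = coverage_threshold(len(masks), fraction)
    return counts, counts >= threshold, threshold


def coverage_threshold(n_participants: int, fraction: float) -> int:
    """Smallest integer ≥ fraction × n (e.g. 118 participants at 5% → 6)."""
    return int(np.ceil(fraction * n_participants))
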