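"""CT windowing, seed-based lesion segmentation, and D-ROI mask construction.

The region-of-interest geometry is three nested masks per axial slice:

* ``core`` — the lesion interior found by local Otsu thresholding;
* ``core_plus_edge`` — the core dilated by a small edge width, absorbing the
  partial-volume transition pixels at the lesion boundary;
* ``ring`` — an annulus of peritumoral parenchyma obtained by dilating the
  core-plus-edge mask a further ``ring_width_px`` and subtracting it.

All coordinates are 0-based ``(slice, row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "CTVolume",
    "LesionAnnotation",
    "MaskTriplet",
    "WindowSpec",
    "SOFT_TISSUE_WINDOW",
    "window_normalize",
    "segment_lesion_slice",
    "build_mask_triplet",
    "select_slices",
    "ring_width_from_spacing",
    "load_volume",
    "save_mask",
]


@dataclass(frozen=True)
class WindowSpec:
    """A clinical display window: intensities are clipped to
    ``[center - width/2, center + width/2]`` and mapped linearly to [0, 1]."""

    center_hu: float
    width_hu: float

    def __post_init__(self) -> None:
        if not self.width_hu > 0:
            raise ValueError(f"width_hu must be positive, got {self.width_hu}")


#: Soft-tissue window used for lesion annotation (center 40 HU, width 400 HU).
SOFT_TISSUE_WINDOW = WindowSpec(center_hu=40.0, width_hu=400.0)


@dataclass
class CTVolume:
    """A CT volume: ``voxels[slice, row, col]`` with physical spacing in mm."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]  # (z, y, x)
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def in_plane_spacing(self) -> float:
        return float(self.spacing_mm[1])


@dataclass(frozen=True)
class LesionAnnotation:
    """Radiologist-style seed annotation for one lesion."""

    patient_id: str
    lesion_id: str
    central_slice_index: int
    seed_point: tuple[int, int]  # (row, col)
    approximate_diameter_mm: float

    def __post_init__(self) -> None:
        if self.approximate_diameter_mm <= 0:
            raise ValueError("approximate_diameter_mm must be positive")


@dataclass
class MaskTriplet:
    """Core / Core-Plus-Edge / Ring binary masks for a single axial slice."""

    core: np.ndarray
    core_plus_edge: np.ndarray
    ring: np.ndarray
    ring_width_px: int
    edge_width_px: int

    def validate(self) -> None:
        if not (self.core.shape == self.core_plus_edge.shape == self.ring.shape):
            raise ValueError("masks must share shape")
        if np.any(self.core & ~self.core_plus_edge):
            raise ValueError("core must be contained in core_plus_edge")
        if np.any(self.ring & self.core_plus_edge):
            raise ValueError("ring must be disjoint from core_plus_edge")


def window_normalize(volume: CTVolume, window: WindowSpec = SOFT_TISSUE_WINDOW) -> CTVolume:
    """Clip HU to the window and rescale linearly to [0, 1].

    ``out = clip((hu - (center - width/2)) / width, 0, 1)``.
    """
    lo = window.center_hu - window.width_hu / 2.0
    out = np.clip((volume.voxels.astype(float) - lo) / window.width_hu, 0.0, 1.0)
    return CTVolume(out, volume.spacing_mm, volume.patient_id)


class SegmentationError(RuntimeError):
    pass


def segment_lesion_slice(
    image: np.ndarray,
    seed: tuple[int, int],
    roi_halfwidth_px: int,
    variance_tol: float = 1e-6,
) -> np.ndarray:
    """Segment a lesion on one axial slice from a seed point.

    Otsu's threshold is computed inside a square ROI of half-width
    ``roi_halfwidth_px`` centred on the seed (clipped at image borders);
    the mask is the 8-connected supra-threshold component containing the
    seed, with interior holes filled.
    """
    image = np.asarray(image, dtype=float)
    r, c = seed
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {image.shape}")
    r0, r1 = max(0, r - roi_halfwidth_px), min(image.shape[0], r + roi_halfwidth_px + 1)
    c0, c1 = max(0, c - roi_halfwidth_px), min(image.shape[1], c + roi_halfwidth_px + 1)
    roi = image[r0:r1, c0:c1]
    if float(np.var(roi)) < variance_tol:
        raise SegmentationError("degenerate ROI: near-constant intensities around seed")
    thresh = threshold_otsu(roi)
    if image[r, c] < thresh:
        raise SegmentationError("seed outside lesion: seed intensity below Otsu threshold")
    supra = np.zeros(image.shape, dtype=bool)
    supra[r0:r1, c0:c1] = roi >= thresh
    labels, _ = ndimage.label(supra, structure=np.ones((3, 3), dtype=int))
    mask = labels == labels[r, c]
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError("empty segmentation")
    return mask


def ring_width_from_spacing(target_mm: float, in_plane_spacing_mm: float | None) -> int:
    """Ring width in pixels for a physical target; 8 px when spacing is unknown
    (the printed 6 mm / 8 px equivalence at 0.75 mm pixels)."""
    if in_plane_spacing_mm is None:
        return 8
    return max(1, round(target_mm / in_plane_spacing_mm))


def build_mask_triplet(
    core: np.ndarray, edge_width_px: int = 2, ring_width_px: int = 8
) -> MaskTriplet:
    """Dilate the core into the edge and ring zones.

    ``core_plus_edge = dilate(core, edge)``;
    ``ring = dilate(core_plus_edge, ring) \\ core_plus_edge``.
    Dilation is by an exact Euclidean disk (thresholded distance transform),
    so nested dilations compose exactly:
    ``core_plus_edge ∪ ring = dilate(core, edge + ring)``.
    Masks are clipped at image bounds.
    """
    core = np.asarray(core, dtype=bool)
    if not core.any():
        raise ValueError("core mask is empty")
    dist = ndimage.distance_transform_edt(~core)
    cpe = dist <= edge_width_px
    ring = (dist <= edge_width_px + ring_width_px) & ~cpe
    if not ring.any():
        raise ValueError("lesion at image border: ring empty after clipping")
    trip = MaskTriplet(core, cpe, ring, ring_width_px=ring_width_px, edge_width_px=edge_width_px)
    trip.validate()
    return trip


def select_slices(
    extent: tuple[int, int], central: int, n_slices_volume: int | None = None, max_steps: int = 2
) -> list[int]:
    """Axial slices for pseudo-volumetric extraction: the central slice plus up
    to ``max_steps`` cranial and caudal neighbours, clipped to the lesion
    extent and the volume bounds (at most five slices by default)."""
    lo, hi = extent
    if not lo <= central <= hi:
        raise ValueError(f"central slice {central} outside extent {extent}")
    lo = max(lo, central - max_steps)
    hi = min(hi, central + max_steps)
    if n_slices_volume is not None:
        lo = max(lo, 0)
        hi = min(hi, n_slices_volume - 1)
    return list(range(lo, hi + 1))


def load_volume(path: str, patient_id: str = "") -> CTVolume:
    """Load a NIfTI volume as (slice, row, col) with (z, y, x) spacing."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    # NIfTI stores (x, y, z); reorder to (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return CTVolume(data, spacing, patient_id)


def save_mask(mask: np.ndarray, spacing_mm: tuple[float, float, float], path: str) -> None:
    """Write a binary mask (slice, row, col) as NIfTI with matching geometry."""
    data = np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    affine = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
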