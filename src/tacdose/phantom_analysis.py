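"""Sphere segmentation and recovery coefficients on 3-D activity images.

Implements the two VOI strategies of a NEMA IEC sphere-phantom analysis:

* CT-based: an analytic sphere of the known diameter placed at the known
  centre (:func:`ct_sphere_voi`);
* isocontour-based: a 12-mm seed sphere at the local activity maximum, a
  threshold at 30% of the seed-sphere mean, and the 26-connected component
  of supra-threshold voxels containing the maximum
  (:func:`isocontour_segment`).

The recovery coefficient of a sphere is the mean measured concentration in
its mask divided by the true filled concentration, without background
subtraction.  Isocontour volumes of small spheres are strongly inflated by
the point-spread function, which motivates a minimum-volume filter for
isocontour-segmented lesions (:func:`volume_threshold_filter`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import EmptyMaskError, InvalidParameterError, OutOfGridError

#: diameter of the seed VOI placed at the activity maximum (mm)
SEED_VOI_DIAMETER_MM = 12.0
#: isocontour threshold as a fraction of the seed-VOI mean
ISOCONTOUR_FRACTION = 0.30
#: radius of the search ball around the user-provided centre hint (mm)
MAX_SEARCH_RADIUS_MM = 30.0
#: minimum mean volume for a reliable isocontour lesion segmentation (ml)
LESION_VOLUME_LIMIT_ML = 5.0


@dataclass
class ActivityImage:
    """Voxelised activity-concentration image (kBq/ml), axes (x, y, z)."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("image must be 3-D")
        if np.any(self.values < 0):
            raise InvalidParameterError("activity concentrations must be >= 0")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidParameterError("voxel size must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates in mm along each axis (broadcastable)."""
        axes = [
            self.origin_mm[i] + (np.arange(self.values.shape[i]) + 0.5) * self.voxel_size_mm[i]
            for i in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with the voxel size in the affine."""
        import nibabel as nib

        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ActivityImage":
        import nibabel as nib

        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), zooms, origin)


@dataclass(frozen=True)
class SphereTruth:
    """Ground truth of one phantom sphere."""

    center_mm: tuple[float, float, float]
    volume_ml: float
    true_concentration_kBq_ml: float

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise InvalidParameterError("sphere volume must be > 0")

    @property
    def radius_mm(self) -> float:
        return float((3.0 * self.volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm


def _distance_sq(image: ActivityImage, center_mm) -> np.ndarray:
    gx, gy, gz = image.coordinate_grids()
    return ((gx - center_mm[0]) ** 2 + (gy - center_mm[1]) ** 2
            + (gz - center_mm[2]) ** 2)


def ct_sphere_voi(center_mm, diameter_mm: float, image: ActivityImage) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within the analytic sphere."""
    if diameter_mm <= 0:
        raise InvalidParameterError("diameter must be > 0")
    r = diameter_mm / 2.0
    lo = np.array(image.origin_mm)
    hi = lo + np.array(image.values.shape) * np.array(image.voxel_size_mm)
    c = np.asarray(center_mm, dtype=float)
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise OutOfGridError(f"sphere (d={diameter_mm} mm) at {center_mm} exceeds the grid")
    return _distance_sq(image, c) <= r ** 2


@dataclass
class IsocontourResult:
    """Isocontour segmentation of one lesion/sphere."""

    mask: np.ndarray
    max_index: tuple[int, int, int]
    threshold_kBq_ml: float
    degenerate: bool  # mask reaches the image boundary (no contained contour)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_ml(self, image: ActivityImage) -> float:
        return self.n_voxels * image.voxel_volume_ml


_CONN_26 = np.ones((3, 3, 3), dtype=bool)


def isocontour_segment(image: ActivityImage, approximate_center_mm,
                       search_radius_mm: float = MAX_SEARCH_RADIUS_MM,
                       seed_diameter_mm: float = SEED_VOI_DIAMETER_MM,
                       threshold_fraction: float = ISOCONTOUR_FRACTION) -> IsocontourResult:
    """Threshold-based lesion segmentation.

    A 12-mm-diameter seed VOI is centred on the maximum-concentration voxel
    within ``search_radius_mm`` of the hint; the contour threshold is
    ``threshold_fraction`` of the seed-VOI mean, and the mask is the
    26-connected supra-threshold component containing the maximum.  A mask
    touching the image boundary is flagged ``degenerate`` (no closed
    isocontour exists, e.g. on a contrast-free image).
    """
    search = _distance_sq(image, approximate_center_mm) <= search_radius_mm ** 2
    if not search.any():
        raise EmptyMaskError("search region lies outside the image")
    masked = np.where(search, image.values, -np.inf)
    max_index = np.unravel_index(int(np.argmax(masked)), image.values.shape)
    max_center = tuple(
        image.origin_mm[i] + (max_index[i] + 0.5) * image.voxel_size_mm[i]
        for i in range(3)
    )
    seed = _distance_sq(image, max_center) <= (seed_diameter_mm / 2.0) ** 2
    if not seed.any():
        raise EmptyMaskError("seed VOI contains no voxels")
    threshold = threshold_fraction * float(image.values[seed].mean())
    above = image.values >= threshold
    labels, _ = ndimage.label(above, structure=_CONN_26)
    component = labels[max_index]
    if component == 0:
        raise EmptyMaskError("maximum voxel below its own threshold")
    mask = labels == component
    on_boundary = bool(
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    return IsocontourResult(mask=mask, max_index=tuple(int(i) for i in max_index),
                            threshold_kBq_ml=threshold, degenerate=on_boundary)


def recovery_coefficient(mask: np.ndarray, image: ActivityImage,
                         truth: SphereTruth) -> float:
    """Mean in-mask concentration divided by the true filled concentration.

    No background subtraction is applied.
    """
    if not np.any(mask):
        raise EmptyMaskError("empty VOI mask")
    return float(image.values[mask].mean()) / truth.true_concentration_kBq_ml


def volume_threshold_filter(series_volumes_ml, threshold_ml: float = LESION_VOLUME_LIMIT_ML):
    """Keep/drop flags for VOIs by mean volume (keep if >= threshold)."""
    return np.asarray(series_volumes_ml, dtype=float) >= threshold_ml
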