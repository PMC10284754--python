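"""Construction and statistics of volumes of interest (VOIs).

Covers every VOI family used in the analysis: diameter-matched spheres
(``VOI_dia``), concentric spheres expanded by a fixed margin
(``VOI_dia+15``), small centered spheres (diameter 10/15/20 mm), the 1 cm^3
peak sphere, and threshold-grown regions capped by a bounding sphere.

Spherical VOIs carry fractional voxel weights by default: with 4.8 mm
voxels and spheres down to 10 mm, binary membership is far too coarse.
Threshold-grown VOIs are binary, since they are defined on voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from luquant._grid import distance_to_point, sphere_fits_grid, sphere_fraction_map
from luquant.phantom import VoxelImage

#: Diameter of a 1 cm^3 sphere, mm (~12.407).
PEAK_SPHERE_DIAMETER_MM = (6.0 * 1000.0 / math.pi) ** (1.0 / 3.0)


@dataclass
class VOIMask:
    """Per-voxel membership weights in [0, 1] over an image grid."""

    weights: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be a 3-D array")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.weights.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    @property
    def volume_ml(self) -> float:
        return float(self.weights.sum()) * self.voxel_volume_ml

    def on_grid_of(self, image: VoxelImage) -> bool:
        return (
            self.shape == image.shape
            and self.voxel_size == image.voxel_size
            and np.allclose(self.origin, image.origin)
        )

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.weights.astype(np.float32), affine), str(path))


@dataclass(frozen=True)
class VOIStats:
    """Summary statistics of an image within a VOI.

    ``activity_kbq`` is always ``mean * volume_ml``; ``peak`` (the maximum
    1 cm^3 average) is filled in separately when requested and defined.
    """

    mean: float
    max: float
    volume_ml: float
    activity_kbq: float
    peak: float | None = None


def spherical_voi(
    image: VoxelImage,
    center,
    diameter: float,
    fractional: bool = True,
    supersampling: int = 4,
) -> VOIMask:
    """Spherical VOI of the given diameter (mm) centered at ``center`` (mm).

    In fractional mode the weight of each voxel is its supersampled inside
    fraction; in binary mode a voxel is included iff its center lies within
    the sphere radius.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    center = np.asarray(center, dtype=float)
    if not sphere_fits_grid(
        image.shape, image.voxel_size, image.origin, center, diameter / 2.0
    ):
        raise ValueError(f"VOI sphere (d={diameter} mm at {tuple(center)}) outside grid")
    weights = np.zeros(image.shape)
    if fractional:
        slices, frac = sphere_fraction_map(
            image.shape, image.voxel_size, image.origin, center, diameter, supersampling
        )
        weights[slices] = frac
    else:
        dist = distance_to_point(image.shape, image.voxel_size, image.origin, center)
        weights[dist <= diameter / 2.0] = 1.0
        if not weights.any():
            # tiny sphere between voxel centers: take the nearest voxel
            weights[image.nearest_index(center)] = 1.0
    return VOIMask(weights=weights, voxel_size=image.voxel_size, origin=image.origin)


def expanded_voi(
    image: VoxelImage,
    center,
    diameter: float,
    expansion_mm: float = 15.0,
    fractional: bool = True,
    supersampling: int = 4,
) -> VOIMask:
    """Concentric spherical VOI with diameter ``diameter + expansion_mm``.

    The default 15 mm margin captures essentially all counts blurred out of
    the object without reaching neighboring spheres.
    """
    return spherical_voi(
        image, center, diameter + expansion_mm, fractional, supersampling
    )


def voi_stats(image: VoxelImage, mask: VOIMask) -> VOIStats:
    """Weighted mean, max, volume and activity of ``image`` within ``mask``."""
    if not mask.on_grid_of(image):
        raise ValueError("mask is not defined on the image grid")
    wsum = float(mask.weights.sum())
    if wsum <= 0:
        raise ValueError("empty VOI mask")
    mean = float((mask.weights * image.values).sum()) / wsum
    mx = float(image.values[mask.weights > 0].max())
    volume = wsum * mask.voxel_volume_ml
    return VOIStats(mean=mean, max=mx, volume_ml=volume, activity_kbq=mean * volume)


def _peak_kernel(voxel_size: float, supersampling: int = 8) -> np.ndarray:
    """Fractional-weight kernel of a 1 cm^3 sphere centered on a voxel."""
    r = PEAK_SPHERE_DIAMETER_MM / 2.0
    n = 2 * int(math.ceil(r / voxel_size + 0.5)) + 1
    shape = (n, n, n)
    center = np.full(3, (n - 1) / 2.0 * voxel_size)
    slices, frac = sphere_fraction_map(
        shape, voxel_size, np.zeros(3), center, PEAK_SPHERE_DIAMETER_MM, supersampling
    )
    kernel = np.zeros(shape)
    kernel[slices] = frac
    return kernel / kernel.sum()


def peak_value(
    image: VoxelImage, search_region: VOIMask, supersampling: int = 8
) -> float | None:
    """Maximum 1 cm^3 sphere average with center inside ``search_region``.

    Candidate sphere centers are the voxel centers with nonzero region
    weight; the averaging sphere itself may extend beyond the region (the
    convention is recorded here rather than configurable). Returns ``None``
    when the region volume is below 1 cm^3, where a peak value is undefined.
    """
    if not search_region.weights.any():
        raise ValueError("empty search region")
    if search_region.volume_ml < 1.0:
        return None
    kernel = _peak_kernel(image.voxel_size, supersampling)
    means = ndimage.convolve(image.values, kernel, mode="constant")
    return float(means[search_region.weights > 0].max())


def grow_threshold_voi(
    image: VoxelImage,
    reference_value: float,
    fraction: float,
    seed_point,
    bound_center,
    bound_diameter: float = 75.0,
) -> tuple[VOIMask, bool]:
    """Region-grow a binary VOI above ``fraction * reference_value``.

    The VOI is the 26-connected component of supra-threshold voxels that
    contains the seed point (mm), intersected with a bounding sphere. The
    returned flag is False when the component touches the bounding-sphere
    surface (any included voxel center within one voxel diagonal of the
    bound radius), meaning the grown region was stopped by the cap rather
    than by the threshold and should not be evaluated further.

    ``reference_value`` is passed in (a max or a peak value) rather than
    recomputed, so the different threshold methods share this operation.
    """
    if reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    threshold = fraction * reference_value
    seed_idx = image.nearest_index(seed_point)
    if image.values[seed_idx] < threshold:
        raise ValueError(
            f"seed voxel value {image.values[seed_idx]:.3g} below threshold "
            f"{threshold:.3g}"
        )
    above = image.values >= threshold
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    comp = labels == labels[seed_idx]

    bound_center = np.asarray(bound_center, dtype=float)
    r_bound = bound_diameter / 2.0
    dist = distance_to_point(image.shape, image.voxel_size, image.origin, bound_center)
    comp &= dist <= r_bound

    diag = math.sqrt(3.0) * image.voxel_size
    touches = bool(np.any(dist[comp] >= r_bound - diag)) if comp.any() else False
    mask = VOIMask(
        weights=comp.astype(float), voxel_size=image.voxel_size, origin=image.origin
    )
    return mask, not touches
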