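"""Shared voxel-grid geometry helpers.

Convention: 0-based voxel indices; the physical position of voxel
``(i, j, k)`` is ``origin + index * voxel_size`` (voxel-center convention);
all geometry in mm.
"""

from __future__ import annotations

import itertools

import numpy as np


def voxel_center_axes(
    shape: tuple[int, int, int], voxel_size: float, origin: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical coordinates (mm) of voxel centers along each axis."""
    return tuple(
        origin[a] + voxel_size * np.arange(shape[a], dtype=float) for a in range(3)
    )


def distance_to_point(
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray,
    point: np.ndarray,
) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to ``point``."""
    ax = voxel_center_axes(shape, voxel_size, origin)
    dx = ax[0] - point[0]
    dy = ax[1] - point[1]
    dz = ax[2] - point[2]
    return np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )


def sphere_bbox(
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray,
    center: np.ndarray,
    radius: float,
) -> tuple[slice, slice, slice]:
    """Index slices of the voxels whose cube can intersect the sphere."""
    half = voxel_size / 2.0
    lo = np.floor((center - radius - half - origin) / voxel_size).astype(int)
    hi = np.ceil((center + radius + half - origin) / voxel_size).astype(int) + 1
    lo = np.clip(lo, 0, np.asarray(shape))
    hi = np.clip(hi, 0, np.asarray(shape))
    return tuple(slice(int(lo[a]), int(hi[a])) for a in range(3))


def sphere_fits_grid(
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray,
    center: np.ndarray,
    radius: float,
) -> bool:
    """True when the sphere lies inside the physical extent of the grid.

    The grid extent runs from half a voxel before the first center to half a
    voxel after the last one.
    """
    half = voxel_size / 2.0
    lo = origin - half
    hi = origin + (np.asarray(shape) - 1) * voxel_size + half
    return bool(np.all(center - radius >= lo) and np.all(center + radius <= hi))


def sphere_fraction_map(
    shape: tuple[int, int, int],
    voxel_size: float,
    origin: np.ndarray,
    center: np.ndarray,
    diameter: float,
    supersampling: int = 4,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Per-voxel inside fraction of a sphere, restricted to its bounding box.

    Each voxel cube is subdivided into ``supersampling**3`` subvoxels; the
    fraction is the share of subvoxel centers lying inside the sphere. The
    subvoxel loop is run incrementally so memory stays proportional to the
    bounding box, not to the supersampling.
    """
    if supersampling < 1:
        raise ValueError("supersampling must be >= 1")
    radius = diameter / 2.0
    center = np.asarray(center, dtype=float)
    slices = sphere_bbox(shape, voxel_size, origin, center, radius)
    bshape = tuple(s.stop - s.start for s in slices)
    if any(n == 0 for n in bshape):
        return slices, np.zeros(bshape)

    ax = [
        origin[a] + voxel_size * (np.arange(slices[a].start, slices[a].stop)) - center[a]
        for a in range(3)
    ]
    sub = voxel_size * ((np.arange(supersampling) + 0.5) / supersampling - 0.5)
    count = np.zeros(bshape, dtype=np.int64)
    r2 = radius * radius
    for ox, oy, oz in itertools.product(sub, sub, sub):
        d2 = (
            (ax[0] + ox)[:, None, None] ** 2
            + (ax[1] + oy)[None, :, None] ** 2
            + (ax[2] + oz)[None, None, :] ** 2
        )
        count += d2 <= r2
    return slices, count / float(supersampling**3)
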