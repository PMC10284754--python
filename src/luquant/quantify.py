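"""Scalar quantification metrics.

Contrast, accuracy deviation, recovery coefficients, sphere-to-background
voxel ratio (SBVR), volume/background-dependent calibration factors, and
total-count rescaling of one reconstruction against another.

All ratios are kept as fractions here; conversion to percent belongs to the
reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from luquant._grid import distance_to_point
from luquant.phantom import PhantomSpec, VoxelImage
from luquant.voi import VOIMask, expanded_voi, spherical_voi, voi_stats

#: Default system sensitivity, s^-1 MBq^-1.
DEFAULT_SENSITIVITY = 10.9


@dataclass(frozen=True)
class CalibrationResult:
    """Calibration factor CF = (C_dia / C_true) * S, with optional SBVR."""

    cf: float
    sensitivity: float = DEFAULT_SENSITIVITY
    sbvr: float | None = None


def contrast(c_dia: float, c_bkg: float) -> float:
    """Contrast (C_dia - C_bkg) / (C_dia + C_bkg), in [-1, 1].

    1 without background activity, 0 when sphere and background read the
    same; equals 0.5 at a measured sphere-to-background ratio of 3.
    """
    denom = c_dia + c_bkg
    if denom <= 0:
        raise ValueError("contrast undefined: c_dia + c_bkg must be > 0")
    return (c_dia - c_bkg) / denom


def accuracy_deviation(reconstructed_activity: float, known_activity: float) -> float:
    """Relative deviation (reconstructed - known) / known of recovered activity."""
    if known_activity <= 0:
        raise ValueError("known_activity must be > 0")
    return (reconstructed_activity - known_activity) / known_activity


def sbvr(c_dia: float, c_bkg: float) -> float:
    """Sphere-to-Background Voxel Ratio, the measured ratio C_dia / C_bkg."""
    if c_bkg <= 0:
        raise ValueError("sbvr undefined: c_bkg must be > 0")
    return c_dia / c_bkg


def calibration_factor(
    c_dia: float,
    c_true: float,
    sensitivity: float = DEFAULT_SENSITIVITY,
    c_bkg: float | None = None,
) -> CalibrationResult:
    """Calibration factor CF = (C_dia / C_true) * S, s^-1 MBq^-1.

    ``S`` is the system sensitivity; with ``c_bkg`` given, the SBVR is
    recorded alongside so CF can be studied against it.
    """
    if c_true <= 0:
        raise ValueError("c_true must be > 0")
    cf = (c_dia / c_true) * sensitivity
    result_sbvr = sbvr(c_dia, c_bkg) if c_bkg is not None else None
    return CalibrationResult(cf=cf, sensitivity=sensitivity, sbvr=result_sbvr)


def recovery_coefficient(
    image: VoxelImage,
    center,
    diameter: float,
    reference_activity: float | None = None,
    expansion_mm: float = 15.0,
    supersampling: int = 4,
) -> float:
    """Recovery coefficient: activity in VOI_dia over a reference total.

    The reference is normally the activity inside the expanded VOI measured
    on the matching background-free image (where it captures essentially
    all of the sphere's counts). Without background, passing ``None`` takes
    the reference from the same image's expanded VOI.
    """
    dia = spherical_voi(image, center, diameter, True, supersampling)
    a_dia = voi_stats(image, dia).activity_kbq
    if reference_activity is None:
        big = expanded_voi(image, center, diameter, expansion_mm, True, supersampling)
        reference_activity = voi_stats(image, big).activity_kbq
    if reference_activity <= 0:
        raise ValueError("reference_activity must be > 0")
    return a_dia / reference_activity


def background_voi(
    image: VoxelImage,
    spec: PhantomSpec,
    clearance_mm: float = 25.0,
    edge_margin_mm: float = 15.0,
) -> VOIMask:
    """Large background VOI away from all spheres and from the grid faces.

    A voxel belongs to the background VOI when it is farther than
    ``sphere radius + clearance_mm`` from every sphere center (so spill-out
    does not contaminate the background estimate) and at least
    ``edge_margin_mm`` from the grid boundary (where blur truncation would
    bias it low).
    """
    keep = np.ones(image.shape, dtype=bool)
    for s in spec.spheres:
        dist = distance_to_point(
            image.shape, image.voxel_size, image.origin, np.asarray(s.center)
        )
        keep &= dist > s.radius + clearance_mm
    m = int(np.ceil(edge_margin_mm / image.voxel_size))
    if m > 0:
        border = np.zeros(image.shape, dtype=bool)
        border[m:-m, m:-m, m:-m] = True
        keep &= border
    if not keep.any():
        raise ValueError("background VOI is empty; reduce margins")
    return VOIMask(
        weights=keep.astype(float), voxel_size=image.voxel_size, origin=image.origin
    )


def rescale_to_reference(image: VoxelImage, reference: VoxelImage) -> VoxelImage:
    """Scale ``image`` so its voxel-value sum matches ``reference``'s.

    This is how a non-quantitative reconstruction is calibrated against a
    quantitative one of the same acquisition: multiply by the ratio of the
    total voxel-value sums.
    """
    if not image.same_grid(reference):
        raise ValueError("images are on different grids")
    s_img = float(image.values.sum())
    s_ref = float(reference.values.sum())
    if s_img <= 0 or s_ref <= 0:
        raise ValueError("both images must have positive total value")
    return VoxelImage(
        values=image.values * (s_ref / s_img),
        voxel_size=image.voxel_size,
        origin=image.origin,
    )
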