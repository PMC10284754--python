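"""Recovery-coefficient model and threshold-VOI partial-volume correction.

The recovery coefficient of a sphere of diameter ``d`` is modelled by the
sigmoid

    RC(d) = 1 / (1 + (alpha / d)^beta)

which rises from 0 for objects much smaller than the resolution to 1 for
large ones; ``alpha`` (mm) is the diameter recovered at 50 %.

A threshold-grown VOI is generally smaller than the object it samples, so
its mean concentration ``C_VOI`` must be corrected for partial-volume loss.
The VOI volume ``V_VOI`` is related to the true object volume ``V`` by the
empirical growth law

    V_VOI(V) = V_0 + c * V * (1 - exp(-V / V_1)),   0 < c <= 1,

fitted on background-free data; inverting it (via a monotone lookup table)
yields the volume scale ``v = V(V_VOI) / V_VOI``, the effective object
diameter

    d' = (v * 6 V_VOI / pi)^(1/3),

and the corrected concentration ``C = C_VOI / RC(d')``. Data points with
``V_VOI < V_0`` fall below the growth law's floor and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class ExcludedVOIError(ValueError):
    """Raised when a VOI volume falls below the fitted floor V_0."""


@dataclass(frozen=True)
class RCModel:
    """Fitted recovery-coefficient curve RC(d) = 1 / (1 + (alpha/d)^beta)."""

    alpha: float
    beta: float
    residual_norm: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")


@dataclass(frozen=True)
class VolumeGrowthModel:
    """Fitted VOI-volume growth law with its inversion lookup table.

    The law approaches ``V_0`` for small true volumes and ``c * V`` for
    large ones. ``lookup_true``/``lookup_voi`` tabulate (V, V_VOI) pairs on
    a log-spaced grid for monotone inversion by linear interpolation.
    """

    v0: float
    c: float
    v1: float
    lookup_true: np.ndarray = field(repr=False)
    lookup_voi: np.ndarray = field(repr=False)
    residual_norm: float = 0.0
    c_at_boundary: bool = False

    def __post_init__(self):
        if not 0 < self.c <= 1:
            raise ValueError("c must be in (0, 1]")
        if self.v1 <= 0:
            raise ValueError("v1 must be > 0")

    @classmethod
    def from_parameters(
        cls,
        v0: float,
        c: float,
        v1: float,
        v_max_ml: float = 120.0,
        table_size: int = 10_000,
    ) -> "VolumeGrowthModel":
        """Build a model (with lookup table) from known parameters."""
        table_v = np.geomspace(0.01, v_max_ml, table_size)
        return cls(
            v0=v0,
            c=c,
            v1=v1,
            lookup_true=table_v,
            lookup_voi=volume_growth_eval(v0, c, v1, table_v),
            c_at_boundary=bool(abs(c - 1.0) < 1e-3),
        )

    def to_dict(self) -> dict:
        return {
            "v0_ml": self.v0,
            "c": self.c,
            "v1_ml": self.v1,
            "c_at_boundary": self.c_at_boundary,
            "residual_norm": self.residual_norm,
            "lookup_size": int(len(self.lookup_true)),
            "lookup_range_ml": [float(self.lookup_true[0]), float(self.lookup_true[-1])],
        }


@dataclass(frozen=True)
class PVCResult:
    """Outcome of the partial-volume correction of one threshold VOI."""

    scale_v: float
    d_prime_mm: float
    corrected_concentration: float
    excluded: bool = False


def rc_eval(model: RCModel, d) -> float | np.ndarray:
    """Evaluate RC(d); strictly increasing in d, 0.5 at d = alpha."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be > 0")
    out = 1.0 / (1.0 + (model.alpha / d) ** model.beta)
    return float(out) if out.ndim == 0 else out


def volume_growth_eval(v0: float, c: float, v1: float, v) -> np.ndarray:
    """Evaluate V_VOI(V) = V_0 + c V (1 - exp(-V/V_1))."""
    v = np.asarray(v, dtype=float)
    return v0 + c * v * (1.0 - np.exp(-v / v1))


def fit_rc(diameters, rcs) -> RCModel:
    """Nonlinear least-squares fit of the recovery curve to (d, RC) data.

    Initialization: alpha at the median diameter, beta = 2 (robust defaults
    for resolution-limited recovery data).
    """
    d = np.asarray(diameters, dtype=float)
    rc = np.asarray(rcs, dtype=float)
    if d.size < 3 or d.size != rc.size:
        raise ValueError("need at least 3 matched (diameter, RC) points")
    if np.any(d <= 0):
        raise ValueError("diameters must be > 0")
    if np.any((rc <= 0) | (rc >= 1)):
        raise ValueError("RC values must lie strictly in (0, 1)")

    def resid(p):
        return 1.0 / (1.0 + (p[0] / d) ** p[1]) - rc

    x0 = [float(np.median(d)), 2.0]
    sol = least_squares(resid, x0, bounds=([1e-9, 1e-9], [np.inf, np.inf]))
    if not sol.success:
        raise RuntimeError(f"RC fit did not converge: {sol.message}")
    return RCModel(
        alpha=float(sol.x[0]),
        beta=float(sol.x[1]),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def fit_volume_growth(
    true_volumes,
    voi_volumes,
    table_size: int = 10_000,
    table_factor: float = 4.0,
) -> VolumeGrowthModel:
    """Constrained fit of the VOI-volume growth law to (V, V_VOI) data.

    The constraint 0 < c <= 1 is imposed; with few points in the large-V
    asymptote, c typically lands on the boundary 1, which is reported via
    ``c_at_boundary``. The inversion lookup table spans log-spaced true
    volumes from 0.01 ml to ``table_factor`` times the largest fitted
    volume.
    """
    v = np.asarray(true_volumes, dtype=float)
    vv = np.asarray(voi_volumes, dtype=float)
    if v.size < 3 or v.size != vv.size:
        raise ValueError("need at least 3 matched (V, V_VOI) points")
    if np.any(v <= 0) or np.any(vv <= 0):
        raise ValueError("volumes must be > 0")
    if np.ptp(vv) == 0 or np.ptp(v) == 0:
        raise ValueError("degenerate input: volume data carry no growth information")

    def resid(p):
        return volume_growth_eval(p[0], p[1], p[2], v) - vv

    x0 = [float(vv.min()), 1.0, float(np.median(v))]
    sol = least_squares(resid, x0, bounds=([0.0, 1e-9, 1e-9], [np.inf, 1.0, np.inf]))
    if not sol.success:
        raise RuntimeError(f"volume-growth fit did not converge: {sol.message}")
    v0, c, v1 = (float(x) for x in sol.x)

    table_v = np.geomspace(0.01, table_factor * v.max(), table_size)
    table_vv = volume_growth_eval(v0, c, v1, table_v)
    if np.any(np.diff(table_vv) <= 0):
        raise RuntimeError("fitted growth curve is not strictly increasing")
    return VolumeGrowthModel(
        v0=v0,
        c=c,
        v1=v1,
        lookup_true=table_v,
        lookup_voi=table_vv,
        residual_norm=float(np.linalg.norm(sol.fun)),
        c_at_boundary=bool(abs(c - 1.0) < 1e-3),
    )


def invert_volume_growth(model: VolumeGrowthModel, v_voi: float) -> tuple[float, float]:
    """Recover the true volume V from a measured VOI volume, plus v = V/V_VOI.

    Inversion uses linear interpolation on the monotone lookup table.
    Raises :class:`ExcludedVOIError` when ``v_voi`` falls below the fitted
    floor V_0 (the data point must be excluded) and ``ValueError`` when it
    lies beyond the table range.
    """
    if v_voi < model.v0:
        raise ExcludedVOIError(
            f"V_VOI = {v_voi:.3g} ml is below the fitted floor V_0 = "
            f"{model.v0:.3g} ml"
        )
    if v_voi < model.lookup_voi[0]:
        # below the table but above V_0: the tiny-V end of the curve
        v_true = float(model.lookup_true[0])
    elif v_voi > model.lookup_voi[-1]:
        raise ValueError(
            f"V_VOI = {v_voi:.3g} ml beyond the lookup range "
            f"(max {model.lookup_voi[-1]:.3g} ml)"
        )
    else:
        v_true = float(np.interp(v_voi, model.lookup_voi, model.lookup_true))
    return v_true, v_true / v_voi


def effective_diameter(v_voi_ml: float, scale_v: float) -> float:
    """Effective object diameter d' = (v * 6 V_VOI / pi)^(1/3), mm.

    ``V_VOI`` is in ml; the ml -> mm^3 factor of 1000 is applied here so
    the result is in mm.
    """
    if v_voi_ml <= 0 or scale_v <= 0:
        raise ValueError("v_voi_ml and scale_v must be > 0")
    return (scale_v * 6.0 * v_voi_ml * 1000.0 / math.pi) ** (1.0 / 3.0)


def pvc_concentration(c_voi: float, d_prime: float, rc_model: RCModel) -> float:
    """Partial-volume-corrected concentration C = C_VOI / RC(d')."""
    if d_prime <= 0:
        raise ValueError("d_prime must be > 0")
    return c_voi / rc_eval(rc_model, d_prime)


def pvc_correct(
    c_voi: float,
    v_voi_ml: float,
    growth_model: VolumeGrowthModel,
    rc_model: RCModel,
) -> PVCResult:
    """Full partial-volume correction of one threshold-VOI measurement.

    Chains the lookup-table inversion, the effective diameter and the RC
    division. A VOI volume below the fitted floor V_0 yields an excluded
    result (NaN correction) rather than an exception, so pipeline rows can
    be retained with flags.
    """
    try:
        v_true, scale_v = invert_volume_growth(growth_model, v_voi_ml)
    except ExcludedVOIError:
        return PVCResult(
            scale_v=math.nan,
            d_prime_mm=math.nan,
            corrected_concentration=math.nan,
            excluded=True,
        )
    d_prime = effective_diameter(v_voi_ml, scale_v)
    return PVCResult(
        scale_v=scale_v,
        d_prime_mm=d_prime,
        corrected_concentration=pvc_concentration(c_voi, d_prime, rc_model),
        excluded=False,
    )
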