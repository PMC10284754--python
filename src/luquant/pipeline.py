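"""Experiment orchestration, tumor-selection criteria and error arithmetic.

`run_experiment` sweeps phantom background ratios x reconstruction variants
x noise replicates, measures every sphere with every quantification method,
fits the recovery and VOI-volume-growth models on the background-free
phantom, applies the partial-volume correction, and returns tidy tables.
Rows that cannot be evaluated (VOI hit the bounding sphere, peak undefined,
VOI volume below the fitted floor) are retained with flags rather than
dropped, so reports show exactly which sphere/method/background
combinations fail.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from luquant.phantom import (
    DEFAULT_FILL_KBQ_ML,
    DEFAULT_GRID_SHAPE,
    DEFAULT_VOXEL_MM,
    PhantomSpec,
    ReconVariant,
    default_phantom,
    default_variants,
    make_phantom_series,
    rasterize_phantom,
    simulate_phantom,
)
from luquant.quantify import (
    DEFAULT_SENSITIVITY,
    accuracy_deviation,
    background_voi,
    calibration_factor,
    contrast,
    sbvr,
)
from luquant.recovery import fit_rc, fit_volume_growth, pvc_correct
from luquant.voi import (
    expanded_voi,
    grow_threshold_voi,
    peak_value,
    spherical_voi,
    voi_stats,
)

#: Threshold methods: name -> (reference kind, threshold fraction).
THRESHOLD_METHODS = {
    "thr_max_40": ("max", 0.40),
    "thr_max_50": ("max", 0.50),
    "thr_peak_50": ("peak", 0.50),
    "thr_peak_60": ("peak", 0.60),
}

#: All quantification method names emitted by `run_experiment`.
METHOD_NAMES = (
    ["large_voi", "small_voi_10", "small_voi_15", "small_voi_20"]
    + list(THRESHOLD_METHODS)
    + [m + "_pvc" for m in THRESHOLD_METHODS]
)


# ---------------------------------------------------------------------------
# criteria and error arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CriteriaDecision:
    """Eligibility of a tumor for one quantification method."""

    method: str
    tumor_diameter: float
    tumor_to_background: float
    solitary: bool
    eligible: bool
    reason: str


def check_criteria(
    method: str,
    tumor_diameter: float,
    tumor_to_background: float = math.inf,
    solitary: bool = False,
) -> CriteriaDecision:
    """Tumor-selection rule for each measurement method (strict inequalities).

    * ``large_voi``: solitary tumor with diameter > 15 mm;
    * ``small_voi``: diameter > 30 mm and tumor-to-background ratio > 2;
    * ``threshold``: diameter > 30 mm and tumor-to-background ratio > 3.

    Boundary values are not eligible.
    """
    if tumor_diameter <= 0:
        raise ValueError("tumor_diameter must be > 0")
    if method == "large_voi":
        if not solitary:
            eligible, reason = False, "tumor is not solitary"
        elif tumor_diameter > 15:
            eligible, reason = True, "solitary tumor with diameter > 15 mm"
        else:
            eligible, reason = False, "diameter not > 15 mm"
    elif method in ("small_voi", "threshold"):
        min_ratio = 2.0 if method == "small_voi" else 3.0
        if tumor_diameter <= 30:
            eligible, reason = False, "diameter not > 30 mm"
        elif tumor_to_background > min_ratio:
            eligible, reason = (
                True,
                f"diameter > 30 mm and tumor-to-background ratio > {min_ratio:g}",
            )
        else:
            eligible, reason = (
                False,
                f"tumor-to-background ratio not > {min_ratio:g}",
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return CriteriaDecision(
        method=method,
        tumor_diameter=tumor_diameter,
        tumor_to_background=tumor_to_background,
        solitary=solitary,
        eligible=eligible,
        reason=reason,
    )


def triangular_sd_from_max_error(max_error: float) -> float:
    """SD of a symmetric triangular error distribution with the given half-width.

    A triangular distribution on [-a, a] has SD a / sqrt(6); a 50 % maximal
    error thus corresponds to a standard deviation of about 20 %.
    """
    if max_error < 0:
        raise ValueError("max_error must be >= 0")
    return max_error / math.sqrt(6.0)


def true_value_bounds(max_relative_error: float) -> tuple[float, float]:
    """Bounds (in percent) on the true value given a bounded estimate error.

    If an estimate is within a fraction ``e`` of the true value, the true
    value lies within ``(1/(1+e) - 1, 1/(1-e) - 1)`` of the estimate; for
    e = 0.5 that is (-33.3 %, +100 %). Returned as (lower %, upper %).
    """
    if not 0 <= max_relative_error < 1:
        raise ValueError("max_relative_error must be in [0, 1)")
    e = max_relative_error
    lower = (1.0 / (1.0 + e) - 1.0) * 100.0
    upper = (1.0 / (1.0 - e) - 1.0) * 100.0
    return lower, upper


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Full configuration of a phantom experiment sweep.

    ``replicates`` maps phantom labels to the number of independent noise
    realizations (defaults mirror repeated scans of the background-free and
    lowest-ratio phantoms); unknown labels get one replicate.
    """

    fill_kbq_ml: float = DEFAULT_FILL_KBQ_ML
    ratios: tuple[float, ...] = (math.inf, 9.5, 5.0, 2.7)
    replicates: dict = field(default_factory=lambda: {"P_inf": 3, "P_2.7": 2})
    variants: dict = field(default_factory=default_variants)
    base_seed: int = 0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size: float = DEFAULT_VOXEL_MM
    supersampling: int = 4
    small_voi_diameters: tuple[float, ...] = (10.0, 15.0, 20.0)
    bound_diameter: float = 75.0
    expansion_mm: float = 15.0
    sensitivity: float = DEFAULT_SENSITIVITY
    growth_fit_min_diameter: float = 13.0  # five largest spheres

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratios"] = [("inf" if math.isinf(r) else r) for r in self.ratios]
        d["variants"] = {k: asdict(v) for k, v in self.variants.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "ratios" in d:
            d["ratios"] = tuple(
                math.inf if r in ("inf", "Infinity") else float(r) for r in d["ratios"]
            )
        if "variants" in d:
            d["variants"] = {k: ReconVariant(**v) for k, v in d["variants"].items()}
        for key in ("grid_shape", "small_voi_diameters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _rep_seed(base_seed: int, p_idx: int, v_idx: int, rep: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), p_idx, v_idx, rep])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# measurement pass
# ---------------------------------------------------------------------------


def _measure_image(image, spec: PhantomSpec, config: ExperimentConfig) -> list[dict]:
    """All per-sphere raw measurements on one reconstructed image."""
    bkg_mask = background_voi(image, spec)
    c_bkg = voi_stats(image, bkg_mask).mean
    rows = []
    for s in sorted(spec.spheres, key=lambda x: x.diameter):
        row = {
            "sphere_d_mm": s.diameter,
            "c_true": s.true_concentration,
            "c_bkg_true": spec.background_concentration,
            "true_volume_ml": s.volume_ml,
            "true_activity_kbq": s.activity_kbq,
            "c_bkg": c_bkg,
        }
        dia = spherical_voi(image, s.center, s.diameter, True, config.supersampling)
        st_dia = voi_stats(image, dia)
        big = expanded_voi(
            image, s.center, s.diameter, config.expansion_mm, True, config.supersampling
        )
        st_big = voi_stats(image, big)
        pk = peak_value(image, dia)
        row.update(
            mean_dia=st_dia.mean,
            max_dia=st_dia.max,
            peak=pk if pk is not None else math.nan,
            act_dia_kbq=st_dia.activity_kbq,
            act_dia15_kbq=st_big.activity_kbq,
        )
        for dv in config.small_voi_diameters:
            key = f"small_{dv:g}_mean"
            if s.diameter >= dv:
                sv = spherical_voi(image, s.center, dv, True, config.supersampling)
                row[key] = voi_stats(image, sv).mean
            else:
                row[key] = math.nan
        # threshold-grown VOIs, seeded at the hottest voxel inside VOI_dia
        inside = dia.weights > 0
        hot_flat = np.argmax(np.where(inside, image.values, -np.inf))
        hot_idx = np.unravel_index(hot_flat, image.shape)
        seed_pt = image.origin + np.asarray(hot_idx, float) * image.voxel_size
        for name, (kind, frac) in THRESHOLD_METHODS.items():
            ref = st_dia.max if kind == "max" else pk
            if ref is None or not np.isfinite(ref) or ref <= 0:
                row[f"{name}_error"] = "reference value undefined"
                row[f"{name}_mean"] = math.nan
                row[f"{name}_vol_ml"] = math.nan
                row[f"{name}_bounded"] = False
                continue
            try:
                mask, bounded = grow_threshold_voi(
                    image, ref, frac, seed_pt, s.center, config.bound_diameter
                )
                st = voi_stats(image, mask)
                row[f"{name}_mean"] = st.mean
                row[f"{name}_vol_ml"] = st.volume_ml
                row[f"{name}_bounded"] = bounded
                row[f"{name}_error"] = ""
            except ValueError as exc:  # seed below threshold etc.
                row[f"{name}_error"] = str(exc)
                row[f"{name}_mean"] = math.nan
                row[f"{name}_vol_ml"] = math.nan
                row[f"{name}_bounded"] = False
        rows.append(row)
    return rows


def _measurement_pass(config: ExperimentConfig) -> pd.DataFrame:
    base = default_phantom(
        config.fill_kbq_ml, 0.0, config.grid_shape, config.voxel_size
    )
    phantoms = make_phantom_series(base, config.ratios)
    raw = []
    for p_idx, spec in enumerate(phantoms):
        truth = rasterize_phantom(
            spec, config.voxel_size, config.grid_shape, config.supersampling
        )
        for v_idx, (vname, variant) in enumerate(sorted(config.variants.items())):
            n_rep = config.replicates.get(spec.label, 1)
            for rep in range(n_rep):
                seed = _rep_seed(config.base_seed, p_idx, v_idx, rep)
                _, image = simulate_phantom(
                    spec, variant, seed=seed, truth=truth,
                    voxel_size=config.voxel_size, grid_shape=config.grid_shape,
                    supersampling=config.supersampling,
                )
                for row in _measure_image(image, spec, config):
                    row.update(phantom=spec.label, variant=vname, rep=rep, seed=seed)
                    raw.append(row)
    return pd.DataFrame(raw)


# ---------------------------------------------------------------------------
# derivation pass
# ---------------------------------------------------------------------------


def _derive(raw: pd.DataFrame, config: ExperimentConfig):
    """Derive RC references/models, growth models and method tables from raw."""
    pinf = raw[raw["c_bkg_true"] == 0]
    if pinf.empty:
        raise ValueError("the experiment needs a background-free phantom (P_inf)")

    # reference activities per (variant, sphere): mean over P_inf replicates
    ref_act = (
        pinf.groupby(["variant", "sphere_d_mm"])["act_dia15_kbq"].mean().rename("ref")
    )
    raw = raw.join(ref_act, on=["variant", "sphere_d_mm"])
    raw["rc"] = raw["act_dia_kbq"] / raw["ref"]

    rc_models, growth_models = {}, {}
    for vname in sorted(config.variants):
        sub = raw[(raw["variant"] == vname) & (raw["c_bkg_true"] == 0)]
        mean_rc = sub.groupby("sphere_d_mm")["rc"].mean()
        try:
            rc_models[vname] = fit_rc(mean_rc.index.to_numpy(), mean_rc.to_numpy())
        except (ValueError, RuntimeError):
            # degenerate data (e.g. unblurred truth with RC = 1 everywhere)
            rc_models[vname] = None
        for mname in THRESHOLD_METHODS:
            ok = sub[
                (sub["sphere_d_mm"] >= config.growth_fit_min_diameter)
                & (sub[f"{mname}_error"] == "")
                & sub[f"{mname}_bounded"]
            ]
            grp = ok.groupby("sphere_d_mm").agg(
                v=("true_volume_ml", "mean"), vv=(f"{mname}_vol_ml", "mean")
            )
            if len(grp) >= 3:
                try:
                    growth_models[(vname, mname)] = fit_volume_growth(
                        grp["v"].to_numpy(), grp["vv"].to_numpy()
                    )
                except (ValueError, RuntimeError):
                    growth_models[(vname, mname)] = None
            else:
                growth_models[(vname, mname)] = None

    spheres = raw.assign(
        max_over_true=raw["max_dia"] / raw["c_true"],
        peak_over_true=raw["peak"] / raw["c_true"],
        contrast=[
            contrast(a, b) for a, b in zip(raw["mean_dia"], raw["c_bkg"])
        ],
        deviation=np.where(
            raw["c_bkg_true"] == 0,
            [
                accuracy_deviation(a, k)
                for a, k in zip(raw["act_dia15_kbq"], raw["true_activity_kbq"])
            ],
            math.nan,
        ),
        sbvr=[
            sbvr(a, b) if b > 0 else math.nan
            for a, b in zip(raw["mean_dia"], raw["c_bkg"])
        ],
        cf=[
            calibration_factor(a, t, config.sensitivity).cf
            for a, t in zip(raw["mean_dia"], raw["c_true"])
        ],
    )

    method_rows = []
    for _, r in raw.iterrows():
        key = dict(
            phantom=r["phantom"], variant=r["variant"], rep=r["rep"],
            sphere_d_mm=r["sphere_d_mm"],
        )
        c_true = r["c_true"]

        def add(method, ratio, bounded=True, excluded=False, error="",
                voi_volume_ml=math.nan):
            method_rows.append(
                {**key, "method": method, "measured_over_true": ratio,
                 "bounded": bounded, "excluded": excluded, "error": error,
                 "voi_volume_ml": voi_volume_ml}
            )

        add("large_voi", r["act_dia15_kbq"] / r["true_activity_kbq"])
        for dv in config.small_voi_diameters:
            v = r[f"small_{dv:g}_mean"]
            add(
                f"small_voi_{dv:g}",
                v / c_true if np.isfinite(v) else math.nan,
                excluded=not np.isfinite(v),
                error="" if np.isfinite(v) else "sphere smaller than VOI",
            )
        for mname in THRESHOLD_METHODS:
            err = r[f"{mname}_error"]
            bounded = bool(r[f"{mname}_bounded"])
            mean_v = r[f"{mname}_mean"]
            vol_v = r[f"{mname}_vol_ml"]
            usable = (err == "") and bounded and np.isfinite(mean_v)
            add(
                mname,
                mean_v / c_true if usable else math.nan,
                bounded=bounded,
                excluded=not usable,
                error=err,
                voi_volume_ml=vol_v,
            )
            gm = growth_models.get((r["variant"], mname))
            if usable and gm is not None and rc_models.get(r["variant"]) is not None:
                res = pvc_correct(mean_v, vol_v, gm, rc_models[r["variant"]])
                add(
                    mname + "_pvc",
                    res.corrected_concentration / c_true
                    if not res.excluded
                    else math.nan,
                    bounded=bounded,
                    excluded=res.excluded,
                    error="V_VOI below fitted V_0" if res.excluded else "",
                    voi_volume_ml=vol_v,
                )
            else:
                add(
                    mname + "_pvc", math.nan, bounded=bounded, excluded=True,
                    error=err or "no growth model", voi_volume_ml=vol_v,
                )
    methods = pd.DataFrame(method_rows)
    sort_cols = ["phantom", "variant", "sphere_d_mm", "method", "rep"]
    methods = methods.sort_values(sort_cols).reset_index(drop=True)
    spheres = spheres.sort_values(
        ["phantom", "variant", "sphere_d_mm", "rep"]
    ).reset_index(drop=True)
    return spheres, methods, rc_models, growth_models


def run_experiment(config: ExperimentConfig | None = None, out_dir=None) -> dict:
    """Run the full sweep and return tidy result tables and fitted models.

    Returns a dict with ``spheres`` (per-sphere metrics), ``methods``
    (per-method measured/true ratios with flags), ``rc_models`` (per
    variant), ``growth_models`` (per variant x threshold method) and the
    config. With ``out_dir`` the tables, fitted models and a run manifest
    are written there (see :func:`report`).
    """
    config = config or ExperimentConfig()
    raw = _measurement_pass(config)
    spheres, methods, rc_models, growth_models = _derive(raw, config)
    results = {
        "spheres": spheres,
        "methods": methods,
        "rc_models": rc_models,
        "growth_models": growth_models,
        "config": config,
    }
    if out_dir is not None:
        report(results, out_dir)
    return results


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def report(results: dict, out_dir) -> list[str]:
    """Write figure-family CSV tables, fitted models and a run manifest.

    Families: max/peak ratios, accuracy deviation, contrast + recovery
    coefficients, small-VOI ratios, threshold ratios, threshold VOI
    volumes, PVC-corrected ratios, and calibration factor vs SBVR and vs
    volume. Output ordering is deterministic; rerunning with the same
    config and seeds reproduces the files byte for byte.
    """
    import pathlib

    spheres: pd.DataFrame = results["spheres"]
    methods: pd.DataFrame = results["methods"]
    if spheres.empty or methods.empty:
        raise ValueError("cannot report empty result tables")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gb = ["phantom", "variant", "sphere_d_mm"]
    written = []

    def fam(name, df):
        p = out / name
        _write(df, p)
        written.append(str(p))

    agg = spheres.groupby(gb, sort=True)
    fam(
        "max_peak.csv",
        agg[["max_over_true", "peak_over_true"]].agg(["mean", "std"]).reset_index(),
    )
    fam(
        "deviation.csv",
        spheres[spheres["c_bkg_true"] == 0]
        .groupby(gb, sort=True)[["deviation"]]
        .agg(["mean", "std"])
        .reset_index(),
    )
    fam(
        "contrast_rc.csv",
        agg[["contrast", "rc"]].agg(["mean", "std"]).reset_index(),
    )

    mg = ["phantom", "variant", "sphere_d_mm", "method"]
    small = methods[methods["method"].str.startswith("small_voi")]
    fam(
        "small_voi.csv",
        small.groupby(mg, sort=True)["measured_over_true"]
        .agg(["mean", "std"])
        .reset_index(),
    )
    thr = methods[
        methods["method"].str.startswith("thr_")
        & ~methods["method"].str.endswith("_pvc")
    ]
    fam(
        "threshold.csv",
        thr.groupby(mg, sort=True)
        .agg(
            mean=("measured_over_true", "mean"),
            std=("measured_over_true", "std"),
            n_bounded=("bounded", "sum"),
            n=("bounded", "size"),
        )
        .reset_index(),
    )
    fam(
        "threshold_volumes.csv",
        thr.groupby(mg, sort=True)["voi_volume_ml"].agg(["mean", "std"]).reset_index(),
    )
    pvc = methods[methods["method"].str.endswith("_pvc")]
    fam(
        "pvc.csv",
        pvc.groupby(mg, sort=True)
        .agg(
            mean=("measured_over_true", "mean"),
            std=("measured_over_true", "std"),
            n_excluded=("excluded", "sum"),
            n=("excluded", "size"),
        )
        .reset_index(),
    )
    sharp = spheres[spheres["variant"] == "sharp"]
    cf_src = sharp if not sharp.empty else spheres
    fam(
        "cf_sbvr.csv",
        cf_src.groupby(gb, sort=True)[["cf", "sbvr"]].agg(["mean", "std"]).reset_index(),
    )
    fam(
        "cf_volume.csv",
        cf_src.groupby(gb + ["true_volume_ml"], sort=True)[["cf"]]
        .agg(["mean", "std"])
        .reset_index(),
    )

    _write(methods, out / "methods.csv")
    _write(spheres, out / "spheres.csv")

    models = {
        "rc": {
            v: (
                {"alpha_mm": m.alpha, "beta": m.beta, "residual_norm": m.residual_norm}
                if m is not None
                else None
            )
            for v, m in sorted(results["rc_models"].items())
        },
        "volume_growth": {
            f"{v}/{t}": (m.to_dict() if m is not None else None)
            for (v, t), m in sorted(results["growth_models"].items())
        },
    }
    (out / "models.json").write_text(json.dumps(models, indent=2, sort_keys=True))
    manifest = {
        "config": results["config"].to_dict(),
        "methods": METHOD_NAMES,
        "n_rows": int(len(methods)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return written
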