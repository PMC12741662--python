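"""End-to-end orchestration: tables in, per-figure quantities out.

Stages: ingest and validate the four input CSVs, fit vessel lengths from
the pneumatic series, derive per-segment anatomy, compute hydraulics at the
configured permeability, calibrate the permeability against the 1:1 line,
fit all scaling relationships, match diameter classes to length classes,
and write a tidy results bundle.  Outputs are a pure function of
(inputs, config): every stochastic statistic is seeded from the config.

Input CSVs may carry lengths/areas in any registry unit by suffixing the
column name (e.g. ``lumen_area_um2`` or ``remaining_length_cm``); columns
are converted to SI on ingest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy as anat
from . import calibration as calib
from . import classes as cls
from . import pneumatron as pneu
from . import stats
from .model import (
    HydraulicConstants,
    PitFieldMeasurement,
    PneumatronSeries,
    SegmentMeta,
    VesselGeometry,
    VesselLengthFit,
    validate_segment_table,
)
from .synthetic import read_fixtures
from .units import _AREAS, _LENGTHS, to_si

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "viscosity_pa_s": 0.001002,
    "permeability_m2": 1.0e-13,
    "pit_membrane_thickness_m": 234e-9,
    "flux_m3_s": 5e-13,
    "k_min_m2": 1e-17,
    "k_max_m2": 1e-11,
    "k_points": 61,
    "class_group_size": 10,
    "seed": 0,
}

#: trait/position pairs fitted by the scaling stage: name -> (x, y) columns
SCALING_PAIRS: dict[str, tuple[str, str]] = {
    "length_vs_diameter": ("mean_diameter_m", "mean_vessel_length_m"),
    "diameter_vs_distance": ("distance_to_tip_m", "mean_diameter_m"),
    "length_vs_distance": ("distance_to_tip_m", "mean_vessel_length_m"),
    "lumen_conductivity_vs_distance": ("distance_to_tip_m", "K_H"),
    "end_wall_conductivity_vs_distance": ("distance_to_tip_m", "K_W"),
    "pit_area_vs_distance": ("distance_to_tip_m", "pit_membrane_area_m2"),
    "pressure_difference_vs_distance": ("distance_to_tip_m", "delta_P"),
    "contact_fraction_vs_distance": ("distance_to_tip_m", "contact_fraction"),
    "pit_field_fraction_vs_distance": ("distance_to_tip_m", "pit_field_fraction"),
}


def load_config(path=None) -> dict:
    """Default constants, optionally overridden by a flat YAML file."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    return config


def constants_from_config(config: dict) -> HydraulicConstants:
    return HydraulicConstants(
        viscosity=config["viscosity_pa_s"],
        permeability=config["permeability_m2"],
        pit_membrane_thickness=config["pit_membrane_thickness_m"],
        flux=config["flux_m3_s"],
    )


def _standardize_units(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Convert any unit-suffixed length/area columns to SI (_m / _m2)."""
    df = df.copy()
    for col in list(df.columns):
        if "_" not in col:
            continue
        base, suffix = col.rsplit("_", 1)
        if suffix in ("m", "m2"):
            continue
        if suffix in _LENGTHS or suffix in _AREAS:
            target = f"{base}_m" if suffix in _LENGTHS else f"{base}_m2"
            if target in df.columns:
                raise ValueError(f"{table}: both {col} and {target} present")
            df[target] = df[col].map(lambda v: to_si(v, suffix))
            df = df.drop(columns=[col])
            logger.info("%s: converted %s -> %s", table, col, target)
    return df


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing columns {missing}")


def ingest(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Validate schemas, convert units to SI, and assign diameter tertiles."""
    tables = {name: _standardize_units(df, name) for name, df in tables.items()}
    _require_columns(
        tables["segments"],
        ["segment_id", "branch_order", "distance_to_tip_m", "segment_length_m", "base_diameter_m"],
        "segments.csv",
    )
    _require_columns(
        tables["pneumatron"],
        ["segment_id", "remaining_length_m", "gas_conductivity"],
        "pneumatron.csv",
    )
    _require_columns(tables["vessels"], ["segment_id", "lumen_area_m2"], "vessels.csv")
    _require_columns(
        tables["pitfields"],
        ["segment_id", "pitfield_id", "contact_perimeter_m", "total_perimeter_m", "pit_field_fraction"],
        "pitfields.csv",
    )
    metas = [
        SegmentMeta(
            segment_id=str(r.segment_id),
            branch_order=int(r.branch_order),
            distance_to_tip=float(r.distance_to_tip_m),
            segment_length=float(r.segment_length_m),
            base_diameter=float(r.base_diameter_m),
        )
        for r in tables["segments"].itertuples()
    ]
    tables["segments"] = validate_segment_table(metas)
    return tables


def fit_vessel_lengths(pneumatron: pd.DataFrame, *, log_fit: bool = True) -> pd.DataFrame:
    """Fit lambda_v and the mean vessel length for every segment."""
    rows = []
    for sid, grp in pneumatron.groupby("segment_id", sort=True):
        grp = grp.sort_values("remaining_length_m", ascending=False)
        series = PneumatronSeries(
            segment_id=str(sid),
            remaining_length=tuple(grp["remaining_length_m"]),
            gas_conductivity=tuple(grp["gas_conductivity"]),
        )
        fit = pneu.fit_lambda(series, log_fit=log_fit)
        rows.append(
            {
                "segment_id": str(sid),
                "lambda_v": fit.lambda_v,
                "mean_vessel_length_m": fit.mean_vessel_length,
                "r2": fit.r_squared,
                "n": fit.n_points,
            }
        )
    return pd.DataFrame(rows)


def derive_anatomy(
    segments: pd.DataFrame,
    vessels: pd.DataFrame,
    pitfields: pd.DataFrame,
    lengths: pd.DataFrame,
    *,
    surface_variant: bool = False,
) -> pd.DataFrame:
    """Per-segment anatomical summary joining vessels, pit fields and lengths."""
    vessel_groups = dict(tuple(vessels.groupby("segment_id", sort=False)))
    pit_groups = dict(tuple(pitfields.groupby("segment_id", sort=False)))
    length_idx = lengths.set_index("segment_id")
    rows = []
    for r in segments.itertuples():
        sid = r.segment_id
        for source, present in (
            ("vessels.csv", sid in vessel_groups),
            ("pitfields.csv", sid in pit_groups),
            ("vessel length fits", sid in length_idx.index),
        ):
            if not present:
                raise ValueError(f"segment {sid} missing from {source}")
        vg = [VesselGeometry.from_area(a) for a in vessel_groups[sid]["lumen_area_m2"]]
        pf = [
            PitFieldMeasurement(
                contact_perimeters=(float(p.contact_perimeter_m),),
                total_perimeters=(float(p.total_perimeter_m),),
                pit_field_fraction=float(p.pit_field_fraction),
            )
            for p in pit_groups[sid].itertuples()
        ]
        lam = float(length_idx.loc[sid, "lambda_v"])
        fit = VesselLengthFit(
            segment_id=sid,
            lambda_v=lam,
            mean_vessel_length=-2.0 / lam,
            r_squared=float(length_idx.loc[sid, "r2"]),
            n_points=int(length_idx.loc[sid, "n"]),
        )
        meta = SegmentMeta(
            segment_id=sid,
            branch_order=int(r.branch_order),
            distance_to_tip=float(r.distance_to_tip_m),
            segment_length=float(r.segment_length_m),
            base_diameter=float(r.base_diameter_m),
            diameter_category=r.diameter_category,
        )
        summary = anat.summarize_segment(vg, pf, fit, meta, surface_variant=surface_variant)
        rows.append(
            {
                "segment_id": sid,
                "branch_order": meta.branch_order,
                "distance_to_tip_m": meta.distance_to_tip,
                "diameter_category": meta.diameter_category,
                "mean_diameter_m": summary.mean_diameter,
                "mean_vessel_length_m": summary.mean_vessel_length,
                "contact_fraction": summary.contact_fraction,
                "pit_field_fraction": summary.pit_field_fraction,
                "pit_fraction": summary.pit_fraction,
                "pit_membrane_area_m2": summary.pit_membrane_area,
                "n_vessels": len(vg),
            }
        )
    return pd.DataFrame(rows)


def _anatomy_objects(anatomy_df: pd.DataFrame) -> list:
    """Rebuild SegmentAnatomy objects from the tabular form."""
    out = []
    for r in anatomy_df.itertuples():
        meta = SegmentMeta(
            segment_id=r.segment_id,
            branch_order=int(r.branch_order),
            distance_to_tip=float(r.distance_to_tip_m),
            segment_length=1.0,  # not used downstream of anatomy
            base_diameter=1.0,
            diameter_category=r.diameter_category,
        )
        out.append(
            anat.SegmentAnatomy(
                meta=meta,
                mean_diameter=float(r.mean_diameter_m),
                mean_vessel_length=float(r.mean_vessel_length_m),
                contact_fraction=float(r.contact_fraction),
                pit_field_fraction=float(r.pit_field_fraction),
                pit_fraction=float(r.pit_fraction),
                pit_membrane_area=float(r.pit_membrane_area_m2),
            )
        )
    return out


def compute_hydraulics(anatomy_df: pd.DataFrame, constants: HydraulicConstants) -> pd.DataFrame:
    """Per-segment K_H, K_W, delta_P, ratio and resistivities (SI)."""
    from .hydraulics import segment_hydraulics

    rows = []
    for a in _anatomy_objects(anatomy_df):
        h = segment_hydraulics(a, constants)
        rows.append(
            {
                "segment_id": h.segment_id,
                "K_H": h.lumen_conductivity,
                "K_W": h.end_wall_conductivity,
                "delta_P": h.end_wall_pressure_difference,
                "ratio": h.ratio,
                "R_H": h.lumen_resistivity,
                "R_W": h.end_wall_resistivity,
            }
        )
    return pd.DataFrame(rows)


def fit_scaling(merged: pd.DataFrame) -> dict:
    """Theil-Sen, Kendall tau and log-log fits for every standard trait pair."""
    fits: dict[str, dict] = {}
    for name, (xcol, ycol) in SCALING_PAIRS.items():
        x = merged[xcol].to_numpy(dtype=float)
        y = merged[ycol].to_numpy(dtype=float)
        try:
            entry = {"theil_sen": asdict(stats.theil_sen(x, y))}
            if np.all(x > 0) and np.all(y > 0):
                entry["loglog"] = asdict(stats.loglog_fit(x, y))
        except ValueError as exc:
            # a degenerate pair (e.g. a constant trait) must not abort the run
            logger.warning("scaling fit %s skipped: %s", name, exc)
            entry = {"skipped": str(exc)}
        fits[name] = entry
    return fits


def group_means(anatomy_df: pd.DataFrame) -> dict:
    """Mean D and mean L_V for the whole tree and per branch order."""
    if "branch_order" not in anatomy_df.columns:
        raise ValueError("anatomy table lacks a branch_order column")
    out = {
        "whole_tree": {
            "mean_diameter_m": float(anatomy_df["mean_diameter_m"].mean()),
            "mean_vessel_length_m": float(anatomy_df["mean_vessel_length_m"].mean()),
            "n": int(len(anatomy_df)),
        }
    }
    for order, grp in anatomy_df.groupby("branch_order", sort=True):
        out[f"order_{order}"] = {
            "mean_diameter_m": float(grp["mean_diameter_m"].mean()),
            "mean_vessel_length_m": float(grp["mean_vessel_length_m"].mean()),
            "n": int(len(grp)),
        }
    return out


def match_classes(
    vessels: pd.DataFrame, lengths: pd.DataFrame, group_size: int = 10
) -> pd.DataFrame:
    """Length-class / diameter-class table for every segment with enough vessels."""
    length_idx = lengths.set_index("segment_id")["mean_vessel_length_m"]
    rows = []
    for sid, grp in vessels.groupby("segment_id", sort=True):
        if sid not in length_idx.index:
            raise ValueError(f"segment {sid} missing from vessel length fits")
        diam = np.sort(anat.equivalent_diameter(grp["lumen_area_m2"].to_numpy()))
        if diam.size < group_size:
            logger.warning("%s: only %d vessels, skipping class matching", sid, diam.size)
            continue
        bounds = cls.build_length_classes(float(length_idx.loc[sid]), diam.size, group_size)
        table = cls.assign_diameters(diam, bounds, group_size)
        for i, ((lo, hi), n, md) in enumerate(
            zip(table.class_bounds, table.diameter_frequencies, table.mean_diameters)
        ):
            rows.append(
                {
                    "segment_id": sid,
                    "class_index": i,
                    "length_low_m": lo,
                    "length_high_m": hi,
                    "n_vessels": n,
                    "mean_diameter_m": md,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config_path=None, input_dir=".", output_dir="results") -> dict:
    """Run every stage on the CSVs in ``input_dir``; write the bundle to ``output_dir``.

    Returns the report dictionary (group means, calibration and ratio
    summaries, paths of all written artifacts).
    """
    t0 = time.monotonic()
    config = load_config(config_path)
    constants = constants_from_config(config)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        logger.info("stage %-16s done at %.2fs", name, time.monotonic() - t0)
        return result

    tables = stage("ingest", lambda: ingest(read_fixtures(input_dir)))
    lengths = stage("vessel_length", fit_vessel_lengths, tables["pneumatron"])
    anatomy_df = stage(
        "anatomy",
        derive_anatomy,
        tables["segments"],
        tables["vessels"],
        tables["pitfields"],
        lengths,
    )
    hydraulics_df = stage("hydraulics", compute_hydraulics, anatomy_df, constants)

    k_grid = np.logspace(
        np.log10(config["k_min_m2"]), np.log10(config["k_max_m2"]), int(config["k_points"])
    )
    calibration = stage(
        "calibration",
        calib.calibrate_permeability,
        _anatomy_objects(anatomy_df),
        constants,
        k_grid,
    )
    calibrated = calib.recompute_with_k(
        _anatomy_objects(anatomy_df), constants, calibration.best_k
    )
    _, ratio_summary = calib.ratio_profile(calibrated)

    merged = anatomy_df.merge(hydraulics_df, on="segment_id")
    scaling_fits = stage("scaling", fit_scaling, merged)
    classes_df = stage(
        "class_matching", match_classes, tables["vessels"], lengths, int(config["class_group_size"])
    )
    means = stage("group_means", group_means, anatomy_df)

    lengths.to_csv(output_dir / "vessel_length.csv", index=False)
    anatomy_df.to_csv(output_dir / "anatomy.csv", index=False)
    hydraulics_df.to_csv(output_dir / "hydraulics.csv", index=False)
    pd.DataFrame(
        {"k_m2": calibration.k_grid, "rmsd_log10": calibration.rmsd_per_k}
    ).to_csv(output_dir / "calibration.csv", index=False)
    classes_df.to_csv(output_dir / "classes.csv", index=False)
    with open(output_dir / "scaling_fits.json", "w") as fh:
        json.dump(scaling_fits, fh, indent=2, sort_keys=True)
    ratio_bundle = {
        "at_calibrated_k": ratio_summary,
        "best_k_m2": calibration.best_k,
        "best_rmsd_log10": calibration.best_rmsd,
    }
    with open(output_dir / "ratio_summary.json", "w") as fh:
        json.dump(ratio_bundle, fh, indent=2, sort_keys=True)

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = {
        "group_means": means,
        "calibration": {
            "best_k_m2": calibration.best_k,
            "best_rmsd_log10": calibration.best_rmsd,
        },
        "ratio_summary": ratio_summary,
        "config_hash": config_hash,
        "seed": config["seed"],
        "n_segments": int(len(anatomy_df)),
    }
    with open(output_dir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.2fs", time.monotonic() - t0)
    return report
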