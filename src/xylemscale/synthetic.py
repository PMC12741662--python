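"""Synthetic sapling generator with the statistical structure the analysis assumes.

The generator emulates a ~2.75 m sapling sampled exhaustively: a main stem
plus 20 lateral branches, divided into 58 segments in total, each segment
carrying a few hundred vessel diameters, a pneumatic trimming series, and a
handful of pit-field measurements.  The planted structure is:

* tip-to-base vessel widening as a softened power law,
  D(d) = tip_diameter * (1 + d/d0)**b, with d the distance from the tip of
  the segment's own branch and d0 a small reference distance keeping tip
  diameters finite;
* vessel lengthening proportional to widening, L_V = a * D;
* exponential decay of gas conductivity in remaining segment length with
  rate lambda_v = -2/L_V;
* weak axial trends in the inter-vessel contact fraction and pit-field
  fraction.

All noise is multiplicative lognormal (mean 1, given CV), guaranteeing
positivity; fractions get truncated Gaussian noise.  Everything is driven
by one seeded generator so a tree is a pure function of its parameters.

An optional "planted identity" mode chooses per-segment contact fractions
so that end-wall conductivity equals lumen conductivity exactly at a known
permeability k0 — the ground truth for calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    PitFieldMeasurement,
    PneumatronSeries,
    SegmentMeta,
    VesselGeometry,
)

DEFAULT_TIP_DIAMETER = 1.05e-5  # m; ~10.5 um vessels right behind an apex
DEFAULT_LENGTHENING_SLOPE = 2530.0  # L_V/D; 22.5 um vessels ~ 5.7 cm long


@dataclass(frozen=True)
class TreeGenParams:
    """Generator settings; defaults reproduce the study-scale sapling."""

    n_branches: int = 20
    segments_per_branch: tuple[int, int] = (2, 8)
    main_stem_segments: int = 8
    total_segments: int = 58
    max_path_length: float = 2.75
    widening_exponent: float = 0.2
    widening_ref_distance: float = 0.01
    tip_diameter: float = DEFAULT_TIP_DIAMETER
    lengthening_slope: float = DEFAULT_LENGTHENING_SLOPE
    diameter_cv: float = 0.3
    vessels_per_segment: tuple[int, int] = (333, 1000)
    f_c_mean: float = 0.20
    f_c_sd: float = 0.02
    f_pf_mean: float = 0.50
    f_pf_sd: float = 0.05
    f_c_axial_trend: float = 0.10  # weak relative increase tip -> base
    f_pf_axial_trend: float = -0.05
    pneumatron_noise_cv: float = 0.05
    pneumatron_points: int = 10
    pitfields_per_segment: tuple[int, int] = (3, 5)
    vessels_per_pitfield: int = 10
    seed: int = 0
    planted_k: float | None = None
    pit_membrane_thickness: float = 234e-9  # only used by the planted mode

    def __post_init__(self) -> None:
        positives = (
            self.n_branches,
            self.max_path_length,
            self.widening_ref_distance,
            self.tip_diameter,
            self.lengthening_slope,
            self.f_c_mean,
            self.f_pf_mean,
            self.pit_membrane_thickness,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all scale parameters must be strictly positive")
        if self.widening_exponent < 0:
            raise ValueError("widening_exponent must be >= 0")
        for cv in (self.diameter_cv, self.pneumatron_noise_cv):
            if not 0 <= cv < 1:
                raise ValueError("CVs must lie in [0, 1)")
        if self.planted_k is not None and self.planted_k <= 0:
            raise ValueError("planted_k must be > 0")


@dataclass
class SyntheticTree:
    """A generated sapling: metadata, ground truth, and measurement tables."""

    params: TreeGenParams
    segments: list[SegmentMeta]
    true_mean_diameter: dict[str, float]
    true_mean_length: dict[str, float]
    true_contact_fraction: dict[str, float]
    true_pit_field_fraction: dict[str, float]
    vessel_tables: dict[str, list[VesselGeometry]] = field(default_factory=dict)
    pneumatron_tables: dict[str, PneumatronSeries] = field(default_factory=dict)
    pitfield_tables: dict[str, list[PitFieldMeasurement]] = field(default_factory=dict)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def true_diameter(distance: float, params: TreeGenParams) -> float:
    """Widening law: tip_diameter * (1 + distance/d0)**b."""
    return params.tip_diameter * (1.0 + distance / params.widening_ref_distance) ** params.widening_exponent


def simulate_vessel_diameters(
    n: int, mean_d: float, cv: float, seed
) -> list[VesselGeometry]:
    """Draw n lognormal vessel diameters with the given mean and CV.

    Lumen areas are the circle areas of the drawn diameters, so the
    diameter/area pair is internally consistent.
    """
    if n < 1:
        raise ValueError("need n >= 1 vessels")
    if mean_d <= 0:
        raise ValueError("mean diameter must be > 0")
    rng = np.random.default_rng(seed)
    d = mean_d * _lognormal_factor(rng, cv, size=n)
    return [VesselGeometry(lumen_area=math.pi * di**2 / 4.0, equivalent_diameter=di) for di in d]


def simulate_pneumatron(
    true_l_v: float,
    trim_lengths,
    noise_cv: float,
    seed,
    segment_id: str = "synthetic",
    c0: float = 1.0,
) -> PneumatronSeries:
    """Exponential gas-conductivity series for a segment of known mean vessel length.

    C(x) = c0 * exp(lambda_v * x) * lognormal(1, noise_cv) with
    lambda_v = -2/true_l_v, evaluated at the decreasing remaining lengths.
    """
    if true_l_v <= 0:
        raise ValueError("true mean vessel length must be > 0")
    x = np.asarray(trim_lengths, dtype=float)
    if np.any(x <= 0):
        raise ValueError("trim lengths must be positive")
    if not np.all(np.diff(x) < 0):
        raise ValueError("trim lengths must be strictly decreasing")
    rng = np.random.default_rng(seed)
    lam = -2.0 / true_l_v
    c = c0 * np.exp(lam * x) * _lognormal_factor(rng, noise_cv, size=x.size)
    return PneumatronSeries(
        segment_id=segment_id,
        remaining_length=tuple(x),
        gas_conductivity=tuple(c),
    )


def _allocate_branch_segments(params: TreeGenParams, rng: np.random.Generator) -> list[int]:
    """Segment counts per branch, adjusted to hit the total segment budget."""
    lo, hi = params.segments_per_branch
    counts = list(rng.integers(lo, hi + 1, size=params.n_branches))
    target = params.total_segments - params.main_stem_segments
    if not params.n_branches * lo <= target <= params.n_branches * hi:
        raise ValueError("total_segments unreachable with segments_per_branch range")
    i = 0
    while sum(counts) > target:
        if counts[i % params.n_branches] > lo:
            counts[i % params.n_branches] -= 1
        i += 1
    while sum(counts) < target:
        if counts[i % params.n_branches] < hi:
            counts[i % params.n_branches] += 1
        i += 1
    return [int(c) for c in counts]


def _segment_lengths(path_length: float, n_segments: int) -> np.ndarray:
    """Split a branch path into segments, shorter near the tip, longer at the base."""
    weights = np.linspace(1.0, 3.0, n_segments)
    return path_length * weights / weights.sum()


def _planted_contact_fraction(d: float, l_v: float, params: TreeGenParams) -> float:
    """F_C making end-wall conductivity equal lumen conductivity at planted_k.

    Solves k * F_C^2 * F_PF * D * L_V / T_PM = pi D^4/(128 L_V) for F_C,
    with F_PF held at its mean.
    """
    assert params.planted_k is not None
    fc2 = (
        math.pi
        * d**3
        * params.pit_membrane_thickness
        / (128.0 * l_v**2 * params.planted_k * params.f_pf_mean)
    )
    fc = math.sqrt(fc2)
    if not 0 < fc <= 1:
        raise ValueError(
            f"planted_k={params.planted_k} needs contact fraction {fc:.3g} outside (0, 1]"
        )
    return fc


def generate_tree(params: TreeGenParams) -> SyntheticTree:
    """Generate the full synthetic sapling, reproducible under the seed."""
    rng = np.random.default_rng(params.seed)

    # branch layout: branch 0 is the main stem; ~70% of laterals first order
    branch_counts = _allocate_branch_segments(params, rng)
    n_first = max(1, round(0.7 * params.n_branches))
    paths: list[tuple[int, int, float, int]] = [
        (0, 0, params.max_path_length, params.main_stem_segments)
    ]
    for b in range(params.n_branches):
        order = 1 if b < n_first else 2
        length = (
            rng.uniform(0.4, 1.4) if order == 1 else rng.uniform(0.15, 0.6)
        )
        paths.append((b + 1, order, float(length), branch_counts[b]))

    segments: list[SegmentMeta] = []
    truth_d: dict[str, float] = {}
    truth_l: dict[str, float] = {}
    truth_fc: dict[str, float] = {}
    truth_fpf: dict[str, float] = {}
    vessel_tables: dict[str, list[VesselGeometry]] = {}
    pneu_tables: dict[str, PneumatronSeries] = {}
    pit_tables: dict[str, list[PitFieldMeasurement]] = {}

    for branch_id, order, path_length, n_seg in paths:
        seg_lengths = _segment_lengths(path_length, n_seg)
        base_dists = np.cumsum(seg_lengths)
        for s, (seg_len, dist) in enumerate(zip(seg_lengths, base_dists), start=1):
            sid = f"B{branch_id:02d}S{s}"
            d_true = true_diameter(float(dist), params)
            l_true = params.lengthening_slope * d_true
            rel = dist / params.max_path_length
            if params.planted_k is not None:
                fc_true = _planted_contact_fraction(d_true, l_true, params)
                fpf_true = params.f_pf_mean
            else:
                fc_true = params.f_c_mean * (1.0 + params.f_c_axial_trend * rel)
                fpf_true = params.f_pf_mean * (1.0 + params.f_pf_axial_trend * rel)
            meta = SegmentMeta(
                segment_id=sid,
                branch_order=order,
                distance_to_tip=float(dist),
                segment_length=float(seg_len),
                base_diameter=0.002 * (1.0 + dist / params.widening_ref_distance) ** 0.3,
            )
            segments.append(meta)
            truth_d[sid] = d_true
            truth_l[sid] = l_true
            truth_fc[sid] = fc_true
            truth_fpf[sid] = fpf_true

            n_vessels = int(rng.integers(*params.vessels_per_segment, endpoint=True))
            vessel_tables[sid] = simulate_vessel_diameters(
                n_vessels, d_true, params.diameter_cv, rng
            )

            trim = np.linspace(seg_len, seg_len / params.pneumatron_points, params.pneumatron_points)
            pneu_tables[sid] = simulate_pneumatron(
                l_true, trim, params.pneumatron_noise_cv, rng, segment_id=sid
            )

            n_pf = int(rng.integers(*params.pitfields_per_segment, endpoint=True))
            fields = []
            for _ in range(n_pf):
                pv = (
                    math.pi
                    * d_true
                    * _lognormal_factor(rng, params.diameter_cv, size=params.vessels_per_pitfield)
                )
                if params.f_c_sd > 0:
                    fc_field = float(np.clip(rng.normal(fc_true, params.f_c_sd), 0.01, 0.95))
                else:
                    fc_field = fc_true
                if params.f_pf_sd > 0:
                    fpf_field = float(np.clip(rng.normal(fpf_true, params.f_pf_sd), 0.01, 0.99))
                else:
                    fpf_field = fpf_true
                fields.append(
                    PitFieldMeasurement(
                        contact_perimeters=tuple(fc_field * pv),
                        total_perimeters=tuple(pv),
                        pit_field_fraction=fpf_field,
                    )
                )
            pit_tables[sid] = fields

    return SyntheticTree(
        params=params,
        segments=segments,
        true_mean_diameter=truth_d,
        true_mean_length=truth_l,
        true_contact_fraction=truth_fc,
        true_pit_field_fraction=truth_fpf,
        vessel_tables=vessel_tables,
        pneumatron_tables=pneu_tables,
        pitfield_tables=pit_tables,
    )


def tree_tables(tree: SyntheticTree) -> dict[str, pd.DataFrame]:
    """Flatten a tree into the four tabular interfaces of the pipeline."""
    segments = pd.DataFrame(
        {
            "segment_id": [m.segment_id for m in tree.segments],
            "branch_order": [m.branch_order for m in tree.segments],
            "distance_to_tip_m": [m.distance_to_tip for m in tree.segments],
            "segment_length_m": [m.segment_length for m in tree.segments],
            "base_diameter_m": [m.base_diameter for m in tree.segments],
        }
    )
    pneumatron = pd.concat(
        [
            pd.DataFrame(
                {
                    "segment_id": sid,
                    "remaining_length_m": series.remaining_length,
                    "gas_conductivity": series.gas_conductivity,
                }
            )
            for sid, series in tree.pneumatron_tables.items()
        ],
        ignore_index=True,
    )
    vessels = pd.concat(
        [
            pd.DataFrame(
                {"segment_id": sid, "lumen_area_m2": [v.lumen_area for v in vs]}
            )
            for sid, vs in tree.vessel_tables.items()
        ],
        ignore_index=True,
    )
    pit_rows = []
    for sid, fields in tree.pitfield_tables.items():
        for i, pf in enumerate(fields, start=1):
            pit_rows.append(
                {
                    "segment_id": sid,
                    "pitfield_id": i,
                    "contact_perimeter_m": sum(pf.contact_perimeters),
                    "total_perimeter_m": sum(pf.total_perimeters),
                    "pit_field_fraction": pf.pit_field_fraction,
                }
            )
    return {
        "segments": segments,
        "pneumatron": pneumatron,
        "vessels": vessels,
        "pitfields": pd.DataFrame(pit_rows),
    }


def write_fixtures(tree: SyntheticTree, directory) -> dict[str, Path]:
    """Write segments/pneumatron/vessels/pitfields CSVs for the pipeline."""
    if not tree.segments:
        raise ValueError("tree has no segments")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tree_tables(tree).items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_fixtures(directory) -> dict[str, pd.DataFrame]:
    """Read the four pipeline CSVs back into DataFrames."""
    directory = Path(directory)
    out = {}
    for name in ("segments", "pneumatron", "vessels", "pitfields"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table {path}")
        out[name] = pd.read_csv(path)
    return out


def planted_params(k0: float = 1e-18, **overrides) -> TreeGenParams:
    """Noise-free parameters with the identity K_W == K_H planted at k0."""
    defaults = dict(
        planted_k=k0,
        diameter_cv=0.0,
        pneumatron_noise_cv=0.0,
        f_c_sd=0.0,
        f_pf_sd=0.0,
    )
    defaults.update(overrides)
    return TreeGenParams(**defaults)
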