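"""Domain types shared by every stage of the analysis.

All quantities are strict SI: lengths in metres, areas in square metres,
conductivities in m3 Pa-1 s-1, pressures in Pa.  A segment is one piece of
stem or branch cut for the pneumatic vessel-length measurement; its base
cross-section supplies the vessel diameters and pit-field measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIAMETER_CATEGORIES = ("small", "intermediate", "large")


@dataclass(frozen=True)
class SegmentMeta:
    """Position and size metadata of one sampled segment.

    branch_order is 0 for the main stem, 1 and 2 for lateral branches;
    distance_to_tip is measured along the axis from the apical tip of the
    segment's own branch (or the main stem) to the segment base.
    """

    segment_id: str
    branch_order: int
    distance_to_tip: float
    segment_length: float
    base_diameter: float
    diameter_category: str | None = None

    def __post_init__(self) -> None:
        if self.distance_to_tip < 0:
            raise ValueError(f"{self.segment_id}: distance_to_tip must be >= 0")
        if self.segment_length <= 0:
            raise ValueError(f"{self.segment_id}: segment_length must be > 0")
        if self.base_diameter <= 0:
            raise ValueError(f"{self.segment_id}: base_diameter must be > 0")
        if self.diameter_category is not None and self.diameter_category not in DIAMETER_CATEGORIES:
            raise ValueError(f"unknown diameter_category {self.diameter_category!r}")


@dataclass(frozen=True)
class PneumatronSeries:
    """Gas conductivity measured while a segment is trimmed shorter.

    remaining_length holds the successively shorter segment lengths x (m,
    strictly decreasing); gas_conductivity the positive conductances read at
    each length, in any consistent unit (only the decay rate matters).
    """

    segment_id: str
    remaining_length: tuple[float, ...]
    gas_conductivity: tuple[float, ...]

    def __post_init__(self) -> None:
        x = np.asarray(self.remaining_length, dtype=float)
        c = np.asarray(self.gas_conductivity, dtype=float)
        if x.size != c.size:
            raise ValueError(f"{self.segment_id}: length/conductivity size mismatch")
        if x.size < 3:
            raise ValueError(f"{self.segment_id}: need >= 3 trimming points, got {x.size}")
        if not np.all(np.diff(x) < 0):
            raise ValueError(f"{self.segment_id}: remaining_length must be strictly decreasing")
        if np.any(x <= 0):
            raise ValueError(f"{self.segment_id}: remaining lengths must be positive")
        if np.any(c <= 0):
            raise ValueError(f"{self.segment_id}: gas conductivities must be positive")


@dataclass(frozen=True)
class VesselLengthFit:
    """Result of fitting the exponential decay of gas conductivity.

    lambda_v (1/m, negative) is the decay slope of log conductivity in
    remaining length; the mean vessel length is -2/lambda_v.
    """

    segment_id: str
    lambda_v: float
    mean_vessel_length: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.lambda_v >= 0:
            raise ValueError("lambda_v must be negative (decaying series)")
        if not math.isclose(self.mean_vessel_length, -2.0 / self.lambda_v, rel_tol=1e-12):
            raise ValueError("mean_vessel_length must equal -2/lambda_v")


@dataclass(frozen=True)
class VesselGeometry:
    """A single vessel lumen: area and the equivalent circle diameter."""

    lumen_area: float
    equivalent_diameter: float

    def __post_init__(self) -> None:
        if self.lumen_area <= 0:
            raise ValueError("lumen_area must be > 0")

    @classmethod
    def from_area(cls, lumen_area: float) -> "VesselGeometry":
        return cls(lumen_area, math.sqrt(4.0 * lumen_area / math.pi))


@dataclass(frozen=True)
class PitFieldMeasurement:
    """One SEM pit-field observation on a segment.

    contact_perimeters (L_VW) and total_perimeters (P_V) are per-vessel
    perimeter measurements in the field of view; pit_field_fraction is the
    fraction of inter-vessel wall occupied by pits in this field.
    """

    contact_perimeters: tuple[float, ...]
    total_perimeters: tuple[float, ...]
    pit_field_fraction: float

    def __post_init__(self) -> None:
        lvw = np.asarray(self.contact_perimeters, dtype=float)
        pv = np.asarray(self.total_perimeters, dtype=float)
        if lvw.size != pv.size:
            raise ValueError("contact/total perimeter size mismatch")
        if np.any(lvw < 0) or np.any(pv <= 0):
            raise ValueError("perimeters must be positive (contact may be 0)")
        if np.any(lvw > pv * (1 + 1e-12)):
            raise ValueError("contact perimeter cannot exceed total perimeter")
        if not 0.0 <= self.pit_field_fraction <= 1.0:
            raise ValueError("pit_field_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentAnatomy:
    """Per-segment anatomical summary feeding the hydraulic formulas."""

    meta: SegmentMeta
    mean_diameter: float
    mean_vessel_length: float
    contact_fraction: float
    pit_field_fraction: float
    pit_fraction: float
    pit_membrane_area: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pit_fraction <= self.contact_fraction <= 1.0:
            raise ValueError("need 0 <= F_P <= F_C <= 1")
        if self.pit_membrane_area < 0:
            raise ValueError("pit_membrane_area must be >= 0")


@dataclass(frozen=True)
class HydraulicConstants:
    """Physical constants shared by all hydraulic computations.

    viscosity: dynamic viscosity of water at 20 C (Pa s).
    permeability: pit membrane permeability k (m2), the one free parameter,
        calibratable against the 1:1 lumen/end-wall relationship.
    pit_membrane_thickness: T_PM (m), assumed axially constant.
    flux: volumetric flux Q (m3/s) across end walls used for the pressure
        difference safety proxy.
    """

    viscosity: float = 0.001002
    permeability: float = 1.0e-13
    pit_membrane_thickness: float = 234e-9
    flux: float = 5e-13

    def __post_init__(self) -> None:
        for name in ("viscosity", "permeability", "pit_membrane_thickness", "flux"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SegmentHydraulics:
    """Computed hydraulic quantities of one segment."""

    segment_id: str
    lumen_conductivity: float
    end_wall_conductivity: float
    end_wall_pressure_difference: float
    ratio: float = field(default=float("nan"))
    lumen_resistivity: float = field(default=float("nan"))
    end_wall_resistivity: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.lumen_conductivity <= 0 or self.end_wall_conductivity <= 0:
            raise ValueError("conductivities must be > 0")
        object.__setattr__(self, "ratio", self.lumen_conductivity / self.end_wall_conductivity)
        object.__setattr__(self, "lumen_resistivity", 1.0 / self.lumen_conductivity)
        object.__setattr__(self, "end_wall_resistivity", 1.0 / self.end_wall_conductivity)


def assign_diameter_categories(base_diameters: pd.Series) -> pd.Series:
    """Split segments into small/intermediate/large tertiles of base diameter.

    The split is by rank so the three category sizes differ by at most one;
    ties in diameter are broken by a stable sort on segment id (the index).
    """
    order = base_diameters.reset_index(drop=True)
    idx = np.argsort(order.to_numpy(), kind="stable")
    n = len(order)
    sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
    cats = np.empty(n, dtype=object)
    start = 0
    for size, name in zip(sizes, DIAMETER_CATEGORIES):
        cats[idx[start : start + size]] = name
        start += size
    return pd.Series(cats, index=base_diameters.index, name="diameter_category")


def validate_segment_table(rows: list[SegmentMeta]) -> pd.DataFrame:
    """Validate segment metadata and assign diameter tertile categories.

    Raises on an empty table or duplicate segment ids (each SegmentMeta has
    already checked its own positivity invariants on construction).
    """
    if not rows:
        raise ValueError("segment table is empty")
    ids = [r.segment_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate segment ids: {dupes}")
    df = pd.DataFrame(
        {
            "segment_id": ids,
            "branch_order": [r.branch_order for r in rows],
            "distance_to_tip_m": [r.distance_to_tip for r in rows],
            "segment_length_m": [r.segment_length for r in rows],
            "base_diameter_m": [r.base_diameter for r in rows],
        }
    )
    df = df.sort_values("segment_id", kind="stable").reset_index(drop=True)
    df["diameter_category"] = assign_diameter_categories(df["base_diameter_m"])
    return df
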