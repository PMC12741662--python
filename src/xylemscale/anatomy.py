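"""Per-segment anatomical traits: D, F_C, F_P and pit membrane area A_P.

From transverse-section lumen areas and SEM pit-field perimeters we derive,
per segment: the mean equivalent circle diameter D, the inter-vessel contact
fraction F_C (shared perimeter over total perimeter), the pit fraction
F_P = F_C * F_PF, and the total inter-vessel pit membrane area per vessel

    A_P = F_C * F_P * D * L_V.

A_P as defined above is the product form used throughout this analysis; a
"surface-area" variant pi * D * L_V * F_P (pit area on the lateral surface
of a cylindrical vessel) is available behind a flag for sensitivity checks.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .model import (
    PitFieldMeasurement,
    SegmentAnatomy,
    SegmentMeta,
    VesselGeometry,
    VesselLengthFit,
)


def equivalent_diameter(lumen_area):
    """Equivalent circle diameter sqrt(4A/pi) of a lumen area (scalar or array)."""
    a = np.asarray(lumen_area, dtype=float)
    if np.any(a <= 0):
        raise ValueError("lumen area must be > 0")
    d = np.sqrt(4.0 * a / math.pi)
    return float(d) if d.ndim == 0 else d


def contact_fraction(pitfields: Sequence[PitFieldMeasurement]) -> float:
    """Inter-vessel contact fraction: sum(L_VW) / sum(P_V) over all pit fields."""
    if not pitfields:
        raise ValueError("need at least one pit field")
    lvw = sum(sum(pf.contact_perimeters) for pf in pitfields)
    pv = sum(sum(pf.total_perimeters) for pf in pitfields)
    if pv <= 0:
        raise ValueError("total conduit perimeter must be > 0")
    fc = lvw / pv
    if not 0.0 <= fc <= 1.0:  # guarded already by per-field invariants
        raise ValueError(f"contact fraction {fc} outside [0, 1]")
    return fc


def pit_fraction(f_c: float, f_pf: float) -> float:
    """Pit fraction F_P = F_C * F_PF (pit area per total vessel wall)."""
    if not 0.0 <= f_c <= 1.0:
        raise ValueError(f"F_C must lie in [0, 1], got {f_c}")
    if not 0.0 <= f_pf <= 1.0:
        raise ValueError(f"F_PF must lie in [0, 1], got {f_pf}")
    return f_c * f_pf


def pit_membrane_area(
    f_c: float,
    f_p: float,
    diameter: float,
    vessel_length: float,
    *,
    surface_variant: bool = False,
) -> float:
    """Total inter-vessel pit membrane area per vessel (m2).

    Default is the product form F_C * F_P * D * L_V.  With
    ``surface_variant=True`` returns pi * D * L_V * F_P, i.e. the pit
    fraction applied to the lateral surface of a cylinder of diameter D and
    length L_V.
    """
    if not 0.0 <= f_c <= 1.0 or not 0.0 <= f_p <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    if diameter <= 0 or vessel_length <= 0:
        raise ValueError("D and L_V must be > 0")
    if surface_variant:
        return math.pi * diameter * vessel_length * f_p
    return f_c * f_p * diameter * vessel_length


def summarize_segment(
    vessels: Sequence[VesselGeometry],
    pitfields: Sequence[PitFieldMeasurement],
    length_fit: VesselLengthFit,
    meta: SegmentMeta,
    *,
    surface_variant: bool = False,
) -> SegmentAnatomy:
    """Chain the anatomical formulas into one per-segment summary.

    Mean diameter is the arithmetic mean of per-vessel equivalent diameters;
    F_PF is the unweighted mean over pit fields.
    """
    if not vessels:
        raise ValueError(f"{meta.segment_id}: no vessels")
    if not pitfields:
        raise ValueError(f"{meta.segment_id}: no pit fields")
    mean_d = float(np.mean([v.equivalent_diameter for v in vessels]))
    f_c = contact_fraction(pitfields)
    f_pf = float(np.mean([pf.pit_field_fraction for pf in pitfields]))
    f_p = pit_fraction(f_c, f_pf)
    l_v = length_fit.mean_vessel_length
    a_p = pit_membrane_area(f_c, f_p, mean_d, l_v, surface_variant=surface_variant)
    return SegmentAnatomy(
        meta=meta,
        mean_diameter=mean_d,
        mean_vessel_length=l_v,
        contact_fraction=f_c,
        pit_field_fraction=f_pf,
        pit_fraction=f_p,
        pit_membrane_area=a_p,
    )
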