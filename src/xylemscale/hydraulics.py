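"""Lumen and end-wall conductivity per segment, and the end-wall pressure drop.

The vessel lumen behaves as a Hagen-Poiseuille capillary normalised to the
mean vessel length:

    K_H = pi * D**4 / (128 * mu * L_V)          [m3 Pa-1 s-1]

The end wall is a Darcy porous medium — the pit membranes of total area A_P,
thickness T_PM and permeability k:

    K_W = k * A_P / (mu * T_PM)                 [m3 Pa-1 s-1]

At a constant volumetric flux Q, the pressure drop across the end wall is

    dP = mu * T_PM * Q / (k * A_P) = Q / K_W    [Pa]

which serves as a hydraulic-safety proxy.  Resistivities are reciprocals of
the conductivities.  Note that with all quantities in strict SI the default
permeability places K_W orders of magnitude above K_H for realistic
anatomies; k is therefore treated as calibratable (see the calibration
module) rather than as a trusted physical constant.
"""

from __future__ import annotations

import math

from .model import HydraulicConstants, SegmentAnatomy, SegmentHydraulics


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")


def lumen_conductivity(diameter: float, vessel_length: float, mu: float) -> float:
    """Hagen-Poiseuille lumen conductivity pi*D^4 / (128*mu*L_V)."""
    _require_positive(diameter=diameter, vessel_length=vessel_length, mu=mu)
    return math.pi * diameter**4 / (128.0 * mu * vessel_length)


def end_wall_conductivity(k: float, pit_area: float, mu: float, t_pm: float) -> float:
    """Darcy end-wall conductivity k*A_P / (mu*T_PM)."""
    _require_positive(k=k, pit_area=pit_area, mu=mu, t_pm=t_pm)
    return k * pit_area / (mu * t_pm)


def end_wall_pressure_difference(
    mu: float, t_pm: float, flux: float, k: float, pit_area: float
) -> float:
    """Pressure drop mu*T_PM*Q / (k*A_P) across the end wall at flux Q."""
    _require_positive(mu=mu, t_pm=t_pm, flux=flux, k=k, pit_area=pit_area)
    return mu * t_pm * flux / (k * pit_area)


def segment_hydraulics(
    anatomy: SegmentAnatomy, constants: HydraulicConstants
) -> SegmentHydraulics:
    """Assemble all hydraulic quantities for one segment."""
    if anatomy.pit_membrane_area <= 0:
        raise ValueError(
            f"{anatomy.meta.segment_id}: end wall undefined for A_P = 0"
        )
    k_h = lumen_conductivity(
        anatomy.mean_diameter, anatomy.mean_vessel_length, constants.viscosity
    )
    k_w = end_wall_conductivity(
        constants.permeability,
        anatomy.pit_membrane_area,
        constants.viscosity,
        constants.pit_membrane_thickness,
    )
    dp = end_wall_pressure_difference(
        constants.viscosity,
        constants.pit_membrane_thickness,
        constants.flux,
        constants.permeability,
        anatomy.pit_membrane_area,
    )
    return SegmentHydraulics(
        segment_id=anatomy.meta.segment_id,
        lumen_conductivity=k_h,
        end_wall_conductivity=k_w,
        end_wall_pressure_difference=dp,
    )
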