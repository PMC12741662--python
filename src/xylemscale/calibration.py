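"""Calibrate the pit membrane permeability k against the 1:1 line.

K_W is linear in k while K_H does not depend on it, so in log10 space
changing k shifts every log10(K_W) by the same amount.  The calibration
scans a log-spaced grid of k values, recomputes K_W per segment at each,
and measures the deviation of (log10 K_W, log10 K_H) from the identity line
by the root mean square deviation

    RMSD = sqrt(mean((log10 K_H - log10 K_W)**2))    [log10 units]

returning the grid k minimising it (ties to the smaller k).  Because the
objective is convex in log10(k), a reasonably fine grid locates the optimum
to grid resolution, which keeps the procedure auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hydraulics import end_wall_conductivity, lumen_conductivity, segment_hydraulics
from .model import HydraulicConstants, SegmentAnatomy, SegmentHydraulics

#: default grid: log-spaced from 1e-17 to 1e-11 m2, 61 points (10 per decade)
DEFAULT_K_GRID = tuple(np.logspace(-17, -11, 61))


@dataclass(frozen=True)
class CalibrationResult:
    k_grid: tuple[float, ...]
    rmsd_per_k: tuple[float, ...]
    best_k: float
    best_rmsd: float

    def __post_init__(self) -> None:
        if self.best_k not in self.k_grid:
            raise ValueError("best_k must be a grid point")
        if not np.isclose(self.best_rmsd, min(self.rmsd_per_k)):
            raise ValueError("best_rmsd must be the grid minimum")


def rmsd_to_identity(x: Sequence[float], y: Sequence[float]) -> float:
    """Root mean square vertical deviation of (x, y) points from y = x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def calibrate_permeability(
    anatomies: Sequence[SegmentAnatomy],
    constants: HydraulicConstants,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
) -> CalibrationResult:
    """Grid-search k for the best fit of log10 K_W vs log10 K_H to the 1:1 line.

    K_H per segment is fixed by anatomy; K_W is recomputed at every k in the
    grid.  Requires >= 2 segments so that "fit to the identity line" is more
    than an exactly solvable equation.
    """
    k_grid = tuple(float(k) for k in k_grid)
    if not k_grid:
        raise ValueError("k grid is empty")
    if any(k <= 0 for k in k_grid):
        raise ValueError("k grid must be positive")
    if list(k_grid) != sorted(k_grid):
        raise ValueError("k grid must be sorted ascending")
    if len(anatomies) < 2:
        raise ValueError("need at least 2 segments to calibrate")

    log_kh = np.array(
        [
            np.log10(
                lumen_conductivity(a.mean_diameter, a.mean_vessel_length, constants.viscosity)
            )
            for a in anatomies
        ]
    )
    # log10 K_W at k = 1; adding log10(k) gives the value at any k
    log_kw_unit = np.array(
        [
            np.log10(
                end_wall_conductivity(
                    1.0, a.pit_membrane_area, constants.viscosity, constants.pit_membrane_thickness
                )
            )
            for a in anatomies
        ]
    )
    rmsds = tuple(
        rmsd_to_identity(log_kw_unit + np.log10(k), log_kh) for k in k_grid
    )
    best_idx = int(np.argmin(rmsds))  # argmin takes the first == smallest k on ties
    return CalibrationResult(
        k_grid=k_grid,
        rmsd_per_k=rmsds,
        best_k=k_grid[best_idx],
        best_rmsd=rmsds[best_idx],
    )


def ratio_profile(
    hydraulics: Sequence[SegmentHydraulics],
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-segment K_H/K_W ratio plus (min, max, median) summary."""
    if not hydraulics:
        raise ValueError("need at least one segment")
    ratios = {h.segment_id: h.ratio for h in hydraulics}
    values = np.array(list(ratios.values()))
    summary = {
        "min": float(values.min()),
        "max": float(values.max()),
        "median": float(np.median(values)),
    }
    return ratios, summary


def recompute_with_k(
    anatomies: Sequence[SegmentAnatomy], constants: HydraulicConstants, k: float
) -> list[SegmentHydraulics]:
    """Hydraulics for all segments with the permeability replaced by ``k``."""
    consts = HydraulicConstants(
        viscosity=constants.viscosity,
        permeability=k,
        pit_membrane_thickness=constants.pit_membrane_thickness,
        flux=constants.flux,
    )
    return [segment_hydraulics(a, consts) for a in anatomies]
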