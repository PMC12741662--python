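"""Relate vessel-diameter classes to plausible vessel-length classes.

Only the mean vessel length of a segment is measured directly; individual
vessel lengths are not.  Under the premise that wide vessels tend to be
long, the sorted vessel diameters of a segment can be mapped onto a
monotone ladder of length classes: class bounds span one-third to three
times the mean vessel length (mean and maximum length assumed linearly
related), each class nominally holds ``group_size`` vessels, and the sorted
diameters are assigned to ascending classes in contiguous rank blocks.
Classes that receive no vessel are dropped from the output table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class LengthClassTable:
    """Length-class bounds with the diameters assigned to each class."""

    class_bounds: tuple[tuple[float, float], ...]
    group_size: int
    diameter_frequencies: tuple[int, ...]
    mean_diameters: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.class_bounds) != len(self.diameter_frequencies):
            raise ValueError("bounds/frequencies length mismatch")
        if any(f <= 0 for f in self.diameter_frequencies):
            raise ValueError("zero-frequency classes must be omitted")


def build_length_classes(
    mean_l_v: float, n_vessels: int, group_size: int = 10
) -> tuple[tuple[float, float], ...]:
    """Evenly spaced vessel-length class bounds from L_V/3 to 3*L_V.

    The number of classes is ceil(n_vessels / group_size); bounds are
    contiguous intervals on the length axis.
    """
    if mean_l_v <= 0:
        raise ValueError("mean vessel length must be > 0")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if n_vessels < group_size:
        raise ValueError(
            f"need at least one full group: n_vessels={n_vessels} < group_size={group_size}"
        )
    n_classes = math.ceil(n_vessels / group_size)
    edges = np.linspace(mean_l_v / 3.0, 3.0 * mean_l_v, n_classes + 1)
    return tuple((float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:]))


def assign_diameters(
    diameters: Sequence[float],
    classes: Sequence[tuple[float, float]],
    group_size: int = 10,
) -> LengthClassTable:
    """Partition sorted diameters into rank blocks matched to ascending classes.

    The smallest ``group_size`` diameters go to the shortest length class,
    the next block to the next class, and so on; the final block may be
    smaller.  Ties in diameter keep input order (stable).  Requires the
    diameters to be sorted ascending.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty diameter list")
    if not classes:
        raise ValueError("need at least one class")
    if np.any(np.diff(d) < 0):
        raise ValueError("diameters must be sorted ascending")

    bounds, freqs, means = [], [], []
    for idx, interval in enumerate(classes):
        block = d[idx * group_size : (idx + 1) * group_size]
        if block.size == 0:
            continue  # zero-frequency classes are omitted
        bounds.append(interval)
        freqs.append(int(block.size))
        means.append(float(block.mean()))
    assigned = sum(freqs)
    if assigned < d.size:
        raise ValueError(
            f"{d.size - assigned} diameters beyond the last class: "
            "build classes from the same n_vessels"
        )
    return LengthClassTable(
        class_bounds=tuple(bounds),
        group_size=group_size,
        diameter_frequencies=tuple(freqs),
        mean_diameters=tuple(means),
    )
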