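"""Numerical summaries of selections and cross-position projections."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .elements import ElementSet, StructuralElement
from .geometry import normalize_angle

__all__ = [
    "SelectionStats",
    "selection_stats",
    "circular_mean",
    "anti_pairs",
    "superimpose_positions",
]


@dataclass(frozen=True)
class SelectionStats:
    mean_x: float
    mean_y: float
    slope: Optional[float]
    n: int


def selection_stats(points: Sequence[tuple[float, float]]) -> SelectionStats:
    """Arithmetic means of window coordinates and the OLS slope of y on x.

    Means are plain arithmetic averages of the coordinates as displayed
    (i.e. after any axis-window remapping has been applied by the
    caller), not circular means; the slope is the ordinary least-squares
    regression slope, ``None`` when all x coincide.
    """
    if len(points) == 0:
        raise ValueError("selection_stats requires at least one point")
    arr = np.asarray(points, dtype=float)
    mean_x, mean_y = arr.mean(axis=0)
    slope: Optional[float] = None
    if len(arr) >= 2 and not np.allclose(arr[:, 0], arr[0, 0]):
        slope = float(sp_stats.linregress(arr[:, 0], arr[:, 1]).slope)
    return SelectionStats(float(mean_x), float(mean_y), slope, len(arr))


def circular_mean(angles: Sequence[float]) -> Optional[float]:
    """Direction of the resultant of unit vectors, in (-180, 180] degrees.

    Offered alongside the window-arithmetic mean of
    :func:`selection_stats` as a wrap-safe alternative.  Returns ``None``
    when the resultant length is below 1e-12 (no preferred direction).
    """
    angles = [a for a in angles]
    if not angles:
        raise ValueError("circular_mean requires at least one angle")
    radians = np.radians(np.asarray(angles, dtype=float))
    x = float(np.cos(radians).mean())
    y = float(np.sin(radians).mean())
    if math.hypot(x, y) < 1e-12:
        return None
    return normalize_angle(math.degrees(math.atan2(y, x)))


def anti_pairs(element: StructuralElement) -> list[tuple[Optional[float], Optional[float]]]:
    """The n-1 pairs (psi_i, phi_{i+1}) spanning each peptide bond.

    These are the angle pairs flanking the peptide bond rather than the
    alpha-carbon; a pair with an undefined member keeps the ``None``.
    """
    return [
        (element.conformations[i].psi, element.conformations[i + 1].phi)
        for i in range(element.n - 1)
    ]


def superimpose_positions(
    element_set: ElementSet,
    positions: Sequence[int],
) -> list[list[tuple[Optional[float], Optional[float]]]]:
    """One (phi, psi) point layer per requested position, in the given order.

    Later layers are meant to overdraw earlier ones when rendered;
    omitting a position suppresses its layer entirely.
    """
    if len(positions) == 0:
        raise ValueError("at least one position is required")
    for p in positions:
        if not 1 <= p <= element_set.n:
            raise ValueError(f"position {p} outside 1..{element_set.n}")
    return [
        [(e.conformations[p - 1].phi, e.conformations[p - 1].psi) for e in element_set]
        for p in positions
    ]
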