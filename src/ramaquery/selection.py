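"""Marquee selection on periodic dihedral planes.

Dihedral angles live on a circle, so a conformational cluster can
straddle the +/-180 seam of a fixed plot.  Every marquee therefore
carries its own 360-degree axis windows: angles are remapped into
[origin, origin + 360) before the point-in-region test, which lets a
single rectangle or ellipse capture a wrapped cluster.  Inverting a
marquee selects the points outside it; points with an undefined
coordinate are never selected either way, mirroring the fact that an
unplotted point cannot be swept over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .elements import ElementSet, StructuralElement

__all__ = ["AxisWindow", "Marquee", "remap", "select_marquee", "highlight_mode", "PLANES"]

PLANES = ("phipsi", "phichi", "anti")


@dataclass(frozen=True)
class AxisWindow:
    """A 360-degree axis interval [origin, origin + 360)."""

    origin: float = -180.0

    def __post_init__(self):
        if not np.isfinite(self.origin):
            raise ValueError("window origin must be finite")


def remap(angle: Optional[float], window: AxisWindow) -> Optional[float]:
    """Representative of *angle* (mod 360) inside *window*; None passes through."""
    if angle is None:
        return None
    return window.origin + (angle - window.origin) % 360.0


@dataclass(frozen=True)
class Marquee:
    """A rectangular or elliptical query region on one position's dihedral plane.

    ``plane`` selects the coordinate pair at ``position`` (1-based):
    ``phipsi`` -> (phi, psi), ``phichi`` -> (phi, chi1), ``anti`` ->
    (psi at position, phi at position + 1).  The bounding box
    (x0, x1, y0, y1) is expressed in window coordinates and must fit
    inside the 360-degree windows.
    """

    shape: str  # "rect" | "ellipse"
    position: int
    plane: str = "phipsi"
    x0: float = -180.0
    x1: float = 180.0
    y0: float = -180.0
    y1: float = 180.0
    x_window: AxisWindow = field(default_factory=AxisWindow)
    y_window: AxisWindow = field(default_factory=AxisWindow)
    inverted: bool = False

    def __post_init__(self):
        if self.shape not in ("rect", "ellipse"):
            raise ValueError(f"unknown marquee shape {self.shape!r}")
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError("marquee box must have x0 < x1 and y0 < y1")
        for lo, hi, window in ((self.x0, self.x1, self.x_window), (self.y0, self.y1, self.y_window)):
            if lo < window.origin or hi > window.origin + 360.0:
                raise ValueError("marquee box must lie within its 360-degree axis window")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    def coordinates(self, element: StructuralElement) -> tuple[Optional[float], Optional[float]]:
        """The raw (x, y) angle pair this marquee examines on *element*."""
        if self.plane == "anti":
            if self.position > element.n - 1:
                raise ValueError(f"anti plane position must be <= {element.n - 1}")
            return (
                element.conformation(self.position).psi,
                element.conformation(self.position + 1).phi,
            )
        conf = element.conformation(self.position)
        return (conf.phi, conf.psi) if self.plane == "phipsi" else (conf.phi, conf.chi1)

    def contains(self, x: float, y: float) -> bool:
        """Point-in-region test on window coordinates; boundaries inclusive."""
        if self.shape == "rect":
            return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1
        cx, cy = (self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0
        rx, ry = (self.x1 - self.x0) / 2.0, (self.y1 - self.y0) / 2.0
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def select_marquee(element_set: ElementSet, marquee: Marquee) -> np.ndarray:
    """Boolean mask of elements whose remapped angle pair lies in the marquee.

    Elements with either coordinate undefined are never selected;
    inversion flips the result only for fully defined pairs.
    """
    max_pos = element_set.n - 1 if marquee.plane == "anti" else element_set.n
    if marquee.position > max_pos:
        raise ValueError(f"position {marquee.position} outside 1..{max_pos} for plane {marquee.plane!r}")
    mask = np.zeros(len(element_set), dtype=bool)
    for idx, element in enumerate(element_set):
        x, y = marquee.coordinates(element)
        if x is None or y is None:
            continue
        inside = marquee.contains(remap(x, marquee.x_window), remap(y, marquee.y_window))
        mask[idx] = inside != marquee.inverted
    return mask


def highlight_mode(
    element_set: ElementSet,
    position: int,
    aa: str,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Display masks (highlight, shown) for one amino acid at one position.

    ``include``: everything shown, matching elements highlighted;
    ``exclude``: matching elements hidden, nothing highlighted;
    ``sole``: only matching elements shown (and highlighted).
    """
    if not 1 <= position <= element_set.n:
        raise ValueError(f"position {position} outside 1..{element_set.n}")
    if mode not in ("include", "exclude", "sole"):
        raise ValueError(f"unknown highlight mode {mode!r}")
    has_aa = np.array([e.sequence[position - 1] == aa for e in element_set], dtype=bool)
    all_on = np.ones(len(element_set), dtype=bool)
    if mode == "include":
        return has_aa, all_on
    if mode == "exclude":
        return np.zeros(len(element_set), dtype=bool), ~has_aa
    return has_aa, has_aa.copy()
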