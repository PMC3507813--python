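"""Named Ramachandran regions and proline ring pucker.

The four default regions (alphaR, alphaL, betaR, betaL) are rectangular
phi/psi boxes treated as half-open intervals [min, max), which makes the
partition unambiguous at the boundaries; the defaults are pairwise
disjoint.  Users may supply their own region table (e.g. to add a zeta
region) as a TSV config file.

Proline pucker is classified from chi1 alone: the two ring states
correspond to opposite chi1 signs.  Which sign is called UP versus DOWN
is a convention, configurable via ``down_positive``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "RegionDef",
    "DEFAULT_REGIONS",
    "classify_region",
    "classify_pucker",
    "read_regions",
]


@dataclass(frozen=True)
class RegionDef:
    name: str
    phi_min: float
    phi_max: float
    psi_min: float
    psi_max: float

    def __post_init__(self):
        if not (self.phi_min < self.phi_max and self.psi_min < self.psi_max):
            raise ValueError(f"region {self.name!r}: min must be below max")
        for v in (self.phi_min, self.phi_max, self.psi_min, self.psi_max):
            if not -180.0 <= v <= 180.0:
                raise ValueError(f"region {self.name!r}: bounds must lie in [-180, 180]")

    def contains(self, phi: float, psi: float) -> bool:
        return (self.phi_min <= phi < self.phi_max) and (self.psi_min <= psi < self.psi_max)

    @property
    def centre(self) -> tuple[float, float]:
        return ((self.phi_min + self.phi_max) / 2.0, (self.psi_min + self.psi_max) / 2.0)


DEFAULT_REGIONS: tuple[RegionDef, ...] = (
    RegionDef("alphaL", 20.0, 140.0, -40.0, 90.0),
    RegionDef("alphaR", -140.0, -20.0, -90.0, 40.0),
    RegionDef("betaL", 20.0, 160.0, -180.0, -80.0),
    RegionDef("betaR", -160.0, -20.0, 80.0, 180.0),
)


def classify_region(
    phi: Optional[float],
    psi: Optional[float],
    regions: Sequence[RegionDef] = DEFAULT_REGIONS,
) -> Optional[str]:
    """Name of the first region containing (phi, psi); ``"other"`` if none.

    Returns ``None`` (undefined, distinct from "other") when either angle
    is undefined.
    """
    if phi is None or psi is None:
        return None
    for region in regions:
        if region.contains(phi, psi):
            return region.name
    return "other"


def classify_pucker(
    chi1: Optional[float],
    *,
    boundary: float = 60.0,
    down_positive: bool = True,
) -> Optional[str]:
    """Classify a proline ring as ``"UP"`` or ``"DOWN"`` from chi1.

    With the default convention, DOWN is chi1 in (0, boundary] and UP is
    chi1 in [-boundary, 0); ``down_positive=False`` swaps the labels.
    Returns ``None`` for undefined chi1 or chi1 outside both windows.
    """
    if chi1 is None:
        return None
    if 0.0 < chi1 <= boundary:
        return "DOWN" if down_positive else "UP"
    if -boundary <= chi1 < 0.0:
        return "UP" if down_positive else "DOWN"
    return None


def read_regions(path: os.PathLike | str) -> list[RegionDef]:
    """Read a region table: TSV ``name phi_min phi_max psi_min psi_max``.

    Blank lines and ``#`` comments are skipped.
    """
    regions: list[RegionDef] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 tab-separated fields")
            try:
                regions.append(RegionDef(parts[0], *(float(p) for p in parts[1:])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if not regions:
        raise ValueError(f"{path}: no regions defined")
    return regions
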