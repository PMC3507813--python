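"""Structural elements: n-mer extraction, template and pattern matching.

An element is a contiguous window of 2-9 residues taken from a chain,
carrying its provenance, 1-letter sequence and per-position dihedrals.
All queries on an :class:`ElementSet` return boolean masks over its
elements, so successive refinements compose with numpy logic (AND, OR,
NOT) without re-reading anything.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .geometry import ResidueConformation, circular_difference, is_consecutive, residue_dihedrals
from .structure_io import ChainModel

__all__ = [
    "MIN_N",
    "MAX_N",
    "DEFAULT_TOL",
    "StructuralElement",
    "ElementSet",
    "AngleTemplate",
    "SequencePattern",
    "extract_nmers",
    "match_template",
    "filter_pattern",
    "composition",
    "read_template",
]

MIN_N = 2
MAX_N = 9  # the longest query peptide supported
DEFAULT_TOL = 40.0  # half-width (degrees) of a template angle window
WILDCARD = "-"


@dataclass(frozen=True)
class StructuralElement:
    source_id: str
    chain_id: str
    start: str  # author residue number of position 1, with insertion code
    sequence: str
    conformations: tuple[ResidueConformation, ...]

    def __post_init__(self):
        n = len(self.sequence)
        if not MIN_N <= n <= MAX_N:
            raise ValueError(f"element length {n} outside {MIN_N}-{MAX_N}")
        if len(self.conformations) != n:
            raise ValueError("sequence and conformations must have equal length")
        object.__setattr__(self, "conformations", tuple(self.conformations))

    @property
    def n(self) -> int:
        return len(self.sequence)

    def conformation(self, position: int) -> ResidueConformation:
        """Per-position conformation, positions numbered 1..n."""
        if not 1 <= position <= self.n:
            raise ValueError(f"position {position} outside 1..{self.n}")
        return self.conformations[position - 1]


@dataclass
class ElementSet:
    """Uniform-length collection of elements; the unit all queries act on."""

    n: int
    elements: list[StructuralElement] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        if not MIN_N <= self.n <= MAX_N:
            raise ValueError(f"element length {self.n} outside {MIN_N}-{MAX_N}")
        for e in self.elements:
            if e.n != self.n:
                raise ValueError(f"element of length {e.n} in a set of length {self.n}")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def subset(self, mask: Sequence[bool]) -> "ElementSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self.elements),):
            raise ValueError("mask length must equal the number of elements")
        return ElementSet(
            n=self.n,
            elements=[e for e, keep in zip(self.elements, mask) if keep],
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class AngleTemplate:
    """Per-position (phi, psi) targets with a shared tolerance half-width.

    ``constraints`` holds one ``(phi_target, psi_target)`` pair per
    position 1..n; either member may be ``None`` (wildcard), as may whole
    positions.  Only main-chain angles are constrainable.
    """

    constraints: tuple[tuple[Optional[float], Optional[float]], ...]
    tol: float = DEFAULT_TOL

    def __post_init__(self):
        object.__setattr__(self, "constraints", tuple(tuple(c) for c in self.constraints))
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if all(phi is None and psi is None for phi, psi in self.constraints):
            raise ValueError("template must constrain at least one angle")

    @property
    def n(self) -> int:
        return len(self.constraints)


@dataclass(frozen=True)
class SequencePattern:
    """Include/exclude sequence patterns; ``-`` is the wildcard."""

    include: str
    exclude: str = ""

    def __post_init__(self):
        if not self.exclude:
            object.__setattr__(self, "exclude", WILDCARD * len(self.include))
        if len(self.include) != len(self.exclude):
            raise ValueError("include and exclude patterns must have equal length")

    @property
    def n(self) -> int:
        return len(self.include)


def extract_nmers(chains: Iterable[ChainModel], n: int) -> ElementSet:
    """All break-free windows of *n* consecutive residues, in file order.

    Dihedrals are computed per residue on the full chain, so phi/psi at a
    window edge can still be defined via neighbours outside the window.
    """
    if not MIN_N <= n <= MAX_N:
        raise ValueError(f"element length must be {MIN_N}-{MAX_N}, got {n}")
    elements: list[StructuralElement] = []
    sources: list[str] = []
    for chain in chains:
        sources.append(f"{chain.source_id}/{chain.chain_id}")
        if len(chain) < n:
            continue
        dihedrals = [residue_dihedrals(chain, i) for i in range(len(chain))]
        contiguous = [is_consecutive(chain, i) for i in range(len(chain) - 1)]
        for start in range(len(chain) - n + 1):
            if not all(contiguous[start : start + n - 1]):
                continue
            window = chain.residues[start : start + n]
            elements.append(
                StructuralElement(
                    source_id=chain.source_id,
                    chain_id=chain.chain_id,
                    start=window[0].start_label,
                    sequence="".join(chain.sequence[start : start + n]),
                    conformations=tuple(dihedrals[start : start + n]),
                )
            )
    return ElementSet(n=n, elements=elements, provenance=f"extract_nmers(n={n}) from {', '.join(sources)}")


def match_template(element_set: ElementSet, template: AngleTemplate) -> np.ndarray:
    """Boolean mask: element matches iff every constrained angle is defined
    and within ``template.tol`` of its target by circular difference."""
    if template.n != element_set.n:
        raise ValueError(f"template length {template.n} != element length {element_set.n}")
    mask = np.empty(len(element_set), dtype=bool)
    for idx, element in enumerate(element_set):
        ok = True
        for conf, (phi_t, psi_t) in zip(element.conformations, template.constraints):
            for target, value in ((phi_t, conf.phi), (psi_t, conf.psi)):
                if target is None:
                    continue
                if value is None or circular_difference(value, target) > template.tol:
                    ok = False
                    break
            if not ok:
                break
        mask[idx] = ok
    return mask


def filter_pattern(element_set: ElementSet, pattern: SequencePattern) -> np.ndarray:
    """Boolean mask: all include positions present AND no exclude position present."""
    if pattern.n != element_set.n:
        raise ValueError(f"pattern length {pattern.n} != element length {element_set.n}")
    mask = np.empty(len(element_set), dtype=bool)
    for idx, element in enumerate(element_set):
        seq = element.sequence
        ok = all(p == WILDCARD or p == s for p, s in zip(pattern.include, seq)) and not any(
            p != WILDCARD and p == s for p, s in zip(pattern.exclude, seq)
        )
        mask[idx] = ok
    return mask


def composition(
    element_set: ElementSet,
    position: int,
    mask: Optional[Sequence[bool]] = None,
) -> Counter:
    """Amino-acid counts at *position* (1..n) over the (masked) elements."""
    if not 1 <= position <= element_set.n:
        raise ValueError(f"position {position} outside 1..{element_set.n}")
    if mask is None:
        selected = element_set.elements
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(element_set),):
            raise ValueError("mask length must equal the number of elements")
        selected = [e for e, keep in zip(element_set, mask) if keep]
    return Counter(e.sequence[position - 1] for e in selected)


def read_template(path: os.PathLike | str, n: int, tol: float = DEFAULT_TOL) -> AngleTemplate:
    """Read a template file: TSV ``position phi psi``, ``*`` for wildcard.

    Positions absent from the file are unconstrained.  Blank lines and
    ``#`` comments are skipped.
    """
    constraints: list[tuple[Optional[float], Optional[float]]] = [(None, None)] * n
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected position<TAB>phi<TAB>psi")
            try:
                position = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad position {parts[0]!r}") from exc
            if not 1 <= position <= n:
                raise ValueError(f"{path}: line {lineno}: position {position} outside 1..{n}")

            def parse(tok: str) -> Optional[float]:
                return None if tok.strip() == "*" else float(tok)

            try:
                constraints[position - 1] = (parse(parts[1]), parse(parts[2]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad angle value") from exc
    return AngleTemplate(constraints=tuple(constraints), tol=tol)
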