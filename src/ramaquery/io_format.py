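"""The element-table text format and export listings.

The on-disk format (version ``SMV1``) is this package's own: a
tab-separated UTF-8 table with a version/length header, one row per
element, and per-position phi/psi/chi1 columns at fixed 2-decimal
precision with ``NA`` for undefined angles.  Writing is canonical, so
write -> read -> write is byte-identical.

Example (n=2)::

    #SMV1	n=2
    source	chain	start	seq	phi_1	psi_1	chi1_1	phi_2	psi_2	chi1_2
    2CBP	A	5	AG	NA	-47.00	-60.00	-57.00	NA	NA
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np

from .elements import MAX_N, MIN_N, ElementSet, StructuralElement
from .geometry import ResidueConformation

__all__ = ["FormatError", "write_elements", "read_elements", "write_listing", "MAGIC"]

MAGIC = "#SMV1"
_FIXED_COLUMNS = ["source", "chain", "start", "seq"]


class FormatError(ValueError):
    """Malformed element file; the message names the offending line."""


def _format_angle(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.2f}"


def _masked(element_set: ElementSet, mask: Optional[Sequence[bool]]) -> list[StructuralElement]:
    if mask is None:
        return list(element_set.elements)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(element_set),):
        raise ValueError("mask length must equal the number of elements")
    return [e for e, keep in zip(element_set, mask) if keep]


def _header_columns(n: int) -> list[str]:
    columns = list(_FIXED_COLUMNS)
    for k in range(1, n + 1):
        columns += [f"phi_{k}", f"psi_{k}", f"chi1_{k}"]
    return columns


def write_elements(
    element_set: ElementSet,
    path: os.PathLike | str,
    mask: Optional[Sequence[bool]] = None,
) -> None:
    """Write the (masked) elements as an SMV1 table; empty selection is an error."""
    selected = _masked(element_set, mask)
    if not selected:
        raise ValueError("refusing to write an empty element selection")
    n = element_set.n
    lines = [f"{MAGIC}\tn={n}", "\t".join(_header_columns(n))]
    for e in selected:
        row = [e.source_id, e.chain_id, e.start, e.sequence]
        for conf in e.conformations:
            row += [_format_angle(conf.phi), _format_angle(conf.psi), _format_angle(conf.chi1)]
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def _parse_angle(token: str, path: str, lineno: int) -> Optional[float]:
    if token == "NA":
        return None
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"{path}: line {lineno}: bad angle value {token!r}") from None


def read_elements(path: os.PathLike | str) -> ElementSet:
    """Read an SMV1 element table back into an :class:`ElementSet`."""
    path = os.fspath(path)
    with open(path, encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: line 1: empty file")
    header = lines[0].split("\t")
    if len(header) != 2 or header[0] != MAGIC or not header[1].startswith("n="):
        raise FormatError(f"{path}: line 1: expected header '{MAGIC}<TAB>n=<n>'")
    try:
        n = int(header[1][2:])
    except ValueError:
        raise FormatError(f"{path}: line 1: bad element length {header[1]!r}") from None
    if not MIN_N <= n <= MAX_N:
        raise FormatError(f"{path}: line 1: element length must be {MIN_N}-{MAX_N}, got {n}")
    if len(lines) < 2 or lines[1].split("\t") != _header_columns(n):
        raise FormatError(f"{path}: line 2: bad column header for n={n}")

    expected_cols = len(_FIXED_COLUMNS) + 3 * n
    elements: list[StructuralElement] = []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != expected_cols:
            raise FormatError(
                f"{path}: line {lineno}: expected {expected_cols} columns, got {len(fields)}"
            )
        source, chain, start, seq = fields[:4]
        if len(seq) != n:
            raise FormatError(f"{path}: line {lineno}: sequence length {len(seq)} != n={n}")
        conformations = []
        for k in range(n):
            phi, psi, chi1 = (
                _parse_angle(tok, path, lineno) for tok in fields[4 + 3 * k : 7 + 3 * k]
            )
            conformations.append(ResidueConformation(phi=phi, psi=psi, chi1=chi1))
        elements.append(
            StructuralElement(
                source_id=source, chain_id=chain, start=start,
                sequence=seq, conformations=tuple(conformations),
            )
        )
    return ElementSet(n=n, elements=elements, provenance=f"read from {path}")


def write_listing(
    element_set: ElementSet,
    path: os.PathLike | str,
    style: str = "located",
    mask: Optional[Sequence[bool]] = None,
) -> None:
    """Write a human-readable listing of the (masked) elements.

    ``located`` gives ``source<TAB>chain<TAB>start<TAB>seq`` per element;
    ``plain`` gives the bare sequence strings, one per line, for
    downstream computational use.
    """
    if style not in ("located", "plain"):
        raise ValueError(f"unknown listing style {style!r}")
    selected = _masked(element_set, mask)
    if not selected:
        raise ValueError("refusing to write an empty listing")
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        for e in selected:
            if style == "plain":
                handle.write(e.sequence + "\n")
            else:
                handle.write(f"{e.source_id}\t{e.chain_id}\t{e.start}\t{e.sequence}\n")
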