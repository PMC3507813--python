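"""Static rendering of dihedral scatter plots and superimpositions.

Four plot modes mirror the analysis views: ``phipsi`` (one Ramachandran
panel per position), ``phichi`` (chi1 against phi), ``phipsichi`` (a
linked composite with a phi-psi row above a phi-chi1 row), and
``antiphipsi`` (psi at position i against phi at position i+1, one panel
per peptide bond).  Selected points are drawn over unselected ones in a
contrasting colour; both colours are configurable (e.g. for impaired
colour vision).  The chi1 axis of the composite defaults to the window
[-120, 240) so the trans rotamer is not split across the +/-180 seam.
"""

from __future__ import annotations

import math
import os
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .elements import AngleTemplate, ElementSet
from .selection import AxisWindow, remap

__all__ = ["plot_elements", "plot_superimposed", "PLOT_MODES", "CHI_AXIS_DEFAULT"]

PLOT_MODES = ("phipsi", "phichi", "phipsichi", "antiphipsi")

# Default chi1 axis window of the composite view: keeps the trans rotamer
# (chi1 ~ 180) contiguous instead of split at the plot edge.
CHI_AXIS_DEFAULT = AxisWindow(-120.0)
DEFAULT_WINDOW = AxisWindow(-180.0)

UNSELECTED_COLOR = "red"
SELECTED_COLOR = "blue"


def _panel_points(element_set, mode: str, panel: int):
    """(x, y) angle pairs of one panel; panel is 0-based."""
    if mode == "antiphipsi":
        return [
            (e.conformations[panel].psi, e.conformations[panel + 1].phi) for e in element_set
        ]
    pairs = []
    for e in element_set:
        conf = e.conformations[panel]
        pairs.append((conf.phi, conf.psi) if mode == "phipsi" else (conf.phi, conf.chi1))
    return pairs


def _subsample_mask(n_points: int, sample: Optional[int], seed: Optional[int]) -> np.ndarray:
    keep = np.ones(n_points, dtype=bool)
    if sample is not None and sample > 1 and n_points:
        rng = np.random.default_rng(seed)
        kept = rng.choice(n_points, size=math.ceil(n_points / sample), replace=False)
        keep = np.zeros(n_points, dtype=bool)
        keep[kept] = True
    return keep


def _scatter_panel(ax, points, mask, x_window, y_window, colors, keep):
    xs = np.array([remap(p[0], x_window) if p[0] is not None else np.nan for p in points])
    ys = np.array([remap(p[1], y_window) if p[1] is not None else np.nan for p in points])
    defined = ~(np.isnan(xs) | np.isnan(ys)) & keep
    unsel = defined & ~mask
    sel = defined & mask
    ax.scatter(xs[unsel], ys[unsel], s=6, c=colors[0], linewidths=0)
    ax.scatter(xs[sel], ys[sel], s=6, c=colors[1], linewidths=0)
    ax.set_xlim(x_window.origin, x_window.origin + 360.0)
    ax.set_ylim(y_window.origin, y_window.origin + 360.0)


def _overlay_constraints(ax, template: AngleTemplate, panel: int) -> None:
    phi_t, psi_t = template.constraints[panel]
    for target, line in ((phi_t, ax.axvline), (psi_t, ax.axhline)):
        if target is not None:
            line(target - template.tol, color="grey", linewidth=0.8)
            line(target + template.tol, color="grey", linewidth=0.8)


def plot_elements(
    element_set: ElementSet,
    path: os.PathLike | str,
    mode: str = "phipsi",
    mask: Optional[Sequence[bool]] = None,
    colors: tuple[str, str] = (UNSELECTED_COLOR, SELECTED_COLOR),
    overlay_template: Optional[AngleTemplate] = None,
    sample: Optional[int] = None,
    seed: Optional[int] = None,
    x_windows: Optional[Sequence[AxisWindow]] = None,
    y_windows: Optional[Sequence[AxisWindow]] = None,
):
    """Render one panel per position (n-1 for ``antiphipsi``) to *path*.

    ``mask`` paints selected points in ``colors[1]`` over the rest in
    ``colors[0]``; ``sample`` keeps ceil(m/sample) points, chosen
    deterministically from ``seed``; per-panel axis windows may be
    overridden.  Returns the matplotlib Figure (also saved to *path*).
    """
    if mode not in PLOT_MODES:
        raise ValueError(f"unknown plot mode {mode!r}")
    if len(element_set) == 0:
        raise ValueError("cannot plot an empty element set")
    n = element_set.n
    n_panels = n - 1 if mode == "antiphipsi" else n
    mask = (
        np.zeros(len(element_set), dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool)
    )
    keep = _subsample_mask(len(element_set), sample, seed)

    n_rows = 2 if mode == "phipsichi" else 1
    fig, axes = plt.subplots(
        n_rows, n_panels, figsize=(2.4 * n_panels, 2.6 * n_rows), squeeze=False
    )
    for panel in range(n_panels):
        if mode == "phipsichi":
            rows = [("phipsi", axes[0][panel], DEFAULT_WINDOW), ("phichi", axes[1][panel], CHI_AXIS_DEFAULT)]
        elif mode == "phichi":
            rows = [("phichi", axes[0][panel], DEFAULT_WINDOW)]
        else:
            rows = [(mode, axes[0][panel], DEFAULT_WINDOW)]
        for sub_mode, ax, default_y in rows:
            x_window = x_windows[panel] if x_windows else DEFAULT_WINDOW
            y_window = y_windows[panel] if y_windows else default_y
            points = _panel_points(element_set, sub_mode, panel)
            _scatter_panel(ax, points, mask, x_window, y_window, colors, keep)
            if overlay_template is not None and sub_mode in ("phipsi", "antiphipsi"):
                _overlay_constraints(ax, overlay_template, panel)
            ax.set_title(f"pos {panel + 1}" + ("-" + str(panel + 2) if mode == "antiphipsi" else ""),
                         fontsize=8)
    fig.tight_layout()
    fig.savefig(os.fspath(path))
    return fig


def plot_superimposed(
    layers: Sequence[Sequence[tuple[Optional[float], Optional[float]]]],
    path: os.PathLike | str,
    colors: Optional[Sequence[str]] = None,
    x_window: AxisWindow = DEFAULT_WINDOW,
    y_window: AxisWindow = DEFAULT_WINDOW,
):
    """Draw point layers on a single phi/psi axes, later layers over earlier.

    The draw order is the layer order, so the last layer is fully
    visible and earlier ones may be occluded where they coincide.
    """
    if len(layers) == 0:
        raise ValueError("at least one layer is required")
    if colors is None:
        cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
        colors = [cycle[i % len(cycle)] for i in range(len(layers))]
    if len(colors) < len(layers):
        raise ValueError("need one colour per layer")
    fig, ax = plt.subplots(figsize=(4, 4))
    for layer, color in zip(layers, colors):
        pts = [
            (remap(x, x_window), remap(y, y_window))
            for x, y in layer
            if x is not None and y is not None
        ]
        if pts:
            arr = np.asarray(pts)
            ax.scatter(arr[:, 0], arr[:, 1], s=10, c=color, linewidths=0)
    ax.set_xlim(x_window.origin, x_window.origin + 360.0)
    ax.set_ylim(y_window.origin, y_window.origin + 360.0)
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("psi (deg)")
    fig.tight_layout()
    fig.savefig(os.fspath(path))
    return fig
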