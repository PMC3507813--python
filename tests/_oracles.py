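"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different computational routes from the package:
the torsion oracle projects the flanking bonds onto the plane normal to
the axis and takes the signed angle between the projections (sign by
triple product); the marquee oracle remaps by repeated +/-360 shifts and
applies the textbook point-in-box / point-in-ellipse formulas.
"""

import math

import numpy as np


def torsion_oracle(p1, p2, p3, p4):
    """Signed dihedral by bond projection; sign from the triple product."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    axis = p3 - p2
    axis = axis / np.linalg.norm(axis)
    u = (p1 - p2) - np.dot(p1 - p2, axis) * axis
    v = (p4 - p3) - np.dot(p4 - p3, axis) * axis
    if np.linalg.norm(u) < 1e-10 or np.linalg.norm(v) < 1e-10:
        return None
    sin_term = np.dot(np.cross(u, v), axis)
    angle = math.degrees(math.atan2(sin_term, np.dot(u, v)))
    return 180.0 if angle <= -180.0 else angle


def circ_diff_oracle(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def remap_oracle(angle, origin):
    while angle < origin:
        angle += 360.0
    while angle >= origin + 360.0:
        angle -= 360.0
    return angle


def marquee_oracle(element, marquee):
    """Point-in-region decision replicated with explicit loops and formulas."""
    x, y = marquee.coordinates(element)
    if x is None or y is None:
        return False
    x = remap_oracle(x, marquee.x_window.origin)
    y = remap_oracle(y, marquee.y_window.origin)
    if marquee.shape == "rect":
        inside = marquee.x0 <= x <= marquee.x1 and marquee.y0 <= y <= marquee.y1
    else:
        cx = 0.5 * (marquee.x0 + marquee.x1)
        cy = 0.5 * (marquee.y0 + marquee.y1)
        rx = 0.5 * (marquee.x1 - marquee.x0)
        ry = 0.5 * (marquee.y1 - marquee.y0)
        inside = ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0
    return inside != marquee.inverted


def template_match_oracle(element, constraints, tol):
    """Per-position circular-difference template check, written longhand."""
    for conf, (phi_t, psi_t) in zip(element.conformations, constraints):
        if phi_t is not None:
            if conf.phi is None or circ_diff_oracle(conf.phi, phi_t) > tol:
                return False
        if psi_t is not None:
            if conf.psi is None or circ_diff_oracle(conf.psi, psi_t) > tol:
                return False
    return True


def window_starts_oracle(contiguous_flags, chain_len, n):
    """Brute-force enumeration of break-free window start indices."""
    return [
        s
        for s in range(chain_len - n + 1)
        if all(contiguous_flags[s : s + n - 1])
    ]
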