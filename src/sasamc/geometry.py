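"""Sphere-overlap geometry: exposed area of two intersecting spheres.

The solvent-accessible area lost when two probe-inflated spheres overlap
is the area of the lens formed by their intersection.  For radii R >= r
and center separation d the two spherical-cap heights are

    h_R = (r - R + d)(r + R - d) / (2d)   (cap cut from the larger sphere)
    h_r = (R - r + d)(R + r - d) / (2d)   (cap cut from the smaller sphere)

and the total exposed area is 4π(R² + r²) - 2π(R·h_R + r·h_r).
"""

from __future__ import annotations

import numpy as np

__all__ = ["cap_heights", "two_sphere_area", "buried_area"]


def cap_heights(R, r, d):
    """Cap heights (h_R, h_r) of the overlap lens of spheres with radii
    ``R >= r`` at separation ``d`` in the overlapping regime.

    Valid for ``|R - r| < d < R + r``; returned values lie in (0, 2r].
    """
    h_big = (r - R + d) * (r + R - d) / (2.0 * d)
    h_small = (R - r + d) * (R + r - d) / (2.0 * d)
    return h_big, h_small


def two_sphere_area(R, r, d):
    """Total exposed surface area (Å²) of two spheres of radii ``R`` and
    ``r`` at center separation ``d``.

    Separated spheres expose 4π(R²+r²); overlapping spheres lose the two
    lens caps; a fully engulfed small sphere contributes nothing and the
    result is clamped to 4π·max(R,r)² so the area stays continuous in
    ``d`` all the way to d = 0.
    """
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(R <= 0) or np.any(r <= 0):
        raise ValueError("sphere radii must be positive")
    big = np.maximum(R, r)
    small = np.minimum(R, r)
    full = 4.0 * np.pi * (big**2 + small**2)

    sep = d >= big + small
    eng = d <= big - small
    mid = ~(sep | eng)

    area = np.where(sep, full, 0.0)
    area = np.where(eng, 4.0 * np.pi * big**2, area)
    if np.any(mid):
        dm = np.where(mid, d, 1.0)  # avoid /0 outside the branch
        h_big, h_small = cap_heights(big, small, dm)
        lens = full - 2.0 * np.pi * (big * h_big + small * h_small)
        area = np.where(mid, lens, area)
    if area.ndim == 0:
        return float(area)
    return area


def buried_area(R, r, d):
    """Area buried by the overlap: A(d -> inf) - A(d) >= 0."""
    R = np.asarray(R, dtype=float)
    r = np.asarray(r, dtype=float)
    full = 4.0 * np.pi * (R**2 + r**2)
    return full - two_sphere_area(R, r, d)
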