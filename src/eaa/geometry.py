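"""Equal-area annulus geometry and edge-effect correction.

The neighborhood of a focal tree is partitioned into ``n_annuli`` concentric
rings of identical area summing to ``total_area`` (m^2), so each distance band
carries the same expected amount of data.  Near plot boundaries a ring is
partially outside the censused rectangle; counts and basal areas from such a
ring are inverse-area weighted by the exact inside fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OUTSIDE",
    "AnnulusSystem",
    "build_annulus_system",
    "annulus_index",
    "edge_fraction",
    "edge_fractions",
    "disc_rectangle_area",
]

#: Sentinel returned by :func:`annulus_index` for neighbors beyond the outermost ring.
OUTSIDE = -1


@dataclass(frozen=True)
class AnnulusSystem:
    """Concentric rings of equal area around a focal point.

    radii[0] = 0 < radii[1] < ... < radii[n_annuli]; ring k (1-based) is the
    half-open shell ``[radii[k-1], radii[k])`` with area ``total_area / n_annuli``.
    """

    n_annuli: int
    total_area: float
    radii: np.ndarray = field(repr=False)

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])

    @property
    def ring_area(self) -> float:
        return self.total_area / self.n_annuli

    def mid_radii(self) -> np.ndarray:
        """Area-weighted mean radius of each ring (continuous physical-distance axis)."""
        r = self.radii
        return (2.0 / 3.0) * (r[1:] ** 3 - r[:-1] ** 3) / (r[1:] ** 2 - r[:-1] ** 2)


def build_annulus_system(total_area: float, n_annuli: int) -> AnnulusSystem:
    """Build an equal-area annulus system.

    r_k = sqrt(k * total_area / (n_annuli * pi)), so every ring has area
    total_area / n_annuli exactly.
    """
    if n_annuli < 1:
        raise ValueError(f"n_annuli must be >= 1, got {n_annuli}")
    if total_area <= 0:
        raise ValueError(f"total_area must be > 0, got {total_area}")
    k = np.arange(n_annuli + 1, dtype=float)
    radii = np.sqrt(k * total_area / (n_annuli * math.pi))
    return AnnulusSystem(n_annuli=n_annuli, total_area=float(total_area), radii=radii)


def annulus_index(focal_xy, neighbor_xy, system: AnnulusSystem) -> int:
    """Ring index (1-based) of a neighbor, or OUTSIDE beyond the last ring.

    Distance d falls in ring k iff radii[k-1] <= d < radii[k]; d = 0 maps to
    ring 1 (co-located stems of distinct trees).
    """
    d = math.hypot(neighbor_xy[0] - focal_xy[0], neighbor_xy[1] - focal_xy[1])
    k = int(np.searchsorted(system.radii, d, side="right"))
    if k > system.n_annuli:
        return OUTSIDE
    return max(k, 1)


def annulus_indices(distances: np.ndarray, system: AnnulusSystem) -> np.ndarray:
    """Vectorized :func:`annulus_index`: OUTSIDE for d >= r_max, else 1..n_annuli."""
    k = np.searchsorted(system.radii, distances, side="right")
    k = np.maximum(k, 1)
    return np.where(distances >= system.r_max, OUTSIDE, k)


# ---------------------------------------------------------------------------
# Exact disc / rectangle intersection (edge correction)
# ---------------------------------------------------------------------------


def _w_integral(t: float, r: float) -> float:
    """Integral of sqrt(r^2 - y^2) dy from -r to t (t clipped to [-r, r])."""
    t = min(max(t, -r), r)
    return 0.5 * (t * math.sqrt(max(r * r - t * t, 0.0)) + r * r * math.asin(t / r)) + 0.25 * math.pi * r * r


def _corner_area(X: float, Y: float, r: float) -> float:
    """Area of disc(origin, r) intersected with the quadrant {x <= X, y <= Y}."""
    if r <= 0.0 or X <= -r or Y <= -r:
        return 0.0
    if X >= r:
        return 2.0 * _w_integral(Y, r)
    yc = min(Y, r)
    if X >= 0.0:
        s = math.sqrt(r * r - X * X)
        total = _w_integral(yc, r)  # integral of the right chord half
        # integral of min(X, w(y)): w(y) < X only for |y| > s
        total += _w_integral(min(yc, -s), r)
        if yc > -s:
            total += X * (min(yc, s) + s)
            if yc > s:
                total += _w_integral(yc, r) - _w_integral(s, r)
        return total
    # X < 0: chord [−w, X] is nonempty only where w(y) >= -X, i.e. |y| <= s
    s = math.sqrt(r * r - X * X)
    hi = min(yc, s)
    if hi <= -s:
        return 0.0
    return X * (hi + s) + _w_integral(hi, r) - _w_integral(-s, r)


def disc_rectangle_area(cx: float, cy: float, r: float, rect: tuple[float, float, float, float]) -> float:
    """Exact area of disc((cx, cy), r) ∩ rectangle (x0, y0, x1, y1)."""
    x0, y0, x1, y1 = rect
    # translate so the disc is centered at the origin
    ax, bx = x0 - cx, x1 - cx
    ay, by = y0 - cy, y1 - cy
    area = (
        _corner_area(bx, by, r)
        - _corner_area(ax, by, r)
        - _corner_area(bx, ay, r)
        + _corner_area(ax, ay, r)
    )
    return max(area, 0.0)


def edge_fraction(focal_xy, ring: int, system: AnnulusSystem, plot_rect) -> float:
    """Fraction of ring ``ring`` (1-based) around ``focal_xy`` lying inside the plot.

    Exact circular-segment geometry; raises if the focal point is outside the plot.
    """
    x0, y0, x1, y1 = plot_rect
    fx, fy = float(focal_xy[0]), float(focal_xy[1])
    if not (x0 <= fx <= x1 and y0 <= fy <= y1):
        raise ValueError(f"focal point {focal_xy} outside plot rectangle {plot_rect}")
    r_in = float(system.radii[ring - 1])
    r_out = float(system.radii[ring])
    inside = disc_rectangle_area(fx, fy, r_out, plot_rect) - disc_rectangle_area(fx, fy, r_in, plot_rect)
    return min(inside / (math.pi * (r_out**2 - r_in**2)), 1.0)


def edge_fractions(xy: np.ndarray, system: AnnulusSystem, plot_rect) -> np.ndarray:
    """Inside fraction for every (focal, ring) pair; shape (n_points, n_annuli).

    Points whose distance to every plot edge is at least r_max get fraction 1
    without evaluating the intersection geometry.
    """
    x0, y0, x1, y1 = plot_rect
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    out = np.ones((n, system.n_annuli))
    d_edge = np.minimum.reduce([xy[:, 0] - x0, x1 - xy[:, 0], xy[:, 1] - y0, y1 - xy[:, 1]])
    if np.any(d_edge < -1e-9):
        raise ValueError("some focal points lie outside the plot rectangle")
    near = np.flatnonzero(d_edge < system.r_max)
    for i in near:
        cx, cy = xy[i]
        disc_areas = [disc_rectangle_area(cx, cy, float(r), plot_rect) for r in system.radii]
        ring_inside = np.diff(disc_areas)
        out[i] = np.minimum(ring_inside / (math.pi * np.diff(system.radii**2)), 1.0)
    return out


def edge_weights(xy: np.ndarray, system: AnnulusSystem, plot_rect, mode: str = "weight",
                 drop_threshold: float = 0.5) -> np.ndarray:
    """Edge-correction weights 1/fraction_inside, shape (n_points, n_annuli).

    mode="weight": inverse-area weighting for every focal tree.
    mode="drop": focal trees whose outermost ring fraction is below
    ``drop_threshold`` get weight NaN in all rings (caller excludes them).
    """
    frac = edge_fractions(xy, system, plot_rect)
    with np.errstate(divide="ignore"):
        w = 1.0 / frac
    if mode == "drop":
        bad = frac[:, -1] < drop_threshold
        w[bad] = np.nan
        w[~bad] = 1.0
    elif mode != "weight":
        raise ValueError(f"unknown edge mode {mode!r}")
    return w
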