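"""Closed-form geometry of elliptical coccolith outlines.

A coccolith distal shield is modelled as an ellipse with semi-axes
``a = DSL/2`` (major) and ``b = DSW/2`` (minor).  The module collects the
planar results the coverage analysis rests on: areas of the maximum
inscribed and minimum circumscribed ``n``-gons of an ellipse, the
inscribed-polygon coverage ratio, the inscribed-ellipse scale factor,
spherical-cap and sphere surface areas, and chord/central-area clearance
tests.  All lengths are in μm, areas in μm², angles in radians.

The inscribed/circumscribed polygon results follow from the affine map
of the unit circle onto the ellipse: an area-maximal inscribed ``n``-gon
of the circle (any regular ``n``-gon) maps to an area-maximal inscribed
``n``-gon of the ellipse, scaling all areas by ``a·b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EllipseSpec",
    "PolygonSpec",
    "SphereCapSpec",
    "max_inscribed_polygon_area",
    "min_circumscribed_polygon_area",
    "coverage_ratio",
    "inscribed_ellipse_scale",
    "max_inscribed_polygon_vertices",
    "spherical_cap_area",
    "sphere_surface_area",
    "line_ellipse_clearance",
    "line_clears_ellipse",
]


@dataclass(frozen=True)
class EllipseSpec:
    """An ellipse in a 2D frame.

    Parameters
    ----------
    a, b
        Semi-axes in μm, ``a ≥ b > 0``.  For a coccolith outline
        ``a = DSL/2`` and ``b = DSW/2``.
    center
        Center coordinates, default the origin.
    angle
        Orientation of the major axis relative to the frame x-axis,
        radians, default 0.
    """

    a: float
    b: float
    center: tuple[float, float] = (0.0, 0.0)
    angle: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse semi-axes must satisfy a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def area(self) -> float:
        return math.pi * self.a * self.b

    def support(self, theta: float) -> float:
        """Support function h(θ) = max over the ellipse of x·(cosθ, sinθ).

        ``theta`` is measured in the ellipse's own frame (major axis = x).
        """
        return math.hypot(self.a * math.cos(theta), self.b * math.sin(theta))

    def point(self, t: float | np.ndarray) -> np.ndarray:
        """Boundary point(s) at parameter angle ``t`` (frame coordinates)."""
        ct, st = np.cos(self.angle), np.sin(self.angle)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.stack([self.center[0] + ct * x - st * y,
                         self.center[1] + st * x + ct * y], axis=-1)

    def implicit(self, pts: np.ndarray) -> np.ndarray:
        """Implicit value (x'/a)² + (y'/b)² − 1 at frame points ``pts``."""
        p = np.asarray(pts, dtype=float) - np.asarray(self.center)
        ct, st = math.cos(self.angle), math.sin(self.angle)
        x = ct * p[..., 0] + st * p[..., 1]
        y = -st * p[..., 0] + ct * p[..., 1]
        return (x / self.a) ** 2 + (y / self.b) ** 2 - 1.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.implicit(pts) <= 0.0


@dataclass(frozen=True)
class PolygonSpec:
    """A simple polygon given by its ordered vertices."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs >= 3 two-dimensional vertices")
        object.__setattr__(self, "vertices", v)

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Unsigned shoelace area."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class SphereCapSpec:
    """A spherical cap: sphere diameter and cap base diameter, both μm."""

    sphere_diameter: float
    base_diameter: float

    def __post_init__(self) -> None:
        if not (0 < self.base_diameter <= self.sphere_diameter):
            raise ValueError(
                f"cap base diameter must lie in (0, sphere diameter], got base={self.base_diameter}, sphere={self.sphere_diameter}"
            )


def _check_sides(n: float, minimum: float) -> None:
    if not n > minimum:
        raise ValueError(f"polygon side count must be > {minimum}, got {n}")


def max_inscribed_polygon_area(n: int, e: EllipseSpec) -> float:
    """Area of the maximum inscribed ``n``-gon: 0.5·n·a·b·sin(2π/n)."""
    if n < 3:
        raise ValueError(f"inscribed polygon needs n >= 3 sides, got {n}")
    return 0.5 * n * e.a * e.b * math.sin(2 * math.pi / n)


def min_circumscribed_polygon_area(n: int, e: EllipseSpec) -> float:
    """Area of the minimum circumscribed ``n``-gon: n·a·b·tan(π/n)."""
    if n < 3:
        raise ValueError(f"circumscribed polygon needs n >= 3 sides, got {n}")
    return n * e.a * e.b * math.tan(math.pi / n)


def coverage_ratio(n: float) -> float:
    """Fraction of an ellipse covered by its maximum inscribed n-gon.

    ``r(n) = 0.5·(n/π)·sin(2π/n)``; real-valued ``n`` is accepted because
    the population analysis evaluates it at the mean edge number per
    coccolith (n̄ = 5.2 for the observed populations).
    """
    _check_sides(n, 2)
    return 0.5 * (n / math.pi) * math.sin(2 * math.pi / n)


def inscribed_ellipse_scale(n: float) -> float:
    """Linear scale of the max ellipse inscribed in the max inscribed n-gon.

    The largest ellipse inscribed in the maximum inscribed ``n``-gon of a
    coccolith outline is a ``cos(π/n)``-scaled copy of the outline, so the
    returned factor applies per axis; the area factor is its square.
    """
    _check_sides(n, 2)
    return math.cos(math.pi / n)


def max_inscribed_polygon_vertices(n: int, e: EllipseSpec, phase: float = 0.0) -> PolygonSpec:
    """One member of the maximum-inscribed-polygon family.

    Vertices sit at parameter angles ``phase + 2πk/n``; every phase gives
    the same (maximal) area because the affine image of a regular polygon
    inscribed in the unit circle is area-maximal for every rotation.
    """
    if n < 3:
        raise ValueError(f"inscribed polygon needs n >= 3 sides, got {n}")
    t = phase + 2 * math.pi * np.arange(n) / n
    return PolygonSpec(e.point(t))


def spherical_cap_area(cap: SphereCapSpec) -> float:
    """Surface area 2πRh of the minor spherical cap with the given base.

    ``R`` is the sphere radius and ``h = R − sqrt(R² − r²)`` the cap height
    for base radius ``r``.  The minor cap is used: a coccolith covers less
    than a hemisphere of the cell surface.
    """
    R = cap.sphere_diameter / 2.0
    r = cap.base_diameter / 2.0
    # stable form of h = R − sqrt(R² − r²) (no cancellation for r ≪ R)
    h = r * r / (R + math.sqrt(max(R * R - r * r, 0.0)))
    return 2 * math.pi * R * h


def sphere_surface_area(diameter: float) -> float:
    """Surface area π·d² of a sphere of the given diameter."""
    if diameter <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter}")
    return math.pi * diameter * diameter


def line_ellipse_clearance(p1, p2, e: EllipseSpec) -> float:
    """Signed clearance of the infinite line through p1, p2 from ellipse ``e``.

    Returns ``p − h(θ)`` where ``p`` is the distance from the ellipse
    center to the line and ``h`` the ellipse support function in the
    line-normal direction (in the ellipse frame).  Positive means the
    line misses the ellipse; zero, tangency; negative, a crossing, with
    magnitude the penetration depth in the normal direction (μm).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    L = math.hypot(d[0], d[1])
    if L == 0.0:
        raise ValueError("line endpoints must be distinct")
    # unit normal of the line in frame coordinates
    nx, ny = -d[1] / L, d[0] / L
    # distance from ellipse center to the line
    c = np.asarray(e.center)
    p = abs(nx * (p1[0] - c[0]) + ny * (p1[1] - c[1]))
    # normal direction expressed in the ellipse's own frame
    theta = math.atan2(ny, nx) - e.angle
    return p - e.support(theta)


def line_clears_ellipse(p1, p2, e: EllipseSpec) -> bool:
    """True iff the infinite line through p1, p2 does not enter ellipse ``e``."""
    return line_ellipse_clearance(p1, p2, e) >= 0.0
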