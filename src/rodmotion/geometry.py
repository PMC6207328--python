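"""Spherocylinder geometry for rod-shaped bacteria on a coverslip.

A rod-shaped cell is modelled as a cylinder of diameter ``width`` capped by
two hemispheres (tip-to-tip ``length``), resting on the coverslip so that the
lowest line of the cylinder flank touches z = 0.  Evanescent (TIRF)
illumination is modelled as a hard horizontal cutoff at ``depth`` above the
coverslip; the illuminated surface area is the part of the membrane with
z <= depth.  These areas normalise track counts between strains whose
dimensions differ.

All lengths are in micrometres unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spherocylinder",
    "IlluminationModel",
    "total_surface_area",
    "illuminated_surface_area",
    "illuminated_fraction",
    "projected_area",
    "area_from_outline",
]


@dataclass(frozen=True)
class Spherocylinder:
    """A cylinder with hemispherical caps: ``length`` tip-to-tip, ``width`` diameter."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError(f"width must be positive, got {self.width}")
        if self.length < self.width:
            raise ValueError(
                f"length ({self.length}) must be >= width ({self.width})"
            )

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical mid-section (excludes the two caps)."""
        return self.length - self.width


@dataclass(frozen=True)
class IlluminationModel:
    """Hard-cutoff evanescent illumination: membrane below ``depth`` is lit."""

    depth: float

    def __post_init__(self) -> None:
        if not (self.depth > 0):
            raise ValueError(f"depth must be positive, got {self.depth}")


def total_surface_area(cell: Spherocylinder) -> float:
    """Total membrane area: 2*pi*r*(L - 2r) + 4*pi*r^2."""
    r = cell.radius
    return 2.0 * math.pi * r * cell.cylinder_length + 4.0 * math.pi * r * r


def illuminated_surface_area(cell: Spherocylinder, illum: IlluminationModel) -> float:
    """Membrane area within ``illum.depth`` of the coverslip.

    On the cylinder flank a point at circumferential angle theta from the
    bottom line sits at height z = r*(1 - cos theta), so the lit band spans
    |theta| <= arccos(1 - depth/r) and has area 2*r*theta_max*(L - 2r).
    The two hemispherical caps together form a sphere whose zone below the
    cutoff has area 2*pi*r*depth.  For depth >= width the whole surface
    is lit.
    """
    r = cell.radius
    d = illum.depth
    if d >= cell.width:
        return total_surface_area(cell)
    theta_max = math.acos(1.0 - d / r)
    band = 2.0 * r * theta_max * cell.cylinder_length
    caps = 2.0 * math.pi * r * d
    return band + caps


def illuminated_fraction(cell: Spherocylinder, illum: IlluminationModel) -> float:
    """Illuminated area as a fraction of total surface area, in (0, 1]."""
    return illuminated_surface_area(cell, illum) / total_surface_area(cell)


def projected_area(cell: Spherocylinder) -> float:
    """2-D footprint on the coverslip: a rectangle plus a disc.

    This is the quantity a segmentation tool reports from a phase-contrast
    outline, and the denominator of the tracks-per-area normalisation.
    """
    return cell.width * cell.cylinder_length + math.pi * cell.radius**2


def area_from_outline(polygon: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Shoelace area of a closed cell outline.

    Parameters
    ----------
    polygon
        (n, 2) vertex array, n >= 3, in pixel (or micron) coordinates.  The
        polygon may be open (last vertex != first); closure is implied.
    pixel_size_um
        Scale of the coordinates in micrometres per unit.

    Returns
    -------
    Area in square micrometres, independent of traversal direction.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("polygon must be an (n>=3, 2) array of vertices")
    # drop an explicit closing vertex
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise ValueError("polygon must have at least 3 distinct vertices")
    if _self_intersects(pts):
        raise ValueError("polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area) * pixel_size_um**2


def _self_intersects(pts: np.ndarray) -> bool:
    """Brute-force check for crossing non-adjacent edges of a closed polygon."""
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]

    def cross2(a, b) -> float:
        return a[0] * b[1] - a[1] * b[0]

    def seg_cross(p1, p2, p3, p4) -> bool:
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent via closure
            if seg_cross(edges[i][0], edges[i][1], edges[j][0], edges[j][1]):
                return True
    return False
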