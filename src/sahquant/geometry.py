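"""Planar geometry primitives for annotated electron micrographs.

Coordinates are in micrometres, y increasing downward (image convention).
Contours are closed simple polygons (the last->first edge is implicit);
polylines are open. Areas come from the shoelace formula via shapely,
lengths from summed edge lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Raised when a contour or polyline violates its invariants."""


@dataclass(frozen=True)
class Contour:
    """A closed, simple polygon given by its ordered vertices (µm)."""

    vertices: np.ndarray  # (n, 2)
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("contour needs >=3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("contour vertices must be finite")
        poly = Polygon(v)
        if not poly.is_valid:
            raise GeometryError("contour is self-intersecting or degenerate")
        if poly.area <= 0:
            raise GeometryError("contour encloses no area")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return self._polygon.area

    @property
    def perimeter(self) -> float:
        return self._polygon.length

    def contains(self, other: "Contour") -> bool:
        return self._polygon.contains(other._polygon)


@dataclass(frozen=True)
class Polyline:
    """An open path given by its ordered vertices (µm)."""

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise GeometryError("polyline needs >=2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polyline vertices must be finite")
        if self._arc_length(v) <= 0:
            raise GeometryError("polyline has zero length")
        object.__setattr__(self, "vertices", v)

    @staticmethod
    def _arc_length(v: np.ndarray) -> float:
        return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))

    @property
    def length(self) -> float:
        return self._arc_length(self.vertices)

    @property
    def linestring(self) -> LineString:
        return LineString(self.vertices)


# -- shape descriptors -------------------------------------------------------

#: digitized circles can overshoot 1 slightly; values beyond this fail loudly
DIGITIZATION_TOLERANCE = 0.02


def _clamp_ratio(value: float, what: str) -> float:
    if value > 1.0 + DIGITIZATION_TOLERANCE:
        raise GeometryError(f"{what} {value:.4f} exceeds 1 beyond digitization tolerance")
    return min(value, 1.0)


def circularity(c: Contour) -> float:
    """4π·area/perimeter²: 1 for a circle, ->0 for elongated shapes.

    Values marginally above 1 (perimeter-estimation bias on digitized
    circles) are clamped to 1; anything beyond the tolerance raises.
    """
    p = c.perimeter
    if p <= 0:
        raise GeometryError("zero-perimeter contour")
    return _clamp_ratio(4.0 * np.pi * c.area / p**2, "circularity")


def polygon_second_moments(c: Contour) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and normalized second central moments of the filled polygon.

    Closed-form integrals over the polygon interior (Green's theorem), so no
    rasterization is involved. Returns (centroid, covariance) where the
    covariance is [[µxx, µxy], [µxy, µyy]] / area.
    """
    v = c.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    x0, y0 = x - cx, y - cy
    xn0, yn0 = xn - cx, yn - cy
    cross0 = x0 * yn0 - xn0 * y0
    ixx = np.sum(cross0 * (x0**2 + x0 * xn0 + xn0**2)) / 12.0
    iyy = np.sum(cross0 * (y0**2 + y0 * yn0 + yn0**2)) / 12.0
    ixy = np.sum(cross0 * (x0 * yn0 + 2 * x0 * y0 + 2 * xn0 * yn0 + xn0 * y0)) / 24.0
    cov = np.array([[ixx, ixy], [ixy, iyy]]) / abs(a)
    return np.array([cx, cy]), cov


def fitted_ellipse_axes(c: Contour) -> tuple[float, float]:
    """(major, minor) axis lengths of the moment-matching ellipse.

    The ellipse with the same normalized second central moments as the filled
    region; for covariance eigenvalues λ1 >= λ2 the axes are 4√λ1 and 4√λ2
    (the convention used by standard particle-analysis software).
    """
    _, cov = polygon_second_moments(c)
    eigvals = np.linalg.eigvalsh(cov)
    lam2, lam1 = float(eigvals[0]), float(eigvals[1])
    return 4.0 * np.sqrt(max(lam1, 0.0)), 4.0 * np.sqrt(max(lam2, 0.0))


def roundness(c: Contour) -> float:
    """4·area/(π·major²): inverse aspect ratio of the fitted ellipse."""
    major, _ = fitted_ellipse_axes(c)
    if major <= 0:
        raise GeometryError("degenerate contour: zero major axis")
    return _clamp_ratio(4.0 * c.area / (np.pi * major**2), "roundness")


def bounding_box_diagonal(p: Polyline) -> float:
    """Diagonal of the axis-aligned rectangle containing the polyline."""
    span = p.vertices.max(axis=0) - p.vertices.min(axis=0)
    d = float(np.hypot(span[0], span[1]))
    if d <= 0:
        raise GeometryError("polyline bounding box has zero extent")
    return d
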