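"""Ultrastructural morphometry of annotated capillary cross-sections.

Each capillary profile is an annotation bundle: closed contours for the
abluminal (capillary) and luminal membranes and the inner/outer faces of the
basal lamina (BL), polygons for pericyte processes, open polylines for
pericyte/astrocyte adhesion arcs and tight junctions (TJ), point-count fields
for pinocytic vesicles, and an optional aligned intensity image used for
electron-lucent "hole" detection. The operations here reduce a profile to the
per-profile parameter set used for group comparison:

- circularity 4π·A/P² and roundness 4A/(π·major²) of capillary and lumen;
- endothelium area = capillary − lumen; lumen/endothelium volume fractions;
- lumen/capillary size = area / circumference;
- BL thickness by grid-overlay sampling (GOIA) on a 0.5 µm grid, with
  crossings adjacent to pericytes excluded;
- TJ tortuosity = junction length / bounding-rectangle diagonal;
- vesicle density pooled over 3–5 fields; pericyte/astrocyte adhesion and
  coverage; thresholded perivascular hole area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from .geometry import (
    Contour,
    GeometryError,
    Polyline,
    bounding_box_diagonal,
    circularity,
    roundness,
)


class MorphometryInputError(ValueError):
    """Raised when a profile's annotations cannot support a measurement."""


@dataclass
class ProfileFlags:
    """Inclusion-relevant observations recorded by the annotator."""

    n_endothelial_cells: int
    is_cross_section: bool
    contains_blood_or_plasma: bool
    has_visible_nucleus: bool


@dataclass
class CapillaryProfile:
    """One annotated capillary cross-section in µm coordinates."""

    group: str
    animal: str
    profile: str
    pixel_size: float  # µm per pixel of the intensity image
    abluminal_contour: Contour
    luminal_contour: Contour
    bl_inner: Optional[Contour] = None
    bl_outer: Optional[Contour] = None
    pericyte_contours: list[Contour] = field(default_factory=list)
    pericyte_adhesion: list[Polyline] = field(default_factory=list)
    astrocyte_adhesion: list[Polyline] = field(default_factory=list)
    tj_polylines: list[Polyline] = field(default_factory=list)
    vesicle_fields: list[tuple[float, int]] = field(default_factory=list)
    intensity_image: Optional[np.ndarray] = None
    image_origin: tuple[float, float] = (0.0, 0.0)  # µm position of pixel (0, 0)
    flags: Optional[ProfileFlags] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise MorphometryInputError("pixel_size must be positive")
        if not self.abluminal_contour.contains(self.luminal_contour):
            raise MorphometryInputError("luminal contour must lie strictly inside the abluminal contour")
        if self.luminal_contour.area >= self.abluminal_contour.area:
            raise MorphometryInputError("lumen area must be smaller than capillary area")
        if (self.bl_inner is None) != (self.bl_outer is None):
            raise MorphometryInputError("bl_inner and bl_outer must be given together")
        if self.bl_outer is not None and self.bl_inner is not None:
            if not (self.bl_outer.polygon.covers(self.bl_inner.polygon)):
                raise MorphometryInputError("bl_inner must lie inside bl_outer")
            circumference = self.bl_outer.perimeter
            for arc in [*self.pericyte_adhesion, *self.astrocyte_adhesion]:
                if arc.length > circumference * (1 + 1e-6):
                    raise MorphometryInputError("adhesion arc longer than BL circumference")
        for area, count in self.vesicle_fields:
            if area <= 0:
                raise MorphometryInputError("vesicle field areas must be positive")
            if count < 0:
                raise MorphometryInputError("vesicle counts must be non-negative")


@dataclass
class MorphometryRecord:
    """Per-profile derived statistics (missing annotations give NaN)."""

    group: str
    animal: str
    profile: str
    capillary_area: float
    lumen_area: float
    endothelium_area: float
    capillary_circularity: float
    lumen_circularity: float
    capillary_roundness: float
    lumen_roundness: float
    endothelium_volume_fraction: float
    lumen_volume_fraction: float
    lumen_size: float
    capillary_size: float
    bl_thickness: float
    tj_tortuosity: float
    vesicle_density: float
    pericyte_area: float
    pericyte_volume_fraction: float
    pericyte_adhesion: float
    pericyte_coverage: float
    astrocyte_adhesion: float
    astrocyte_coverage: float
    hole_area: float

    #: measurement columns, in reporting order
    PARAMETERS = (
        "capillary_area",
        "lumen_area",
        "endothelium_area",
        "capillary_circularity",
        "lumen_circularity",
        "capillary_roundness",
        "lumen_roundness",
        "lumen_volume_fraction",
        "endothelium_volume_fraction",
        "lumen_size",
        "capillary_size",
        "bl_thickness",
        "tj_tortuosity",
        "pericyte_area",
        "pericyte_volume_fraction",
        "pericyte_adhesion",
        "pericyte_coverage",
        "astrocyte_adhesion",
        "astrocyte_coverage",
        "hole_area",
        "vesicle_density",
    )


# -- individual measurements -------------------------------------------------


def areas_and_fractions(p: CapillaryProfile) -> tuple[float, float, float, float, float]:
    """(capillary, lumen, endothelium area; lumen, endothelium volume fraction).

    Endothelium area is capillary minus lumen, so the two volume fractions sum
    to 1 exactly on every profile.
    """
    cap = p.abluminal_contour.area
    lum = p.luminal_contour.area
    endo = cap - lum
    lumen_vf = lum / cap
    return cap, lum, endo, lumen_vf, 1.0 - lumen_vf


def size_ratios(p: CapillaryProfile) -> tuple[float, float]:
    """(lumen size, capillary size) = area / circumference, in µm."""
    lumen_size = p.luminal_contour.area / p.luminal_contour.perimeter
    capillary_size = p.abluminal_contour.area / p.abluminal_contour.perimeter
    return lumen_size, capillary_size


def tj_tortuosity(tj: Polyline) -> float:
    """Junction arc length over the diagonal of its axis-aligned bounding box."""
    return tj.length / bounding_box_diagonal(tj)


def vesicle_density(
    fields: Sequence[tuple[float, int]], min_fields: int = 3, max_fields: int = 5
) -> float:
    """Pooled pinocytic vesicle density: Σcounts / Σareas over 3–5 fields."""
    if not (min_fields <= len(fields) <= max_fields):
        raise MorphometryInputError(
            f"vesicle density needs {min_fields}–{max_fields} fields, got {len(fields)}"
        )
    areas = np.array([a for a, _ in fields], dtype=float)
    counts = np.array([c for _, c in fields], dtype=float)
    if np.any(areas <= 0):
        raise MorphometryInputError("vesicle field areas must be positive")
    return float(counts.sum() / areas.sum())


def _bl_circumference(p: CapillaryProfile) -> float:
    # coverage denominators use the outer (parenchymal) BL face
    if p.bl_outer is None:
        raise MorphometryInputError("profile has no basal lamina annotation")
    return p.bl_outer.perimeter


def pericyte_metrics(p: CapillaryProfile) -> tuple[float, float, float, float]:
    """(summed area, volume fraction, summed adhesion, coverage).

    Areas of multiple processes are added; the fraction is relative to the
    capillary area; coverage divides summed adhesion arc length by the BL
    circumference. No pericytes -> all zeros.
    """
    area = sum(c.area for c in p.pericyte_contours)
    fraction = area / p.abluminal_contour.area
    adhesion = sum(a.length for a in p.pericyte_adhesion)
    coverage = adhesion / _bl_circumference(p) if adhesion > 0 else 0.0
    return area, fraction, adhesion, coverage


def astrocyte_metrics(p: CapillaryProfile) -> tuple[float, float]:
    """(summed astrocyte adhesion length, coverage over BL circumference)."""
    adhesion = sum(a.length for a in p.astrocyte_adhesion)
    coverage = adhesion / _bl_circumference(p) if adhesion > 0 else 0.0
    return adhesion, coverage


# -- GOIA basal lamina thickness ---------------------------------------------


def _outward_normals(contour: Contour) -> tuple[np.ndarray, np.ndarray]:
    """Vertex positions and outward unit normals of a closed contour."""
    v = contour.vertices
    nxt = np.roll(v, -1, axis=0)
    prv = np.roll(v, 1, axis=0)
    tangent = nxt - prv
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent = tangent / norm
    # rotate tangent by -90° / +90°; pick the orientation pointing outward
    normal = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
    centroid = np.array(contour.polygon.centroid.coords[0])
    outward = np.sign(np.sum((v - centroid) * normal, axis=1))
    outward[outward == 0] = 1.0
    return v, normal * outward[:, None]


def _normal_at(contour: Contour, pt: np.ndarray) -> np.ndarray:
    """Outward unit normal of the contour at its boundary point nearest pt."""
    v, normals = _outward_normals(contour)
    i = int(np.argmin(np.sum((v - pt) ** 2, axis=1)))
    return normals[i]


def _grid_crossings(contour: Contour, pitch: float) -> list[np.ndarray]:
    """Intersection points of a square gridline lattice with the contour."""
    ring = LineString(np.vstack([contour.vertices, contour.vertices[:1]]))
    minx, miny, maxx, maxy = contour.polygon.bounds
    pts: list[np.ndarray] = []

    def collect(line: LineString) -> None:
        inter = ring.intersection(line)
        if inter.is_empty:
            return
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if g.geom_type == "Point":
                pts.append(np.array(g.coords[0]))
            else:  # tangent overlap: take its midpoint
                pts.append(np.array(g.interpolate(0.5, normalized=True).coords[0]))

    for x in np.arange(math.floor(minx / pitch) * pitch, maxx + pitch, pitch):
        collect(LineString([(x, miny - pitch), (x, maxy + pitch)]))
    for y in np.arange(math.floor(miny / pitch) * pitch, maxy + pitch, pitch):
        collect(LineString([(minx - pitch, y), (maxx + pitch, y)]))
    return pts


def bl_thickness_goia(
    p: CapillaryProfile,
    grid_pitch: float = 0.5,
    pericyte_exclusion_radius: float = 0.25,
    min_crossings: int = 3,
) -> float:
    """Grid-overlay (GOIA) estimate of basal lamina thickness, in µm.

    A square grid of the given pitch is laid over the profile; at every point
    where a gridline crosses the inner BL face, thickness is the distance to
    the outer face along the local outward normal. Crossings within
    `pericyte_exclusion_radius` of a pericyte adhesion arc are discarded (the
    BL thins where a pericyte is interposed). The estimate is the mean over
    admissible crossings; fewer than `min_crossings` of them is an error.
    Coincident inner/outer faces return 0.
    """
    if p.bl_inner is None or p.bl_outer is None:
        raise MorphometryInputError("profile has no basal lamina annotation")
    if np.allclose(p.bl_inner.vertices, p.bl_outer.vertices):
        return 0.0

    outer_ring = LineString(np.vstack([p.bl_outer.vertices, p.bl_outer.vertices[:1]]))
    exclusion = (
        unary_union([a.linestring for a in p.pericyte_adhesion])
        if p.pericyte_adhesion
        else None
    )
    reach = 4.0 * (p.bl_outer.perimeter / (2 * np.pi))  # ray length bound

    thicknesses: list[float] = []
    for pt in _grid_crossings(p.bl_inner, grid_pitch):
        if exclusion is not None and exclusion.distance(Point(pt)) < pericyte_exclusion_radius:
            continue
        n = _normal_at(p.bl_inner, pt)
        ray = LineString([pt, pt + reach * n])
        hit = ray.intersection(outer_ring)
        if hit.is_empty:
            continue
        thicknesses.append(hit.distance(Point(pt)))
    if len(thicknesses) < min_crossings:
        raise MorphometryInputError(
            f"profile {p.group}/{p.animal}/{p.profile}: only {len(thicknesses)} "
            f"admissible BL grid crossings (minimum {min_crossings})"
        )
    return float(np.mean(thicknesses))


# -- perivascular hole area --------------------------------------------------


def hole_area(
    p: CapillaryProfile,
    band_width: float = 2.0,
    threshold: Optional[float] = None,
    min_contrast_sd: float = 5.0,
) -> float:
    """Electron-lucent ("hole") area adjacent to the capillary, in µm².

    Pixels of the aligned intensity image are thresholded (Otsu on the
    perivascular band by default, or a fixed grey level), labelled into
    connected components, and components intersecting the band between the
    abluminal contour and `band_width` µm outside it are summed. The Otsu
    threshold is only accepted when the separated classes differ by more than
    `min_contrast_sd` background standard deviations — on an image with no
    unequivocally bright pixels the area is 0, not the noise split.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label

    if p.intensity_image is None:
        raise MorphometryInputError("profile has no intensity image")
    img = np.asarray(p.intensity_image, dtype=float)
    px = p.pixel_size
    ox, oy = p.image_origin

    # signed distance outside the abluminal contour, per pixel
    from scipy.ndimage import distance_transform_edt

    from .raster import rasterize_interior

    inside = rasterize_interior(p.abluminal_contour.vertices, (ox, oy), px, img.shape)
    dist_out = distance_transform_edt(~inside) * px
    band = (~inside) & (dist_out <= band_width)
    if not band.any():
        return 0.0

    band_vals = img[band]
    if threshold is None:
        if band_vals.max() == band_vals.min():
            return 0.0
        # Otsu seed + intermeans refinement: histogram-bin ties on strongly
        # bimodal data can land Otsu inside a class; iterating to the midpoint
        # of the class means settles between the modes
        t = threshold_otsu(band_vals)
        for _ in range(50):
            lo, hi = band_vals[band_vals <= t], band_vals[band_vals > t]
            if lo.size == 0 or hi.size == 0:
                break
            t_new = (lo.mean() + hi.mean()) / 2.0
            if abs(t_new - t) < 1e-6:
                break
            t = t_new
        below, above = band_vals[band_vals <= t], band_vals[band_vals > t]
        if below.size == 0 or above.size == 0:
            return 0.0
        sd = below.std()
        if sd == 0 or (above.mean() - below.mean()) < min_contrast_sd * sd:
            return 0.0
    else:
        t = threshold

    bright = img > t
    labels = label(bright, connectivity=2)
    hit = np.unique(labels[band & bright])
    hit = hit[hit != 0]
    if hit.size == 0:
        return 0.0
    n_pixels = int(np.isin(labels, hit).sum())
    return float(n_pixels) * px * px


# -- inclusion and the full record -------------------------------------------


def profile_passes_inclusion(p: CapillaryProfile) -> bool:
    """Sampling criteria: a usable capillary cross-section.

    Lined by at most two endothelial cells, cut in cross-section, free of
    blood cells or plasma, and without an endothelial/pericyte nucleus in
    frame (nuclei generate extreme area/adhesion measurements).
    """
    f = p.flags
    if f is None:
        raise MorphometryInputError("profile has no inclusion flags")
    return (
        f.n_endothelial_cells <= 2
        and f.is_cross_section
        and not f.contains_blood_or_plasma
        and not f.has_visible_nucleus
    )


def measure_profile(
    p: CapillaryProfile,
    grid_pitch: float = 0.5,
    band_width: float = 2.0,
    hole_threshold: Optional[float] = None,
    pericyte_exclusion_radius: float = 0.25,
) -> MorphometryRecord:
    """Reduce a profile to its complete morphometry record.

    Annotations absent from the profile yield NaN fields rather than zeros,
    so downstream means are taken over the profiles that carry the structure.
    """
    cap, lum, endo, lumen_vf, endo_vf = areas_and_fractions(p)
    lumen_size, capillary_size = size_ratios(p)

    if p.bl_inner is not None and p.bl_outer is not None:
        bl = bl_thickness_goia(p, grid_pitch, pericyte_exclusion_radius)
        peri = pericyte_metrics(p)
        astro = astrocyte_metrics(p)
    else:
        bl = math.nan
        peri = (math.nan, math.nan, math.nan, math.nan)
        astro = (math.nan, math.nan)

    tort = (
        float(np.mean([tj_tortuosity(t) for t in p.tj_polylines]))
        if p.tj_polylines
        else math.nan
    )
    dens = vesicle_density(p.vesicle_fields) if p.vesicle_fields else math.nan
    hole = (
        hole_area(p, band_width=band_width, threshold=hole_threshold)
        if p.intensity_image is not None
        else math.nan
    )

    return MorphometryRecord(
        group=p.group,
        animal=p.animal,
        profile=p.profile,
        capillary_area=cap,
        lumen_area=lum,
        endothelium_area=endo,
        capillary_circularity=circularity(p.abluminal_contour),
        lumen_circularity=circularity(p.luminal_contour),
        capillary_roundness=roundness(p.abluminal_contour),
        lumen_roundness=roundness(p.luminal_contour),
        endothelium_volume_fraction=endo_vf,
        lumen_volume_fraction=lumen_vf,
        lumen_size=lumen_size,
        capillary_size=capillary_size,
        bl_thickness=bl,
        tj_tortuosity=tort,
        vesicle_density=dens,
        pericyte_area=peri[0],
        pericyte_volume_fraction=peri[1],
        pericyte_adhesion=peri[2],
        pericyte_coverage=peri[3],
        astrocyte_adhesion=astro[0],
        astrocyte_coverage=astro[1],
        hole_area=hole,
    )
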