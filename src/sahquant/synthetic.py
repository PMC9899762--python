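"""Phantom data with known ground truth for every pipeline stage.

The study's raw inputs (electron micrographs, confocal stacks, blots, CT
values) are not deposited, so every downstream stage is exercised on
synthetic stand-ins generated here:

- capillary cross-section phantoms whose true geometric parameters are drawn
  from the per-group distributions of the morphometry reference table
  (mean ± SD per parameter for SHAM, SAH and SAH + Mino);
- correlated two-channel volumes with a target Pearson coefficient;
- CT tables with known group fold effects, densitometry lane tables with
  per-membrane gains, and six-segment hemorrhage grade sheets.

Contours are Fourier-perturbed ellipses: low-order radial harmonics give
non-circular, SAH-like irregularity while the enclosed area is controlled
analytically and corrected by uniform scaling, so the drawn value is hit
exactly. Parameter draws use truncated normals at the physical bounds, with
the location moment-matched so the truncated mean equals the requested mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import substring

from .geometry import Contour, Polyline
from .morphometry import CapillaryProfile, ProfileFlags
from .raster import rasterize_interior

GROUPS = ("SHAM", "SAH", "SAH+Mino")

#: per-group (mean, sd) of the generator's target distributions, as reported
#: for the three experimental groups; areas in µm², lengths/thickness in µm,
#: vesicle density in counts/µm², fractions and tortuosity dimensionless.
GROUP_PARAMETERS: dict[str, dict[str, tuple[float, float]]] = {
    "SHAM": {
        "capillary_area": (34.45, 8.67),
        "lumen_volume_fraction": (0.60, 0.07),
        "bl_thickness": (0.10, 0.002),
        "tj_tortuosity": (1.25, 0.16),
        "pericyte_area": (5.56, 0.98),
        "pericyte_adhesion": (7.43, 1.07),
        "astrocyte_adhesion": (16.8, 2.04),
        "hole_area": (0.0, 0.0),
        "vesicle_density": (7.48, 0.25),
    },
    "SAH": {
        "capillary_area": (20.58, 5.25),
        "lumen_volume_fraction": (0.30, 0.10),
        "bl_thickness": (0.10, 0.02),
        "tj_tortuosity": (1.25, 0.08),
        "pericyte_area": (1.80, 0.40),
        "pericyte_adhesion": (5.68, 0.20),
        "astrocyte_adhesion": (7.70, 3.49),
        "hole_area": (22.29, 4.18),
        "vesicle_density": (4.67, 0.77),
    },
    "SAH+Mino": {
        "capillary_area": (29.86, 5.036),
        "lumen_volume_fraction": (0.65, 0.06),
        "bl_thickness": (0.10, 0.07),
        "tj_tortuosity": (1.05, 0.04),
        "pericyte_area": (5.17, 1.67),
        "pericyte_adhesion": (7.93, 1.80),
        "astrocyte_adhesion": (13.2, 2.58),
        "hole_area": (0.0, 0.0),
        "vesicle_density": (8.10, 0.84),
    },
}

#: physical bounds per parameter, used to truncate the sampling distributions
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "capillary_area": (1e-3, math.inf),
    "lumen_volume_fraction": (1e-3, 1 - 1e-3),
    "bl_thickness": (0.0, math.inf),
    "tj_tortuosity": (1.0, math.inf),
    "pericyte_area": (0.0, math.inf),
    "pericyte_adhesion": (0.0, math.inf),
    "astrocyte_adhesion": (0.0, math.inf),
    "hole_area": (0.0, math.inf),
    "vesicle_density": (0.0, math.inf),
}


class PhantomError(RuntimeError):
    """Raised when drawn parameters stay geometrically infeasible."""


@dataclass
class PhantomConfig:
    """Generator settings for one experimental group."""

    group_label: str = "SHAM"
    parameters: dict[str, tuple[float, float]] = dc_field(default_factory=dict)
    n_animals: int = 4
    profiles_per_animal: int = 10
    pixel_size: float = 0.02  # µm/px of the painted intensity image
    n_fields: tuple[int, int] = (3, 5)  # vesicle-count fields per capillary
    field_area: float = 1.0  # µm² per field
    hole_intensity: float = 3000.0
    background_intensity: float = 100.0
    background_noise_sd: float = 15.0
    band_width: float = 2.0  # perivascular band the holes live in, µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_PARAMETERS and not self.parameters:
            raise ValueError(f"unknown group {self.group_label!r} and no parameters given")
        base = dict(GROUP_PARAMETERS.get(self.group_label, {}))
        base.update(self.parameters)
        self.parameters = base
        for name, (mean, sd) in self.parameters.items():
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")
            lo, hi = PARAMETER_BOUNDS[name]
            if not (lo <= mean <= hi):
                raise ValueError(f"{name}: mean {mean} outside physical bounds")
        if not (1 <= self.n_fields[0] <= self.n_fields[1]):
            raise ValueError("n_fields bounds must satisfy 1 <= lo <= hi")
        if self.pixel_size <= 0 or self.field_area <= 0:
            raise ValueError("pixel_size and field_area must be positive")


from functools import lru_cache


@lru_cache(maxsize=256)
def _moment_matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal whose truncated mean equals `mean`.

    Plain truncation at a nearby bound shifts the realized mean (e.g. a
    tortuosity of 1.25 ± 0.16 truncated at 1 gains ~0.02); solving for the
    location removes that bias while keeping the stated scale.
    """

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    if trunc_mean(mean) == mean:  # truncation inactive
        return mean
    left, right = mean - 12 * sd, mean + 12 * sd
    for _ in range(40):  # expand until the target mean is bracketed
        if trunc_mean(left) <= mean:
            break
        left -= 12 * sd
    for _ in range(40):
        if trunc_mean(right) >= mean:
            break
        right += 12 * sd
    if trunc_mean(left) > mean or trunc_mean(right) < mean:
        return right  # target unreachable within the bounds: best effort
    return float(optimize.brentq(lambda m: trunc_mean(m) - mean, left, right))


def draw_parameter(name: str, mean: float, sd: float, rng: np.random.Generator) -> float:
    lo, hi = PARAMETER_BOUNDS[name]
    return draw_bounded(mean, sd, lo, hi, rng)


def draw_bounded(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    """Moment-matched truncated-normal draw on [lo, hi].

    A requested mean at or beyond the upper bound (a large structure on a
    small capillary) is clamped just inside it instead of failing, which
    keeps the per-profile draw feasible at negligible cost to the group mean.
    """
    if math.isfinite(hi):
        # quantize the bound so the solved location is shared across profiles
        hi = math.floor(hi * 20) / 20
        if hi <= lo:
            return lo
        mean = min(mean, lo + 0.995 * (hi - lo))
    if sd == 0:
        return min(max(mean, lo), hi)
    loc = _moment_matched_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


# -- contour construction ----------------------------------------------------


def fourier_ellipse(
    area: float,
    rng: np.random.Generator,
    n_vertices: int = 256,
    aspect_range: tuple[float, float] = (0.75, 1.0),
    irregularity: float = 0.25,
) -> np.ndarray:
    """Closed contour with exactly the requested area.

    An ellipse radius function is modulated by low-order cosine harmonics
    (amplitude ~ irregularity/k², keeping the shape near-convex), rotated
    randomly, and uniformly rescaled so the shoelace area equals `area`.
    """
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    aspect = rng.uniform(*aspect_range)
    r = 1.0 / np.sqrt(np.cos(theta) ** 2 + (np.sin(theta) / aspect) ** 2)
    for k in (2, 3, 4):
        amp = rng.uniform(0.0, irregularity / k**2)
        r *= 1.0 + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    phi = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = pts @ rot.T
    pts *= math.sqrt(area / Polygon(pts).area)
    return pts


def _outward_offset(vertices: np.ndarray, distance: float) -> np.ndarray:
    """Parallel curve at the given outward normal distance."""
    nxt = np.roll(vertices, -1, axis=0)
    prv = np.roll(vertices, 1, axis=0)
    tangent = nxt - prv
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.stack([tangent[:, 1], -tangent[:, 0]], axis=1)
    centroid = vertices.mean(axis=0)
    sign = np.sign(np.sum((vertices - centroid) * normal, axis=1))
    sign[sign == 0] = 1.0
    return vertices + distance * normal * sign[:, None]


def _zigzag_tj(tortuosity: float, rng: np.random.Generator, width: float = 1.2) -> np.ndarray:
    """Sawtooth polyline whose length / bbox-diagonal ratio is exact.

    With n teeth spanning a w × h box the length is √(w² + n²h²) and the
    diagonal √(w² + h²); h is solved from the target ratio. A target of 1
    degenerates to a straight (axis-aligned) segment. The polyline is kept
    axis-aligned because the bounding rectangle is.
    """
    n = 4
    if tortuosity < 1.0:
        raise ValueError("tortuosity must be >= 1")
    if tortuosity < 1.0 + 1e-9:
        return np.array([[0.0, 0.0], [width, 0.0]])
    if tortuosity >= n:
        raise ValueError(f"tortuosity {tortuosity} not reachable with {n} teeth")
    h2 = (tortuosity**2 - 1.0) / (n**2 - tortuosity**2)
    h = width * math.sqrt(h2)
    xs = np.linspace(0.0, width, n + 1)
    ys = np.tile([0.0, h], n)[: n + 1]
    pts = np.stack([xs, ys], axis=1)
    return pts + rng.uniform(-3, 3, size=2)  # translation only: bbox is axis-aligned


def _place_arcs(
    ring: LineString, total_length: float, n_arcs: int, rng: np.random.Generator
) -> list[Polyline]:
    """Disjoint sub-arcs of a closed ring with exactly the summed length."""
    c = ring.length
    if total_length <= 0:
        return []
    if total_length > c:
        raise PhantomError("adhesion length exceeds BL circumference")
    splits = np.sort(rng.uniform(0.2, 0.8, size=n_arcs - 1)) if n_arcs > 1 else np.array([])
    lengths = np.diff(np.concatenate([[0.0], splits, [1.0]])) * total_length
    # spread arc start points around the ring, leaving gaps
    slack = c - total_length
    gap_weights = rng.dirichlet(np.ones(n_arcs)) * slack
    arcs, s = [], rng.uniform(0, c)
    for length, gap in zip(lengths, gap_weights):
        start = s % c
        end = start + length
        if end <= c:
            seg = substring(ring, start, end)
            coords = np.asarray(seg.coords)
        else:  # wraps around the ring start
            a = np.asarray(substring(ring, start, c).coords)
            b = np.asarray(substring(ring, 0, end - c).coords)
            coords = np.vstack([a, b[1:]])
        arcs.append(Polyline(coords))
        s = end + gap
    return arcs


def _pericyte_blob(area: float, anchor: np.ndarray, direction: np.ndarray, rng: np.random.Generator) -> Contour:
    """Elongated elliptical process of exact area, seated outside the BL."""
    theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    a_semi = max(0.8, math.sqrt(area))
    b_semi = area / (math.pi * a_semi)
    tang = np.array([-direction[1], direction[0]])
    pts = (
        anchor[None, :]
        + (b_semi + 0.15) * direction[None, :]
        + a_semi * np.cos(theta)[:, None] * tang[None, :]
        + b_semi * np.sin(theta)[:, None] * direction[None, :]
    )
    center = pts.mean(axis=0)
    pts = center + (pts - center) * math.sqrt(area / Polygon(pts).area)
    return Contour(pts)


# -- hole painting -----------------------------------------------------------


def _paint_holes(
    img: np.ndarray,
    inside: np.ndarray,
    target_area: float,
    pixel_size: float,
    band_width: float,
    bl_clearance: float,
    hole_intensity: float,
    rng: np.random.Generator,
) -> float:
    """Paint a bright electron-lucent blob into the perivascular band.

    Pixels strictly outside the capillary, beyond the BL but within the band,
    are swept in angular order from a random start until exactly
    round(target/px²) pixels are painted; returns the painted area (µm²).
    """
    from scipy.ndimage import distance_transform_edt

    target_px = int(round(target_area / pixel_size**2))
    if target_px == 0:
        return 0.0
    dist_out = distance_transform_edt(~inside) * pixel_size
    candidate = (dist_out > bl_clearance) & (dist_out <= band_width - pixel_size)
    rows, cols = np.nonzero(candidate)
    if rows.size < target_px:
        raise PhantomError("hole area exceeds the available perivascular band")
    cy, cx = np.mean(np.nonzero(inside), axis=1)
    ang = np.arctan2(rows - cy, cols - cx)
    start = rng.uniform(-np.pi, np.pi)
    order = np.argsort((ang - start) % (2 * np.pi))[:target_px]
    img[rows[order], cols[order]] = hole_intensity
    return target_px * pixel_size**2


# -- the phantom itself ------------------------------------------------------

MAX_REDRAWS = 60

#: parameters drawn before any geometry exists, in a fixed stream order
CONTEXT_FREE_PARAMETERS = (
    "capillary_area",
    "lumen_volume_fraction",
    "bl_thickness",
    "tj_tortuosity",
    "pericyte_area",
    "vesicle_density",
)
#: parameters whose feasible range depends on the realized contour; they are
#: drawn afterwards with the distribution truncated at the geometric bound
GEOMETRY_BOUND_PARAMETERS = ("pericyte_adhesion", "astrocyte_adhesion", "hole_area")


def make_capillary_phantom(
    config: PhantomConfig,
    animal_id: int,
    profile_id: int,
    with_image: bool = True,
) -> tuple[CapillaryProfile, dict]:
    """One phantom cross-section plus the ground truth of every drawn value.

    Deterministic in (config.seed, animal_id, profile_id). Size-free
    parameters are drawn first; adhesion lengths and hole area are then
    drawn truncated at what the realized contour can host (an arc cannot
    exceed the BL circumference, a hole cannot exceed the perivascular
    band), keeping the group means unbiased. Rare residual infeasibilities
    are redrawn up to a bounded number of attempts.
    """
    ss = np.random.SeedSequence((config.seed, animal_id, profile_id))
    rng = np.random.default_rng(ss)
    pars = config.parameters

    last_err: Optional[Exception] = None
    for _ in range(MAX_REDRAWS):
        try:
            drawn = {name: draw_parameter(name, *pars[name], rng) for name in CONTEXT_FREE_PARAMETERS}
            return _build_phantom(config, animal_id, profile_id, drawn, rng, with_image)
        except PhantomError as err:  # infeasible draw: try again
            last_err = err
    raise PhantomError(
        f"no feasible phantom after {MAX_REDRAWS} draws "
        f"({config.group_label} a{animal_id} p{profile_id}): {last_err}"
    )


def _build_phantom(
    config: PhantomConfig,
    animal_id: int,
    profile_id: int,
    drawn: dict,
    rng: np.random.Generator,
    with_image: bool,
) -> tuple[CapillaryProfile, dict]:
    irregular = 0.25 if config.group_label != "SHAM" else 0.12
    abluminal_pts = fourier_ellipse(drawn["capillary_area"], rng, irregularity=irregular)
    abluminal = Contour(abluminal_pts)
    centroid = np.array(abluminal.polygon.centroid.coords[0])

    # lumen: the same shape scaled about the centroid, so the area ratio is exact
    scale = math.sqrt(drawn["lumen_volume_fraction"])
    luminal = Contour(centroid + (abluminal_pts - centroid) * scale)

    bl_inner = abluminal
    t = drawn["bl_thickness"]
    outer_pts = _outward_offset(abluminal_pts, t) if t > 0 else abluminal_pts.copy()
    outer_poly = Polygon(outer_pts)
    if not outer_poly.is_valid or not outer_poly.covers(abluminal.polygon):
        raise PhantomError("BL offset curve self-intersects")
    bl_outer = Contour(outer_pts)

    ring = LineString(np.vstack([outer_pts, outer_pts[:1]]))
    circumference = ring.length

    # adhesion arcs and hole are drawn truncated at what this contour can host
    pars = config.parameters
    arc_cap = 0.98 * circumference
    drawn["pericyte_adhesion"] = draw_bounded(*pars["pericyte_adhesion"], 0.0, arc_cap, rng)
    drawn["astrocyte_adhesion"] = draw_bounded(*pars["astrocyte_adhesion"], 0.0, arc_cap, rng)
    band_capacity = 0.8 * (
        abluminal.polygon.buffer(config.band_width - config.pixel_size).area
        - outer_poly.area
    )
    drawn["hole_area"] = draw_bounded(*pars["hole_area"], 0.0, max(band_capacity, 0.0), rng)

    n_peri = 1 if drawn["pericyte_area"] < 3.0 else 2
    peri_arcs = _place_arcs(ring, drawn["pericyte_adhesion"], n_peri, rng)
    astro_arcs = _place_arcs(ring, drawn["astrocyte_adhesion"], int(rng.integers(1, 4)), rng)

    peri_contours = []
    if drawn["pericyte_area"] > 0 and peri_arcs:
        split = rng.dirichlet(np.ones(len(peri_arcs))) * drawn["pericyte_area"]
        for arc, area_i in zip(peri_arcs, split):
            if area_i <= 1e-3:
                continue
            mid = np.asarray(arc.linestring.interpolate(0.5, normalized=True).coords[0])
            direction = mid - centroid
            direction /= np.linalg.norm(direction)
            peri_contours.append(_pericyte_blob(area_i, mid, direction, rng))

    tj = Polyline(_zigzag_tj(drawn["tj_tortuosity"], rng) + centroid + np.array([0.0, 0.0]))

    n_fields = int(rng.integers(config.n_fields[0], config.n_fields[1] + 1))
    fields = []
    for _ in range(n_fields):
        a = config.field_area * rng.uniform(0.8, 1.2)
        fields.append((a, int(rng.poisson(drawn["vesicle_density"] * a))))
    realized_density = sum(c for _, c in fields) / sum(a for a, _ in fields)

    image = None
    origin = (0.0, 0.0)
    painted_hole = 0.0
    if with_image:
        margin = config.band_width + 0.5
        minx, miny, maxx, maxy = abluminal.polygon.bounds
        origin = (minx - margin, miny - margin)
        shape = (
            int(math.ceil((maxy - miny + 2 * margin) / config.pixel_size)),
            int(math.ceil((maxx - minx + 2 * margin) / config.pixel_size)),
        )
        image = rng.normal(config.background_intensity, config.background_noise_sd, size=shape)
        np.clip(image, 0, None, out=image)
        inside = rasterize_interior(abluminal.vertices, origin, config.pixel_size, shape)
        if drawn["hole_area"] > 0:
            painted_hole = _paint_holes(
                image,
                inside,
                drawn["hole_area"],
                config.pixel_size,
                config.band_width,
                bl_clearance=t + 2 * config.pixel_size,
                hole_intensity=config.hole_intensity,
                rng=rng,
            )
        image = image.astype(np.uint16)

    profile = CapillaryProfile(
        group=config.group_label,
        animal=f"a{animal_id}",
        profile=f"p{profile_id}",
        pixel_size=config.pixel_size,
        abluminal_contour=abluminal,
        luminal_contour=luminal,
        bl_inner=bl_inner,
        bl_outer=bl_outer,
        pericyte_contours=peri_contours,
        pericyte_adhesion=peri_arcs,
        astrocyte_adhesion=astro_arcs,
        tj_polylines=[tj],
        vesicle_fields=fields,
        intensity_image=image,
        image_origin=origin,
        flags=ProfileFlags(
            n_endothelial_cells=int(rng.integers(1, 3)),
            is_cross_section=True,
            contains_blood_or_plasma=False,
            has_visible_nucleus=False,
        ),
    )

    truth = {
        "group": config.group_label,
        "animal": f"a{animal_id}",
        "profile": f"p{profile_id}",
        "capillary_area": drawn["capillary_area"],
        "lumen_volume_fraction": drawn["lumen_volume_fraction"],
        "lumen_area": drawn["capillary_area"] * drawn["lumen_volume_fraction"],
        "endothelium_area": drawn["capillary_area"] * (1 - drawn["lumen_volume_fraction"]),
        "bl_thickness": drawn["bl_thickness"],
        "tj_tortuosity": drawn["tj_tortuosity"],
        "vesicle_density": realized_density,
        "vesicle_intensity": drawn["vesicle_density"],
        "pericyte_area": sum(c.area for c in peri_contours),
        "pericyte_adhesion": drawn["pericyte_adhesion"],
        "astrocyte_adhesion": drawn["astrocyte_adhesion"],
        "pericyte_coverage": drawn["pericyte_adhesion"] / circumference,
        "astrocyte_coverage": drawn["astrocyte_adhesion"] / circumference,
        "hole_area": painted_hole if with_image else drawn["hole_area"],
        "hole_area_drawn": drawn["hole_area"],
    }
    return profile, truth


def make_group_dataset(
    configs: list[PhantomConfig], seed: Optional[int] = None, with_images: bool = True
) -> tuple[list[CapillaryProfile], pd.DataFrame]:
    """Phantom profiles for several groups plus their ground-truth table.

    `seed`, when given, overrides every config's seed (each group gets a
    distinct derived stream). Reproducible: the same seed yields identical
    profiles and ground truth.
    """
    if not configs:
        raise ValueError("need at least one group config")
    profiles, rows = [], []
    for gi, cfg in enumerate(configs):
        if seed is not None:
            cfg = PhantomConfig(**{**cfg.__dict__, "seed": seed + 1000 * gi})
        for a in range(cfg.n_animals):
            for p in range(cfg.profiles_per_animal):
                prof, truth = make_capillary_phantom(cfg, a, p, with_image=with_images)
                profiles.append(prof)
                rows.append(truth)
    return profiles, pd.DataFrame(rows)


def draw_record_table(
    config: PhantomConfig, parameters: Optional[list[str]] = None
) -> pd.DataFrame:
    """Parameter draws only (no geometry): one row per phantom profile.

    The geometric pipeline reproduces drawn values exactly (verified by the
    round-trip tests), so analyses that depend only on the values — e.g.
    power simulations over many replicates — can run on this fast path.
    """
    pars = parameters or list(config.parameters)
    rows = []
    for a in range(config.n_animals):
        for p in range(config.profiles_per_animal):
            ss = np.random.SeedSequence((config.seed, a, p))
            rng = np.random.default_rng(ss)
            # same stream order as the geometric path, so size-free draws are
            # bit-identical; geometry-bound parameters use their physical
            # bounds here (the contour-specific truncation is almost never
            # active, so the distributions agree to high accuracy)
            drawn = {
                name: draw_parameter(name, *config.parameters[name], rng)
                for name in CONTEXT_FREE_PARAMETERS
            }
            for name in GEOMETRY_BOUND_PARAMETERS:
                drawn[name] = draw_parameter(name, *config.parameters[name], rng)
            row = {"group": config.group_label, "animal": f"a{a}", "profile": f"p{p}"}
            row.update({k: drawn[k] for k in pars})
            rows.append(row)
    return pd.DataFrame(rows)


# -- colocalization volumes --------------------------------------------------


@dataclass
class ColocSimConfig:
    """Settings for a correlated two-channel volume phantom."""

    shape: tuple[int, int, int] = (32, 64, 64)
    voxel_size: tuple[float, float, float] = (0.82, 0.414, 0.414)  # z, y, x µm
    rho: float = 0.8  # target Pearson coefficient between channels
    coloc_fraction: float = 1.0  # share of each channel's signal that is colocalized
    blur_sigma: float = 1.5  # voxel-units Gaussian width of the blob texture
    noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("volume shape must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")


def make_coloc_volume(config: ColocSimConfig):
    """Two-channel volume with controlled correlation and colocalized share.

    With ``coloc_fraction = 1`` both channels everywhere mix a shared
    smoothed component S with independent components in proportions solved
    from rho (corr = ±α²/(α²+β²) with α² = |rho|; negative rho inverts the
    shared component), so the empirical whole-stack Pearson coefficient hits
    rho directly. With ``coloc_fraction < 1`` the signal instead occupies
    sparse supports over a dark background: a shared support carries the
    rho-correlated pair and each channel gets its own private support, sized
    so the shared support holds ~`coloc_fraction` of each channel's signal
    mass — the regime threshold-based (Costes) analysis is built for, where
    rho is the correlation of the colocalized voxels.
    """
    from scipy.ndimage import gaussian_filter

    from .coloc import VolumePair

    rng = np.random.default_rng(config.seed)

    def texture() -> np.ndarray:
        x = gaussian_filter(rng.normal(size=config.shape), config.blur_sigma)
        x -= x.mean()
        sd = x.std()
        if sd == 0:
            raise ValueError("degenerate texture (volume too small for blur width)")
        return x / sd

    alpha = math.sqrt(abs(config.rho))
    beta = math.sqrt(1.0 - abs(config.rho))
    s = texture()
    shared_b = s if config.rho >= 0 else -s
    ta = alpha * s + beta * texture()
    tb = alpha * shared_b + beta * texture()

    if config.coloc_fraction >= 1.0:
        a, b = ta, tb
        if config.noise_scale > 0:
            a = a + config.noise_scale * rng.normal(size=config.shape)
            b = b + config.noise_scale * rng.normal(size=config.shape)
        a = np.clip(a * 500.0 + 2000.0, 0, None)
        b = np.clip(b * 500.0 + 2000.0, 0, None)
        return VolumePair(channel_a=a, channel_b=b, voxel_size=config.voxel_size)

    if config.rho < 0:
        raise ValueError("negative rho requires coloc_fraction = 1 (global mixture)")

    # sparse-support mode: signal lives on ~30% of voxels, partitioned into
    # shared / a-only / b-only so each channel's colocalized mass share is f
    f = config.coloc_fraction
    support = texture() > stats.norm.ppf(1 - 0.3)
    idx = np.nonzero(support.ravel())[0]
    q = f / (2.0 - f)  # shared share of the support, so shared/|channel| = f
    u = rng.random(idx.size)
    shared_idx = idx[u < q]
    a_only = idx[(u >= q) & (u < q + (1 - q) / 2)]
    b_only = idx[u >= q + (1 - q) / 2]

    base, amp, bg = 1500.0, 250.0, 20.0
    a = np.abs(rng.normal(bg, bg / 2, size=config.shape)).ravel()
    b = np.abs(rng.normal(bg, bg / 2, size=config.shape)).ravel()
    a[shared_idx] = base + amp * ta.ravel()[shared_idx]
    b[shared_idx] = base + amp * tb.ravel()[shared_idx]
    a[a_only] = base + amp * texture().ravel()[a_only]
    b[b_only] = base + amp * texture().ravel()[b_only]
    a = np.clip(a, 0, None).reshape(config.shape)
    b = np.clip(b, 0, None).reshape(config.shape)
    return VolumePair(channel_a=a, channel_b=b, voxel_size=config.voxel_size)


# -- molecular tables and grade sheets ---------------------------------------


def make_ct_table(
    genes: list[str],
    group_folds: dict[str, dict[str, float]],
    n_per_group: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "GAPDH",
    control_group: str = "SHAM",
) -> pd.DataFrame:
    """Synthetic qPCR CT table with known per-group fold effects.

    `group_folds[group][gene]` is the true expression fold relative to the
    control group (control folds are 1); a fold of 2 lowers the gene's ΔCT by
    exactly one cycle. Columns: sample, group, gene, ct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    base_ct = {g: 24.0 + 2.0 * i for i, g in enumerate(genes)}
    for group, folds in group_folds.items():
        for i in range(n_per_group):
            sample = f"{group}_{i}"
            ref_ct = 18.0 + rng.normal(0, noise_sd)
            rows.append({"sample": sample, "group": group, "gene": reference_gene, "ct": ref_ct})
            for gene in genes:
                fold = 1.0 if group == control_group else folds.get(gene, 1.0)
                ct = base_ct[gene] - math.log2(fold) + ref_ct - 18.0 + rng.normal(0, noise_sd)
                rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    return pd.DataFrame(rows)


def make_grade_sheet(
    n: int, distribution: tuple[float, float, float, float] = (0.1, 0.2, 0.4, 0.3), seed: int = 0
) -> pd.DataFrame:
    """Six-segment hemorrhage grade sheets: columns animal, seg1..seg6.

    Each segment grade is drawn i.i.d. from the categorical distribution over
    {0, 1, 2, 3}. n = 0 yields an empty sheet.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(distribution, dtype=float)
    probs = probs / probs.sum()
    rows = []
    for i in range(n):
        grades = rng.choice(4, size=6, p=probs)
        rows.append({"animal": f"r{i}", **{f"seg{j + 1}": int(g) for j, g in enumerate(grades)}})
    return pd.DataFrame(rows, columns=["animal"] + [f"seg{j + 1}" for j in range(6)])


def make_lane_table(
    group_folds: dict[str, float],
    n_per_group: int,
    n_membranes: int = 2,
    noise_sd: float = 0.0,
    seed: int = 0,
    control_group: str = "SHAM",
) -> pd.DataFrame:
    """Synthetic densitometry lanes with per-membrane multiplicative gains.

    True normalized target levels are `group_folds[group]` (control 1.0);
    each membrane applies its own gain to every band and background, which
    per-membrane normalization must cancel. Columns: membrane, sample,
    group, band, background_above, background_below, loading.
    """
    rng = np.random.default_rng(seed)
    rows = []
    groups = list(group_folds)
    if control_group not in groups:
        groups = [control_group] + groups
    for m in range(n_membranes):
        gain = rng.uniform(0.6, 1.6)
        for group in groups:
            fold = 1.0 if group == control_group else group_folds.get(group, 1.0)
            for i in range(n_per_group):
                level = fold * math.exp(rng.normal(0, noise_sd))
                loading = 500.0 * math.exp(rng.normal(0, noise_sd / 2 if noise_sd else 0.0))
                bg = 80.0
                rows.append(
                    {
                        "membrane": f"m{m}",
                        "sample": f"m{m}_{group}_{i}",
                        "group": group,
                        "band": gain * (level * loading + bg),
                        "background_above": gain * bg,
                        "background_below": gain * bg,
                        # the loading lane carries the same additive background,
                        # which blot_fold_changes subtracts before normalizing
                        "loading": gain * (loading + bg),
                    }
                )
    return pd.DataFrame(rows)
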