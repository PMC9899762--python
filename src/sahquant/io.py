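"""File formats: layered annotation JSON, grayscale TIFF, CSV tables.

An annotation file is a GeoJSON-like JSON document with named layers in a
declared µm coordinate system: closed contours ("abluminal", "lumen",
"bl_inner", "bl_outer", "pericyte[i]"), open polylines
("pericyte_adhesion[i]", "astrocyte_adhesion[i]", "tj[i]") and vesicle-count
fields ("vesicle_field[i]"). The aligned intensity image travels as a
separate 16-bit grayscale TIFF referenced from the document. All invariants
are re-checked on load; schema violations name the offending layer.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .coloc import VolumePair
from .geometry import Contour, GeometryError, Polyline
from .morphometry import CapillaryProfile, MorphometryRecord, ProfileFlags

_CONTOUR_LAYERS = ("abluminal", "lumen", "bl_inner", "bl_outer")
_INDEXED = re.compile(
    r"^(pericyte|pericyte_adhesion|astrocyte_adhesion|tj|vesicle_field)\[(\d+)\]$"
)


class AnnotationError(ValueError):
    pass


def write_profile(profile: CapillaryProfile, path: str | Path) -> Path:
    """Write a profile as annotation JSON (+ sibling TIFF for its image)."""
    path = Path(path)
    layers: dict = {}
    layers["abluminal"] = {"type": "contour", "coordinates": profile.abluminal_contour.vertices.tolist()}
    layers["lumen"] = {"type": "contour", "coordinates": profile.luminal_contour.vertices.tolist()}
    if profile.bl_inner is not None and profile.bl_outer is not None:
        layers["bl_inner"] = {"type": "contour", "coordinates": profile.bl_inner.vertices.tolist()}
        layers["bl_outer"] = {"type": "contour", "coordinates": profile.bl_outer.vertices.tolist()}
    for i, c in enumerate(profile.pericyte_contours):
        layers[f"pericyte[{i}]"] = {"type": "contour", "coordinates": c.vertices.tolist()}
    for name, items in (
        ("pericyte_adhesion", profile.pericyte_adhesion),
        ("astrocyte_adhesion", profile.astrocyte_adhesion),
        ("tj", profile.tj_polylines),
    ):
        for i, pl in enumerate(items):
            layers[f"{name}[{i}]"] = {"type": "polyline", "coordinates": pl.vertices.tolist()}
    for i, (area, count) in enumerate(profile.vesicle_fields):
        layers[f"vesicle_field[{i}]"] = {"type": "field", "area": area, "count": count}

    doc = {
        "coordinate_units": "um",
        "group": profile.group,
        "animal": profile.animal,
        "profile": profile.profile,
        "pixel_size": profile.pixel_size,
        "image_origin": list(profile.image_origin),
        "flags": asdict(profile.flags) if profile.flags else None,
        "image": None,
        "layers": layers,
    }
    if profile.intensity_image is not None:
        image_path = path.with_suffix(".tif")
        tifffile.imwrite(image_path, np.asarray(profile.intensity_image, dtype=np.uint16))
        doc["image"] = image_path.name
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")
    return path


def _coords(layer_name: str, entry: dict) -> np.ndarray:
    coords = np.asarray(entry.get("coordinates", []), dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise AnnotationError(f"layer {layer_name!r}: coordinates must be an (n, 2) list")
    return coords


def read_profile(path: str | Path) -> CapillaryProfile:
    """Load and validate an annotation file into a CapillaryProfile."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("coordinate_units") != "um":
        raise AnnotationError(f"{path}: coordinate_units must be 'um'")
    layers = doc.get("layers", {})

    contours: dict[str, Contour] = {}
    pericytes: dict[int, Contour] = {}
    polylines: dict[str, dict[int, Polyline]] = {
        "pericyte_adhesion": {}, "astrocyte_adhesion": {}, "tj": {}
    }
    fields: dict[int, tuple[float, int]] = {}
    for name, entry in layers.items():
        try:
            if name in _CONTOUR_LAYERS:
                contours[name] = Contour(_coords(name, entry))
                continue
            m = _INDEXED.match(name)
            if not m:
                raise AnnotationError(f"{path}: unknown layer {name!r}")
            kind, idx = m.group(1), int(m.group(2))
            if kind == "pericyte":
                pericytes[idx] = Contour(_coords(name, entry))
            elif kind == "vesicle_field":
                fields[idx] = (float(entry["area"]), int(entry["count"]))
            else:
                polylines[kind][idx] = Polyline(_coords(name, entry))
        except GeometryError as err:
            raise AnnotationError(f"{path}: layer {name!r}: {err}") from err

    for required in ("abluminal", "lumen"):
        if required not in contours:
            raise AnnotationError(f"{path}: missing required layer {required!r}")

    image = None
    if doc.get("image"):
        image = tifffile.imread(path.parent / doc["image"])

    flags = ProfileFlags(**doc["flags"]) if doc.get("flags") else None
    return CapillaryProfile(
        group=doc["group"],
        animal=doc["animal"],
        profile=doc["profile"],
        pixel_size=float(doc["pixel_size"]),
        abluminal_contour=contours["abluminal"],
        luminal_contour=contours["lumen"],
        bl_inner=contours.get("bl_inner"),
        bl_outer=contours.get("bl_outer"),
        pericyte_contours=[pericytes[i] for i in sorted(pericytes)],
        pericyte_adhesion=[polylines["pericyte_adhesion"][i] for i in sorted(polylines["pericyte_adhesion"])],
        astrocyte_adhesion=[polylines["astrocyte_adhesion"][i] for i in sorted(polylines["astrocyte_adhesion"])],
        tj_polylines=[polylines["tj"][i] for i in sorted(polylines["tj"])],
        vesicle_fields=[fields[i] for i in sorted(fields)],
        intensity_image=image,
        image_origin=tuple(doc.get("image_origin", (0.0, 0.0))),
        flags=flags,
    )


def write_records(records: list[MorphometryRecord], path: str | Path) -> Path:
    """Per-profile morphometry records as CSV, one row per profile."""
    path = Path(path)
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"group", "animal", "profile"} - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: records CSV missing columns {sorted(missing)}")
    return df


def read_volume_pair(
    path_a: str | Path,
    path_b: str | Path,
    voxel_size: Optional[tuple[float, float, float]] = None,
) -> VolumePair:
    """Two multi-page grayscale TIFF stacks as an aligned volume pair.

    Voxel size comes from the argument or a YAML sidecar named
    `<path_a stem>.yaml` with a `voxel_size: [z, y, x]` entry.
    """
    a = tifffile.imread(path_a)
    b = tifffile.imread(path_b)
    if voxel_size is None:
        import yaml

        sidecar = Path(path_a).with_suffix(".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
            voxel_size = tuple(float(v) for v in meta["voxel_size"])
        else:
            voxel_size = (1.0, 1.0, 1.0)
    return VolumePair(channel_a=a, channel_b=b, voxel_size=voxel_size)


def write_volume_pair(pair: VolumePair, path_a: str | Path, path_b: str | Path) -> None:
    import yaml

    tifffile.imwrite(path_a, pair.channel_a.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(path_b, pair.channel_b.astype(np.float32), photometric="minisblack")
    Path(path_a).with_suffix(".yaml").write_text(
        yaml.safe_dump({"voxel_size": [float(v) for v in pair.voxel_size]})
    )
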