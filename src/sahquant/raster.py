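"""Shared polygon rasterization so generator and measurement agree pixel-for-pixel."""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw


def rasterize_interior(
    vertices_um: np.ndarray,
    origin_um: tuple[float, float],
    pixel_size: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of pixels inside a polygon given in µm coordinates.

    `origin_um` is the µm position of pixel (row 0, col 0); pixel centers sit
    on the integer lattice of the image frame. Scanline fill via PIL.
    """
    ox, oy = origin_um
    cols = (vertices_um[:, 0] - ox) / pixel_size
    rows = (vertices_um[:, 1] - oy) / pixel_size
    img = Image.new("1", (shape[1], shape[0]), 0)
    ImageDraw.Draw(img).polygon(list(zip(cols.tolist(), rows.tolist())), fill=1)
    return np.asarray(img, dtype=bool)
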