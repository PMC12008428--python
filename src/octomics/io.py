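"""File formats: 8-bit grayscale PNG images, mask PNGs, polygon-annotation
JSON (labeling-tool style), and cohort CSV tables.

Coordinates are 0-based and row-major internally; polygon JSON uses
(x, y) = (col, row) vertices as common labeling tools export them. A
pixel (r, c) covers the unit square [c, c+1) x [r, r+1); it is
foreground when its center (c+0.5, r+0.5) falls inside a polygon under
the even-odd (crossing-number) rule; multiple polygons are unioned.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .features.image import BScanImage, InputError, ROIMask

log = logging.getLogger(__name__)


def write_image_png(image: BScanImage, path) -> None:
    px = np.asarray(image.pixels)
    if px.dtype != np.uint8:
        px = np.round(np.clip(px, 0, 255)).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path)


def read_image_png(path, spacing_mm=(0.011, 0.011), id: str = "") -> BScanImage:
    px = np.asarray(Image.open(path).convert("L"))
    return BScanImage(pixels=px, spacing_mm=spacing_mm, id=id or Path(path).stem)


def write_mask_png(mask: ROIMask, path) -> None:
    Image.fromarray((mask.pixels.astype(np.uint8) * 255), mode="L").save(path)


def read_mask_png(path) -> ROIMask:
    px = np.asarray(Image.open(path).convert("L"))
    return ROIMask(pixels=px > 0)


def _point_in_polygon_evenodd(px_x, px_y, vertices: np.ndarray) -> np.ndarray:
    """Vectorized crossing-number test for points against one polygon."""
    inside = np.zeros(px_x.shape, dtype=bool)
    n = len(vertices)
    x, y = px_x, px_y
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y))
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def read_mask_polygons(json_doc, image_shape) -> ROIMask:
    """Rasterize a polygon-annotation document to a binary mask.

    Accepts a dict (labeling-tool export with ``shapes: [{points: ...}]``),
    a plain list of polygons, or a path to a JSON file. Degenerate
    polygons (< 3 vertices) are skipped with a warning; an empty result
    is an input error.
    """
    if isinstance(json_doc, (str, Path)):
        with open(json_doc) as fh:
            json_doc = json.load(fh)
    if isinstance(json_doc, dict):
        polys = [np.asarray(s["points"], dtype=float) for s in json_doc.get("shapes", [])]
    else:
        polys = [np.asarray(p, dtype=float) for p in json_doc]
    h, w = image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = xx + 0.5, yy + 0.5  # pixel centers in (x, y) annotation coords
    mask = np.zeros((h, w), dtype=bool)
    n_used = 0
    for poly in polys:
        if len(poly) < 3:
            warnings.warn("degenerate polygon (<3 vertices) skipped", stacklevel=2)
            continue
        mask |= _point_in_polygon_evenodd(cx, cy, poly)
        n_used += 1
    if n_used == 0 or not mask.any():
        raise InputError("polygon annotation produced an empty mask")
    return ROIMask(pixels=mask)


def write_mask_polygons(mask: ROIMask, path, image_filename: str = "") -> None:
    """Export a mask's connected components as polygon annotations."""
    from skimage import measure

    shapes = []
    padded = np.pad(mask.pixels.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        pts = [[float(c - 1.0), float(r - 1.0)] for r, c in contour[::4]]
        if len(pts) >= 3:
            shapes.append({"label": "roi", "points": pts, "shape_type": "polygon"})
    doc = {"imagePath": image_filename, "shapes": shapes}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_cohort(eyes, out_dir) -> None:
    """Persist a synthetic cohort: PNGs, mask PNGs + polygon JSON, clinical CSV."""
    from .synthetic import cohort_clinical_table

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for eye in eyes:
        write_image_png(eye.image, out / "images" / f"{eye.eye_id}.png")
        write_mask_png(eye.mask, out / "masks" / f"{eye.eye_id}.png")
        write_mask_polygons(eye.mask, out / "masks" / f"{eye.eye_id}.json",
                            image_filename=f"{eye.eye_id}.png")
    cohort_clinical_table(eyes).to_csv(out / "clinical.csv")
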