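"""Gland-level patch extraction from polygon annotations.

Glands arrive as GeoJSON polygons in slide pixel coordinates with a grade
property; they are rasterized into the label codebook and cut out with one
of three bounding-box styles: ``tight`` (minimal box), ``squared`` (tight
box expanded symmetrically to a square) or ``fixed`` (constant edge
centered on the gland).

Rasterization uses a pixel-center rule: a pixel (x, y) belongs to a gland
when its center (x + 0.5, y + 0.5) lies strictly inside the polygon. This
is a half-open fill — adjacent glands sharing an integer-coordinate edge
never double-claim boundary pixels, and an axis-aligned square of side s
fills exactly s^2 pixels.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import shapely

from .core_io import GRADE_CODES, PatchRecord, Window

__all__ = [
    "GlandAnnotation",
    "BoundingBoxMode",
    "rasterize",
    "bounding_box",
    "extract_gland_patches",
    "read_annotations",
    "write_annotations",
]

logger = logging.getLogger(__name__)


@dataclass
class GlandAnnotation:
    """One delineated gland: id, polygon vertices (x, y) and its grade."""

    gland_id: str
    polygon: np.ndarray  # (n_vertices, 2) float, slide pixel coordinates
    grade: str

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError(f"gland {self.gland_id}: polygon needs >= 3 (x, y) vertices")
        if self.grade not in GRADE_CODES:
            raise ValueError(
                f"gland {self.gland_id}: unknown grade {self.grade!r}; "
                f"allowed: {', '.join(GRADE_CODES)}"
            )
        if not self.shapely().is_valid:
            raise ValueError(f"gland {self.gland_id}: degenerate or self-intersecting polygon")

    def shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.polygon)

    @property
    def code(self) -> int:
        return GRADE_CODES[self.grade]


@dataclass(frozen=True)
class BoundingBoxMode:
    """Patch cutting style: tight, squared, or fixed (with ``fixed_edge``)."""

    mode: str = "tight"
    fixed_edge: int = 400

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "squared", "tight"):
            raise ValueError(f"unknown bounding-box mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_edge <= 0:
            raise ValueError("fixed_edge must be positive for fixed mode")


def _fill_pixels(poly: shapely.Polygon, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of pixels whose centers fall inside the polygon."""
    height, width = shape
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(math.floor(minx)), 0)
    y0 = max(int(math.floor(miny)), 0)
    x1 = min(int(math.ceil(maxx)) + 1, width)
    y1 = min(int(math.ceil(maxy)) + 1, height)
    if x1 <= x0 or y1 <= y0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xs, ys = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(ys.shape)
    rows, cols = np.nonzero(inside)
    return rows + y0, cols + x0


def rasterize(annotations: Iterable[GlandAnnotation], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize gland polygons onto a (height, width) label mask.

    Non-gland pixels stay 0. When glands overlap, later annotations
    overwrite earlier ones and the overlap pixel count is logged.
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for ann in annotations:
        rows, cols = _fill_pixels(ann.shapely(), shape)
        overlap = int((mask[rows, cols] != 0).sum())
        if overlap:
            logger.warning("gland %s overwrites %d already-labeled pixels", ann.gland_id, overlap)
        mask[rows, cols] = ann.code
    return mask


def _clip_window(x0: int, y0: int, width: int, height: int, shape: tuple[int, int]) -> Window:
    H, W = shape
    cx0, cy0 = max(x0, 0), max(y0, 0)
    cx1, cy1 = min(x0 + width, W), min(y0 + height, H)
    if (cx0, cy0, cx1, cy1) != (x0, y0, x0 + width, y0 + height):
        logger.info("bounding box clipped to slide bounds")
    if cx1 <= cx0 or cy1 <= cy0:
        raise ValueError("bounding box lies entirely outside the slide")
    return Window(cx0, cy0, cx1 - cx0, cy1 - cy0)


def bounding_box(
    annotation: GlandAnnotation, mode: BoundingBoxMode, shape: tuple[int, int]
) -> Window:
    """Bounding window for a gland under the chosen mode, clipped in-bounds.

    tight: the minimal axis-aligned pixel box. squared: the tight box grown
    symmetrically along its shorter axis to a square (odd remainders go to
    the low side). fixed: a ``fixed_edge`` square centered on the tight
    box's center.
    """
    minx, miny, maxx, maxy = annotation.shapely().bounds
    tx0, ty0 = int(math.floor(minx)), int(math.floor(miny))
    tx1, ty1 = int(math.ceil(maxx)), int(math.ceil(maxy))
    tw, th = tx1 - tx0, ty1 - ty0

    if mode.mode == "tight":
        return _clip_window(tx0, ty0, tw, th, shape)
    if mode.mode == "squared":
        edge = max(tw, th)
        pad_x, pad_y = edge - tw, edge - th
        return _clip_window(tx0 - (pad_x + 1) // 2, ty0 - (pad_y + 1) // 2, edge, edge, shape)
    # fixed: center the constant-edge box on the tight box's center
    cx, cy = tx0 + tw / 2.0, ty0 + th / 2.0
    edge = mode.fixed_edge
    return _clip_window(round(cx - edge / 2.0), round(cy - edge / 2.0), edge, edge, shape)


def extract_gland_patches(
    slide_id: str,
    image: np.ndarray,
    annotations: Iterable[GlandAnnotation],
    mode: BoundingBoxMode = BoundingBoxMode(),
) -> list[tuple[np.ndarray, PatchRecord]]:
    """Cut one patch per annotated gland; sizes vary for tight/squared modes."""
    image = np.asarray(image)
    out = []
    for ann in annotations:
        w = bounding_box(ann, mode, image.shape[:2])
        record = PatchRecord(
            slide_id=slide_id,
            window=w,
            target_code=ann.code,
            coverage=1.0,
            purity=1.0,
            accepted=True,
        )
        out.append((image[w.slices], record))
    return out


# -- GeoJSON IO ---------------------------------------------------------------


def read_annotations(path: str | Path) -> list[GlandAnnotation]:
    """Read gland polygons from a GeoJSON FeatureCollection.

    Each feature must be a Polygon with properties ``gland_id`` and
    ``grade`` (benign/GS3/GS4/GS5).
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    anns = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(f"{path}: feature {i} is not a Polygon")
        props = feat.get("properties", {})
        anns.append(
            GlandAnnotation(
                gland_id=str(props.get("gland_id", f"gland-{i}")),
                polygon=np.asarray(geom["coordinates"][0], dtype=float),
                grade=props["grade"],
            )
        )
    return anns


def write_annotations(path: str | Path, annotations: Iterable[GlandAnnotation]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ann.polygon.tolist()]},
            "properties": {"gland_id": ann.gland_id, "grade": ann.grade},
        }
        for ann in annotations
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
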