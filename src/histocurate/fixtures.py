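"""Synthetic slide and patch generators for desk-scale pipeline runs.

Everything downstream — window synthesis, gland extraction, curation,
training, evaluation — can be exercised on these fixtures without any
external download. The generator emulates the structural properties the
pipeline depends on, not histological realism:

* a biopsy-core-shaped tissue region on a light glass background, dark
  enough for Otsu foreground isolation;
* gland-like blobs whose tight bounding boxes fall within 15% of nominal
  edges of 120, 240, 360 or 720 pixels — lumen-ring ellipses for benign
  and GS3 (distinct lumen fractions), fused multi-lobed blobs for GS4 and
  GS5;
* label masks consistent with the emitted polygons (the mask is produced
  by rasterizing those same polygons over a stroma base);
* class-dependent color/texture separable by simple summary features; and
* per-source global color shifts standing in for staining differences
  between laboratories.

All outputs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    CODE_STROMA,
    GRADE_CODES,
    SlideRecord,
)
from .gland_extract import GlandAnnotation, rasterize

__all__ = [
    "CLASS_STYLE",
    "FixtureSpec",
    "SlideBundle",
    "PatchSet",
    "make_slide",
    "make_engineered_slide",
    "make_cohort",
    "make_separable_patch_set",
]

# per-class rendering style: base RGB, lumen fraction (of gland area), noise sd
CLASS_STYLE = {
    "benign": {"color": (225, 185, 205), "lumen": 0.30, "noise": 6.0},
    "GS3": {"color": (198, 140, 188), "lumen": 0.12, "noise": 6.0},
    "GS4": {"color": (168, 112, 168), "lumen": 0.04, "noise": 7.0},
    "GS5": {"color": (138, 95, 150), "lumen": 0.01, "noise": 8.0},
}
_STROMA_COLOR = (234, 205, 218)
_BACKGROUND_COLOR = (246, 245, 246)
_LUMEN_COLOR = (250, 246, 250)

#: additive stain shift per source cohort (affine color model of Fig-5-style
#: laboratory variation)
STAIN_SHIFT = {"cohortA": (0, 0, 0), "cohortB": (14, -10, 8)}

_DIAGNOSIS_FOR_CLASS = {"benign": "benign", "GS3": "3+3", "GS4": "4+4", "GS5": "5+4"}
_GS5_DIAGNOSES = ("4+5", "5+4", "5+5")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic slide."""

    slide_shape: tuple[int, int] = (1400, 1000)
    glands_per_class: dict[str, int] = field(default_factory=lambda: {"benign": 4, "GS3": 4})
    gland_nominal_edges: tuple[int, ...] = (120, 240, 360, 720)
    source: str = "cohortA"
    seed: int | None = 0
    max_placement_retries: int = 80


@dataclass
class SlideBundle:
    """A generated slide with all its companion artifacts."""

    image: np.ndarray
    mask: np.ndarray
    annotations: list[GlandAnnotation]
    record: SlideRecord


@dataclass
class PatchSet:
    """Labeled patch images with ground truth for noise-injection studies."""

    images: np.ndarray  # (n, H, W, 3) uint8
    labels: np.ndarray  # training labels (possibly flipped)
    true_labels: np.ndarray
    flipped: np.ndarray  # bool, True where label was flipped
    sources: np.ndarray
    subjects: np.ndarray
    class_names: list[str]


def _blob_polygon(grade: str, edge: float, rng: np.random.Generator) -> np.ndarray:
    """Gland outline centered at the origin with max bbox dimension == edge.

    Benign/GS3 are single rotated ellipses (24-gons); GS4/GS5 fuse two or
    three overlapping lobes into one multi-lobed outline. The polygon is
    rescaled so its longer bounding-box edge equals ``edge`` exactly.
    """
    theta = np.linspace(0.0, 2.0 * math.pi, 24, endpoint=False)
    if grade in ("benign", "GS3"):
        aspect = rng.uniform(0.7, 1.0)
        rot = rng.uniform(-0.26, 0.26)
        pts = np.stack([0.5 * np.cos(theta), 0.5 * aspect * np.sin(theta)], axis=1)
        c, s = math.cos(rot), math.sin(rot)
        pts = pts @ np.array([[c, s], [-s, c]])
    else:
        import shapely

        n_lobes = int(rng.integers(2, 4))
        lobes = []
        for k in range(n_lobes):
            r = rng.uniform(0.22, 0.35)
            cx, cy = rng.uniform(-0.2, 0.2, size=2) if k else (0.0, 0.0)
            lobes.append(
                shapely.Polygon(np.stack([cx + r * np.cos(theta), cy + r * np.sin(theta)], axis=1))
            )
        merged = shapely.unary_union(lobes)
        if merged.geom_type != "Polygon":  # disjoint lobes: keep the largest
            merged = max(merged.geoms, key=lambda g: g.area)
        pts = np.asarray(merged.exterior.coords[:-1])
    # rescale so the larger bbox edge is exactly `edge`
    span = pts.max(axis=0) - pts.min(axis=0)
    pts = pts * (edge / span.max())
    return pts - (pts.max(axis=0) + pts.min(axis=0)) / 2.0


def _tissue_ellipse(shape: tuple[int, int]) -> tuple[np.ndarray, tuple]:
    """Boolean biopsy-core region: an elongated ellipse filling most of the slide."""
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ry, rx = 0.46 * H, 0.42 * W
    yy, xx = np.ogrid[:H, :W]
    region = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return region, (cy, cx, ry, rx)


def _render(
    mask: np.ndarray,
    tissue: np.ndarray,
    annotations: list[GlandAnnotation],
    source: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint the RGB slide from the label mask plus lumen highlights."""
    H, W = mask.shape
    img = np.empty((H, W, 3), dtype=np.float32)
    img[:] = _BACKGROUND_COLOR
    img[tissue] = _STROMA_COLOR
    for grade, style in CLASS_STYLE.items():
        sel = mask == GRADE_CODES[grade]
        if sel.any():
            img[sel] = style["color"]
    # lumen: a bright inner ellipse per gland, area ~ lumen fraction
    yy, xx = np.ogrid[:H, :W]
    for ann in annotations:
        frac = CLASS_STYLE[ann.grade]["lumen"]
        if frac <= 0.02:
            continue
        lo, hi = ann.polygon.min(axis=0), ann.polygon.max(axis=0)
        cx, cy = (lo + hi) / 2.0
        rx, ry = (hi - lo) / 2.0 * math.sqrt(frac)
        inner = ((yy - cy) / max(ry, 1.0)) ** 2 + ((xx - cx) / max(rx, 1.0)) ** 2 <= 1.0
        img[inner & (mask == ann.code)] = _LUMEN_COLOR
    shift = np.asarray(STAIN_SHIFT.get(source, (0, 0, 0)), dtype=np.float32)
    img[tissue] += shift
    img += rng.normal(0.0, 5.0, size=img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


def _diagnosis_from_mix(glands_per_class: dict[str, int]) -> str:
    present = [g for g, n in glands_per_class.items() if n > 0 and g != "benign"]
    if not present:
        return "benign"
    worst = max(present, key=lambda g: GRADE_CODES[g])
    return _DIAGNOSIS_FOR_CLASS[worst]


def make_slide(spec: FixtureSpec, rng: np.random.Generator | int | None = None) -> SlideBundle:
    """Generate a slide with placed gland blobs, its mask, polygons and record.

    Glands are placed by rejection sampling of non-overlapping bounding
    boxes inside the tissue core; a gland that cannot be placed within
    ``max_placement_retries`` attempts raises. The mask is built by
    rasterizing the emitted polygons over a stroma base, so polygons and
    mask gland pixels agree exactly by construction.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    H, W = spec.slide_shape
    tissue, (cy, cx, ry, rx) = _tissue_ellipse((H, W))

    annotations: list[GlandAnnotation] = []
    placed_boxes: list[tuple[float, float, float, float]] = []
    idx = 0
    for grade, count in spec.glands_per_class.items():
        if grade not in GRADE_CODES:
            raise ValueError(f"unknown gland class {grade!r}")
        for _ in range(count):
            feasible = [e for e in spec.gland_nominal_edges if e < 1.2 * min(ry, rx)]
            if not feasible:
                raise ValueError("no nominal gland edge fits the tissue core")
            nominal = int(rng.choice(feasible))
            edge = nominal * rng.uniform(0.92, 1.1)
            outline = _blob_polygon(grade, edge, rng)
            half = (outline.max(axis=0) - outline.min(axis=0)) / 2.0
            for attempt in range(spec.max_placement_retries):
                # center inside a shrunken tissue ellipse so the blob fits
                ang = rng.uniform(0.0, 2.0 * math.pi)
                rad = math.sqrt(rng.uniform(0.0, 1.0))
                gx = cx + rad * (rx - half[0] - 4) * math.cos(ang)
                gy = cy + rad * (ry - half[1] - 4) * math.sin(ang)
                box = (gx - half[0], gy - half[1], gx + half[0], gy + half[1])
                clash = any(
                    not (box[2] < b[0] or b[2] < box[0] or box[3] < b[1] or b[3] < box[1])
                    for b in placed_boxes
                )
                if not clash:
                    placed_boxes.append(box)
                    annotations.append(
                        GlandAnnotation(
                            gland_id=f"gland-{idx:03d}",
                            polygon=outline + np.array([gx, gy]),
                            grade=grade,
                        )
                    )
                    idx += 1
                    break
            else:
                raise ValueError(
                    f"could not place a {grade} gland of edge {edge:.0f} px after "
                    f"{spec.max_placement_retries} retries"
                )

    gland_mask = rasterize(annotations, (H, W))
    mask = np.where(tissue, CODE_STROMA, 0).astype(np.uint8)
    mask[gland_mask > 0] = gland_mask[gland_mask > 0]
    image = _render(mask, tissue, annotations, spec.source, rng)
    record = SlideRecord(
        slide_id=f"{spec.source}-slide-{rng.integers(0, 10**9):09d}",
        source=spec.source,
        diagnosis=_diagnosis_from_mix(spec.glands_per_class),
    )
    return SlideBundle(image=image, mask=mask, annotations=annotations, record=record)


def make_engineered_slide(
    grade: str,
    slide_id: str,
    source: str = "cohortB",
    shape: tuple[int, int] = (1200, 1200),
    margin: int = 40,
    diagnosis: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SlideRecord, np.ndarray, np.ndarray]:
    """A slide whose tissue is one large pure region of the target class.

    A 1200 x 1200 slide gives a 600 x 600 scan-grid mask on which the
    default synthesizer finds a 5 x 5 grid of 200-edge windows at
    p_omega = 0.5 — 25 accepted candidates, comfortably above the 20-patch
    retention cut, so no overlap escalation is needed.
    """
    rng = np.random.default_rng(rng)
    if grade not in GRADE_CODES:
        raise ValueError(f"unknown grade {grade!r}")
    H, W = shape
    mask = np.zeros((H, W), dtype=np.uint8)
    mask[margin : H - margin, margin : W - margin] = GRADE_CODES[grade]

    style = CLASS_STYLE[grade]
    jitter = rng.normal(0.0, 4.0, size=3)  # per-slide stain wobble
    img = rng.standard_normal((H, W, 3), dtype=np.float32)
    img *= style["noise"]
    img += np.asarray(_BACKGROUND_COLOR, dtype=np.float32)
    # tissue is rectangular, so a slice add beats masked indexing
    img[margin : H - margin, margin : W - margin] += (
        np.asarray(style["color"], dtype=np.float32)
        + jitter
        + np.asarray(STAIN_SHIFT.get(source, (0, 0, 0)), dtype=np.float32)
        - np.asarray(_BACKGROUND_COLOR, dtype=np.float32)
    )
    image = np.clip(img, 0, 255, out=img).astype(np.uint8)

    record = SlideRecord(
        slide_id=slide_id,
        source=source,
        diagnosis=diagnosis if diagnosis is not None else _DIAGNOSIS_FOR_CLASS[grade],
    )
    return record, image, mask


def make_cohort(
    n_per_class: int,
    classes: tuple[str, ...] = ("benign", "GS3", "GS4", "GS5"),
    shape: tuple[int, int] = (1200, 1200),
    source: str = "cohortB",
    rng: np.random.Generator | int | None = None,
):
    """Yield (record, image, mask) for an engineered multi-class slide cohort.

    Diagnoses follow the eligibility rules (benign, 3+3, 4+4; GS5 slides
    cycle through 4+5, 5+4 and 5+5). A generator, so slides are produced
    one at a time and never held in memory together.
    """
    rng = np.random.default_rng(rng)
    for grade in classes:
        for i in range(n_per_class):
            if grade == "GS5":
                diagnosis = _GS5_DIAGNOSES[i % len(_GS5_DIAGNOSES)]
            else:
                diagnosis = _DIAGNOSIS_FOR_CLASS[grade]
            yield make_engineered_slide(
                grade,
                slide_id=f"{source}-{grade}-{i:04d}",
                source=source,
                shape=shape,
                diagnosis=diagnosis,
                rng=rng,
            )


def make_separable_patch_set(
    n_per_class: int,
    classes: tuple[str, ...] = ("benign", "GS3"),
    patch_shape: tuple[int, int] = (64, 64),
    flip_rate: float = 0.0,
    two_source: bool = False,
    rng: np.random.Generator | int | None = None,
) -> PatchSet:
    """Labeled patch images with class-conditional texture, optionally noised.

    Class base colors are separated far beyond the pixel noise, so the
    reference classifier separates them reliably. ``flip_rate`` flips each
    label independently to a different class (binomial planting) for
    consensus-outlier studies; ``two_source`` applies the cohortB stain
    shift to a random half of the patches.
    """
    rng = np.random.default_rng(rng)
    H, W = patch_shape
    n_total = n_per_class * len(classes)
    images = np.empty((n_total, H, W, 3), dtype=np.uint8)
    true_labels = np.repeat(np.arange(len(classes)), n_per_class)
    sources = np.full(n_total, "cohortA", dtype=object)
    if two_source:
        sources[rng.random(n_total) < 0.5] = "cohortB"

    yy, xx = np.ogrid[:H, :W]
    for i, cls_idx in enumerate(true_labels):
        style = CLASS_STYLE[classes[cls_idx]]
        base = np.asarray(style["color"], dtype=np.float32) + rng.normal(0.0, 3.0, size=3)
        img = np.empty((H, W, 3), dtype=np.float32)
        img[:] = base
        frac = style["lumen"]
        if frac > 0.02:
            r = math.sqrt(frac * H * W / math.pi)
            cy = rng.uniform(r, H - r)
            cx = rng.uniform(r, W - r)
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = _LUMEN_COLOR
        img += np.asarray(STAIN_SHIFT[sources[i]], dtype=np.float32)
        img += rng.normal(0.0, style["noise"], size=img.shape).astype(np.float32)
        images[i] = np.clip(img, 0, 255).astype(np.uint8)

    labels = true_labels.copy()
    flipped = np.zeros(n_total, dtype=bool)
    if flip_rate > 0:
        flipped = rng.random(n_total) < flip_rate
        for i in np.flatnonzero(flipped):
            others = [c for c in range(len(classes)) if c != true_labels[i]]
            labels[i] = rng.choice(others)

    return PatchSet(
        images=images,
        labels=labels,
        true_labels=true_labels,
        flipped=flipped,
        sources=np.asarray(sources),
        subjects=np.array([f"subj-{i:05d}" for i in range(n_total)]),
        class_names=list(classes),
    )
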