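"""Shared domain types and file IO for the curation pipeline.

The label codebook encodes one byte per slide pixel:

====  ===================
code  meaning
====  ===================
0     background (glass)
1     stroma
2     benign epithelium
3     Gleason pattern 3
4     Gleason pattern 4
5     Gleason pattern 5
====  ===================

Epithelial pixels are exactly those with code >= 2; codes 3..5 carry the
malignant Gleason patterns. Masks are stored as paletted PNG so they stay
lossless and can be eyeballed in any image viewer.

Coordinates are 0-based and half-open, with x = column and y = row, so a
window covers ``[x0, x0 + width) x [y0, y0 + height)`` and tiling arithmetic
never double-counts a pixel.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

# -- label codebook -----------------------------------------------------------

CODE_BACKGROUND = 0
CODE_STROMA = 1
CODE_BENIGN = 2
CODE_GS3 = 3
CODE_GS4 = 4
CODE_GS5 = 5

#: lowest code that counts as epithelium (the l_epithelium cut)
EPITHELIUM_MIN_CODE = 2

CODE_NAMES = {
    CODE_BACKGROUND: "background",
    CODE_STROMA: "stroma",
    CODE_BENIGN: "benign",
    CODE_GS3: "GS3",
    CODE_GS4: "GS4",
    CODE_GS5: "GS5",
}
NAME_CODES = {name: code for code, name in CODE_NAMES.items()}

#: grade vocabulary for gland annotations and patch targets
GRADE_CODES = {"benign": CODE_BENIGN, "GS3": CODE_GS3, "GS4": CODE_GS4, "GS5": CODE_GS5}
GRADE_NAMES = {code: name for name, code in GRADE_CODES.items()}

#: closed slide-level diagnosis vocabulary (ISUP-style primary+secondary)
DIAGNOSES = ("benign", "3+3", "4+4", "4+5", "5+4", "5+5", "other")

#: which patch target codes a slide may contribute, by diagnosis. Benign
#: patches come only from benign slides, GS3 only from 3+3, GS4 only from
#: 4+4; GS5 is scarce so 4+5, 5+4 and 5+5 slides all contribute.
ELIGIBLE_TARGETS = {
    "benign": (CODE_BENIGN,),
    "3+3": (CODE_GS3,),
    "4+4": (CODE_GS4,),
    "4+5": (CODE_GS5,),
    "5+4": (CODE_GS5,),
    "5+5": (CODE_GS5,),
    "other": (),
}

SOURCES = ("cohortA", "cohortB")

# palette for paletted-PNG masks: index = code, colors chosen for inspection
_MASK_PALETTE = [
    (255, 255, 255),  # background
    (230, 200, 215),  # stroma
    (120, 190, 120),  # benign epithelium
    (250, 210, 80),  # GS3
    (240, 130, 60),  # GS4
    (200, 40, 40),  # GS5
]


class MaskCodeError(ValueError):
    """A mask contains values outside the 0..5 codebook."""


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    """Axis-aligned half-open pixel window ``[x0, x0+width) x [y0, y0+height)``."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"window must have positive extent, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"window origin must be non-negative, got {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices for indexing a numpy image."""
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))

    def scaled(self, factor: int) -> "Window":
        """The same window expressed on a grid ``factor`` times finer."""
        return Window(self.x0 * factor, self.y0 * factor, self.width * factor, self.height * factor)

    def contains(self, other: "Window") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x0 + other.width <= self.x0 + self.width
            and other.y0 + other.height <= self.y0 + self.height
        )


@dataclass
class SlideRecord:
    """One slide in a manifest: identity, source cohort, diagnosis, file paths."""

    slide_id: str
    source: str
    diagnosis: str
    image: Path | None = None
    mask: Path | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"unknown diagnosis {self.diagnosis!r} for slide {self.slide_id!r}; "
                f"allowed: {', '.join(DIAGNOSES)}"
            )
        if self.image is not None:
            self.image = Path(self.image)
        if self.mask is not None:
            self.mask = Path(self.mask)


@dataclass
class PatchRecord:
    """One candidate or retained window with its coverage/purity scores.

    ``window`` is expressed on the grid the synthesizer scanned (the
    downsampled mask grid by default); ``coverage`` is the epithelial
    fraction M/N and ``purity`` the target-label purity used for acceptance.
    """

    slide_id: str
    window: Window
    target_code: int
    coverage: float
    purity: float
    accepted: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.purity <= 1.0):
            raise ValueError("coverage and purity must lie in [0, 1]")


# -- mask IO ------------------------------------------------------------------


def _validate_codes(arr: np.ndarray, where: str) -> None:
    bad = arr > CODE_GS5
    if bad.any():
        codes, counts = np.unique(arr[bad], return_counts=True)
        detail = ", ".join(f"code {c} ({n} px)" for c, n in zip(codes, counts))
        raise MaskCodeError(f"{where}: values outside codebook 0..5: {detail}")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a label mask from an 8-bit paletted or grayscale image.

    Returns a uint8 array of codebook values; raises :class:`MaskCodeError`
    naming the offending code(s) and pixel counts if anything falls outside
    0..5.
    """
    path = Path(path)
    with Image.open(path) as img:
        if img.mode not in ("P", "L"):
            raise ValueError(f"{path}: expected paletted or 8-bit grayscale mask, got mode {img.mode}")
        arr = np.asarray(img, dtype=np.uint8)
    _validate_codes(arr, str(path))
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label mask as a paletted PNG with the codebook palette."""
    mask = np.asarray(mask)
    _validate_codes(mask, "mask to write")
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = [v for rgb in _MASK_PALETTE for v in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(Path(path), format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB slide image (PNG or TIFF) as a uint8 H x W x 3 array."""
    with Image.open(Path(path)) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(Path(path))


# -- manifest IO --------------------------------------------------------------

_MANIFEST_COLUMNS = ("slide_id", "source", "diagnosis", "image", "mask")


def read_manifest(path: str | Path) -> list[SlideRecord]:
    """Read a slide manifest from CSV or JSON into validated records.

    Required columns/keys: slide_id, source, diagnosis, image, mask.
    Duplicate slide ids and out-of-vocabulary diagnoses are errors.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = pd.DataFrame(json.loads(path.read_text()))
    else:
        rows = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s): {', '.join(missing)}")
    dupes = rows["slide_id"][rows["slide_id"].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate slide_id(s): {', '.join(map(str, dupes))}")
    base = path.parent

    def resolve(value) -> Path | None:
        if not isinstance(value, str) or not value:
            return None
        p = Path(value)
        return p if p.is_absolute() else base / p

    records = []
    for row in rows.itertuples(index=False):
        records.append(
            SlideRecord(
                slide_id=str(row.slide_id),
                source=str(row.source),
                diagnosis=str(row.diagnosis),
                image=resolve(row.image),
                mask=resolve(row.mask),
            )
        )
    return records


def write_manifest(path: str | Path, records: list[SlideRecord]) -> None:
    """Write a CSV manifest; image/mask paths are stored relative to it."""
    path = Path(path)

    def relativize(p: Path | None) -> str:
        if p is None:
            return ""
        return os.path.relpath(p, path.parent)

    frame = pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "source": [r.source for r in records],
            "diagnosis": [r.diagnosis for r in records],
            "image": [relativize(r.image) for r in records],
            "mask": [relativize(r.mask) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def patch_records_frame(records: list[PatchRecord]) -> pd.DataFrame:
    """Tabulate patch records for CSV export."""
    return pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "x0": [r.window.x0 for r in records],
            "y0": [r.window.y0 for r in records],
            "width": [r.window.width for r in records],
            "height": [r.window.height for r in records],
            "target_code": [r.target_code for r in records],
            "target": [GRADE_NAMES.get(r.target_code, str(r.target_code)) for r in records],
            "coverage": [r.coverage for r in records],
            "purity": [r.purity for r in records],
            "accepted": [r.accepted for r in records],
        }
    )
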