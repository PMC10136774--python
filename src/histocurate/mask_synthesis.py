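"""Sliding-window patch synthesis from labeled whole-slide masks.

A slide's label mask is scanned with a square window; each window is scored
by how much epithelium it contains (coverage M/N) and how pure that
epithelium is at the targeted Gleason level. Windows pass when coverage and
purity clear the p_alpha / p_beta cut points. The window overlap p_omega
starts at 0.5 and is raised stepwise to 0.8 until a slide yields at least
``retain_k`` accepted windows; the best ``retain_k`` by coverage are kept
and slides that cannot produce that many even at maximum overlap are
excluded from the cohort.

Scanning happens on the mask downsampled by ``downsample_factor`` (2 by
default, matching the 2x-downsampled foreground isolation), so the nominal
400-pixel window becomes a 200-pixel window on the scan grid. Patch pixels
are cut from the same grid unless ``full_resolution`` is set.

On purity there are two readings. The literal acceptance rule compares the
target-pixel fraction of the whole window (T/N) against p_beta = 0.95 —
but since target pixels are a subset of epithelial pixels (T <= M), any
window passing T/N >= 0.95 automatically has coverage M/N >= 0.95, which
makes the separate p_alpha >= 0.1 coverage test inert. The default here
therefore measures purity among epithelial pixels (T/M): "purity of label
at the targeted Gleason level" within the labeled tissue. The literal T/N
reading stays available via ``purity_denominator="all"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core_io import (
    CODE_BENIGN,
    ELIGIBLE_TARGETS,
    EPITHELIUM_MIN_CODE,
    GRADE_NAMES,
    PatchRecord,
    SlideRecord,
    Window,
)

__all__ = [
    "SynthesisParams",
    "WindowScore",
    "SynthesisResult",
    "CohortResult",
    "foreground_mask",
    "scan_windows",
    "score_window",
    "accept",
    "synthesize_slide",
    "cut_patches",
    "assemble_cohort",
]


@dataclass(frozen=True)
class SynthesisParams:
    """Cut points and geometry for the patch synthesizer.

    window_edge is in full-resolution slide pixels; the scan grid uses
    ``window_edge // downsample_factor``. p_alpha is the minimum epithelial
    coverage M/N, p_beta the minimum label purity, and the p_omega_* fields
    define the overlap escalation grid.
    """

    window_edge: int = 400
    p_alpha: float = 0.1
    p_beta: float = 0.95
    p_omega_start: float = 0.5
    p_omega_max: float = 0.8
    p_omega_step: float = 0.1
    retain_k: int = 20
    downsample_factor: int = 2
    purity_denominator: str = "epithelial"  # or "all" for the literal T/N rule
    min_foreground: float = 0.5
    full_resolution: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_alpha <= 1.0 and 0.0 < self.p_beta <= 1.0):
            raise ValueError("p_alpha and p_beta must lie in (0, 1]")
        if not (0.0 <= self.p_omega_start <= self.p_omega_max < 1.0):
            raise ValueError("need 0 <= p_omega_start <= p_omega_max < 1")
        if self.retain_k < 1:
            raise ValueError("retain_k must be >= 1")
        if self.purity_denominator not in ("epithelial", "all"):
            raise ValueError("purity_denominator must be 'epithelial' or 'all'")
        if self.window_edge < self.downsample_factor:
            raise ValueError("window_edge must be at least downsample_factor")

    @property
    def scan_edge(self) -> int:
        """Window edge on the downsampled scan grid."""
        return self.window_edge // self.downsample_factor

    def p_omega_grid(self) -> list[float]:
        """Overlap escalation schedule p_omega_start, +step, ..., <= p_omega_max."""
        n = int(math.floor((self.p_omega_max - self.p_omega_start) / self.p_omega_step + 1e-9)) + 1
        return [round(self.p_omega_start + i * self.p_omega_step, 10) for i in range(max(n, 1))]


@dataclass(frozen=True)
class WindowScore:
    """Pixel counts for one window: N total, M epithelial (code >= 2), T target."""

    N: int
    M: int
    T: int
    purity_denominator: str = "epithelial"

    def __post_init__(self) -> None:
        if not 0 <= self.T <= self.M <= self.N:
            raise ValueError(f"need 0 <= T <= M <= N, got T={self.T} M={self.M} N={self.N}")

    @property
    def coverage(self) -> float:
        return self.M / self.N

    @property
    def purity(self) -> float:
        if self.purity_denominator == "all":
            return self.T / self.N
        return self.T / self.M if self.M else 0.0


@dataclass
class SynthesisResult:
    """Outcome for one slide: retained patches, or an exclusion with reason."""

    slide_id: str
    target_code: int
    patches: list[PatchRecord] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""
    p_omega_used: float | None = None
    n_candidates: int = 0
    n_accepted: int = 0


@dataclass
class CohortResult:
    """Patch records, exclusions and a per-class bookkeeping table."""

    patches: list[PatchRecord]
    exclusions: list[SynthesisResult]
    ineligible: list[str]
    counts: pd.DataFrame


def foreground_mask(slide_image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Tissue/glass separation: downsample, gray, Otsu; tissue is the darker side.

    Returns a boolean array of shape ``ceil(H/factor) x ceil(W/factor)``
    (True = tissue). A constant-intensity image has no Otsu split and comes
    back all-background with a warning.
    """
    slide_image = np.asarray(slide_image)
    if slide_image.size == 0:
        raise ValueError("empty slide image")
    gray = slide_image[::factor, ::factor].astype(np.float32)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    if np.ptp(gray) == 0:
        warnings.warn("constant-intensity slide: no foreground/background split", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    return gray < threshold_otsu(gray)


def _axis_starts(length: int, edge: int, stride: int) -> list[int]:
    if length < edge:
        return []
    last = length - edge
    starts = list(range(0, last + 1, stride))
    if starts[-1] != last:
        starts.append(last)  # flush final window against the far edge
    return starts


def scan_windows(mask_shape: tuple[int, int], window_edge: int, p_omega: float) -> list[Window]:
    """Tile a (height, width) grid with square windows at overlap ``p_omega``.

    Stride is ``max(1, round(edge * (1 - p_omega)))``; both axes start at 0
    and append a final window flush with the far edge when the strided grid
    would fall short. A grid smaller than the window yields no windows.
    """
    height, width = mask_shape
    stride = max(1, round(window_edge * (1.0 - p_omega)))
    ys = _axis_starts(height, window_edge, stride)
    xs = _axis_starts(width, window_edge, stride)
    return [Window(x, y, window_edge, window_edge) for y in ys for x in xs]


def score_window(
    mask: np.ndarray, w: Window, target_code: int, params: SynthesisParams
) -> WindowScore:
    """Count N, M (epithelial, code >= 2) and T (== target) inside the window."""
    sub = mask[w.slices]
    return WindowScore(
        N=sub.size,
        M=int((sub >= EPITHELIUM_MIN_CODE).sum()),
        T=int((sub == target_code).sum()),
        purity_denominator=params.purity_denominator,
    )


def accept(score: WindowScore, params: SynthesisParams) -> bool:
    """Acceptance rule: coverage >= p_alpha AND purity >= p_beta (both inclusive)."""
    return score.coverage >= params.p_alpha and score.purity >= params.p_beta


def _scan_mask(image: np.ndarray, mask: np.ndarray, factor: int) -> np.ndarray:
    """Bring the label mask onto the downsampled scan grid, checking alignment."""
    img_shape = image.shape[:2]
    down_shape = tuple(-(-s // factor) for s in img_shape)  # ceil division
    if mask.shape == img_shape:
        return mask[::factor, ::factor]
    if mask.shape == down_shape:
        return mask
    raise ValueError(
        f"mask shape {mask.shape} matches neither the slide {img_shape} "
        f"nor its {factor}x-downsampled grid {down_shape}"
    )


def synthesize_slide(
    record: SlideRecord,
    image: np.ndarray,
    mask: np.ndarray,
    target_code: int,
    params: SynthesisParams = SynthesisParams(),
) -> SynthesisResult:
    """Run the full per-slide synthesis loop.

    Escalates p_omega through the schedule until at least ``retain_k``
    windows are accepted; the accepted set is then rank-sorted by coverage
    (descending, ties broken by (y0, x0) ascending) and truncated to
    ``retain_k``. If even the maximum overlap cannot produce ``retain_k``
    accepted windows the slide is excluded. Windows are gated on the Otsu
    foreground: only windows at least ``min_foreground`` tissue are scored.
    """
    mask = np.asarray(mask)
    scan = _scan_mask(np.asarray(image), mask, params.downsample_factor)
    fg = foreground_mask(image, params.downsample_factor)
    edge = params.scan_edge

    chosen: list[tuple[Window, WindowScore]] = []
    result = SynthesisResult(slide_id=record.slide_id, target_code=target_code)
    for p_omega in params.p_omega_grid():
        windows = scan_windows(scan.shape, edge, p_omega)
        accepted: list[tuple[Window, WindowScore]] = []
        for w in windows:
            if fg[w.slices].mean() < params.min_foreground:
                continue
            s = score_window(scan, w, target_code, params)
            if accept(s, params):
                accepted.append((w, s))
        result.n_candidates = len(windows)
        result.n_accepted = len(accepted)
        result.p_omega_used = p_omega
        chosen = accepted
        if len(accepted) >= params.retain_k:
            break
    if len(chosen) < params.retain_k:
        result.excluded = True
        result.reason = (
            f"slide {record.slide_id}: only {len(chosen)} accepted windows for "
            f"{GRADE_NAMES.get(target_code, target_code)} at p_omega={result.p_omega_used}"
        )
        return result

    chosen.sort(key=lambda ws: (-ws[1].coverage, ws[0].y0, ws[0].x0))
    result.patches = [
        PatchRecord(
            slide_id=record.slide_id,
            window=w,
            target_code=target_code,
            coverage=s.coverage,
            purity=s.purity,
            accepted=True,
        )
        for w, s in chosen[: params.retain_k]
    ]
    return result


def cut_patches(
    image: np.ndarray, records: Iterable[PatchRecord], params: SynthesisParams = SynthesisParams()
) -> list[np.ndarray]:
    """Extract patch pixel arrays for retained records.

    Records carry scan-grid windows; by default patches are cut from the
    downsampled image, or from the native slide when ``full_resolution``.
    """
    image = np.asarray(image)
    if params.full_resolution:
        return [image[r.window.scaled(params.downsample_factor).slices] for r in records]
    down = image[:: params.downsample_factor, :: params.downsample_factor]
    return [down[r.window.slices] for r in records]


def assemble_cohort(
    slides: Iterable[tuple[SlideRecord, np.ndarray, np.ndarray]],
    params: SynthesisParams = SynthesisParams(),
    require_all_classes: bool = False,
) -> CohortResult:
    """Synthesize a cohort under the slide-eligibility rules.

    Each slide contributes patches only for the target class(es) its
    clinical diagnosis allows (benign from benign slides, GS3 from 3+3,
    GS4 from 4+4, GS5 from 4+5/5+4/5+5); slides with no eligible class are
    skipped and slides that cannot yield ``retain_k`` patches are logged as
    exclusions. The counts table tallies contributing slides and retained
    patches per class.
    """
    patches: list[PatchRecord] = []
    exclusions: list[SynthesisResult] = []
    ineligible: list[str] = []
    class_names = [GRADE_NAMES[c] for c in (2, 3, 4, 5)]
    slide_counts = dict.fromkeys(class_names, 0)
    patch_counts = dict.fromkeys(class_names, 0)

    for record, image, mask in slides:
        targets = ELIGIBLE_TARGETS[record.diagnosis]
        if not targets:
            ineligible.append(record.slide_id)
            continue
        for target_code in targets:
            res = synthesize_slide(record, image, mask, target_code, params)
            name = GRADE_NAMES[target_code]
            if res.excluded:
                exclusions.append(res)
            else:
                patches.extend(res.patches)
                slide_counts[name] += 1
                patch_counts[name] += len(res.patches)

    counts = pd.DataFrame(
        {
            "total": [sum(slide_counts.values()), sum(patch_counts.values())],
            **{n: [slide_counts[n], patch_counts[n]] for n in class_names},
        },
        index=["slides", "patches"],
    )
    if require_all_classes:
        empty = [n for n in class_names if slide_counts[n] == 0]
        if empty:
            raise ValueError(f"no eligible contributing slides for class(es): {', '.join(empty)}")
    return CohortResult(patches=patches, exclusions=exclusions, ineligible=ineligible, counts=counts)
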