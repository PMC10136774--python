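"""Patch preprocessing: sample-mix tiled resize and z-score standardization.

Sample-mix brings variably sized gland patches to a common network input
size without interpolation: ``rank x rank`` tiles of fixed edge
``target_edge / rank`` are sampled at uniformly random positions from the
source image and mosaicked in row-major order. Because tiles are copied
verbatim, the scale and aspect ratio of the tissue texture are preserved —
the mosaic's pixels are a sub-multiset of the source's.

Sources smaller than one tile in either direction cannot supply a tile at
native scale; the default policy removes them from the dataset, while the
``shrink`` policy falls back to the largest tile edge that still divides
the target so the mosaic is assembled (and reported) at a reduced scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SampleMixParams", "SampleMixResult", "sample_mix", "zscore"]


@dataclass(frozen=True)
class SampleMixParams:
    target_edge: int = 300
    rank: int = 3
    undersized_policy: str = "remove"  # or "shrink"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.target_edge % self.rank:
            raise ValueError(
                f"target_edge {self.target_edge} must be divisible by rank {self.rank}"
            )
        if self.undersized_policy not in ("remove", "shrink"):
            raise ValueError("undersized_policy must be 'remove' or 'shrink'")

    @property
    def tile_edge(self) -> int:
        return self.target_edge // self.rank


@dataclass
class SampleMixResult:
    """Mosaic output; ``removed`` marks sources dropped under the remove policy.

    ``tile_edge`` records the edge actually used — smaller than the nominal
    tile under the shrink policy, in which case the mosaic edge is
    ``tile_edge * rank`` rather than ``target_edge``.
    """

    image: np.ndarray | None
    removed: bool
    tile_edge: int
    positions: list[tuple[int, int]]  # (y, x) source offsets, row-major tile order


def _largest_feasible_tile(params: SampleMixParams, limit: int) -> int:
    # largest divisor of target_edge that fits the source; 0 if none
    per_axis = params.target_edge // params.rank
    for edge in range(min(per_axis, limit), 0, -1):
        if params.target_edge % edge == 0:
            return edge
    return 0


def sample_mix(
    image: np.ndarray, params: SampleMixParams, rng: np.random.Generator | int | None = None
) -> SampleMixResult:
    """Assemble a ``target_edge`` square mosaic of randomly sampled tiles.

    Tile top-left positions are drawn independently and uniformly over all
    in-bounds offsets (tiles may overlap); no pixel value is interpolated
    or rescaled. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng)
    image = np.asarray(image)
    h, w = image.shape[:2]
    tile = params.tile_edge
    if h < tile or w < tile:
        if params.undersized_policy == "remove":
            return SampleMixResult(image=None, removed=True, tile_edge=tile, positions=[])
        tile = _largest_feasible_tile(params, min(h, w))
        if tile == 0:
            return SampleMixResult(image=None, removed=True, tile_edge=0, positions=[])

    out_edge = tile * params.rank
    out_shape = (out_edge, out_edge) + image.shape[2:]
    mosaic = np.empty(out_shape, dtype=image.dtype)
    positions = []
    for i in range(params.rank):
        for j in range(params.rank):
            y = int(rng.integers(0, h - tile + 1))
            x = int(rng.integers(0, w - tile + 1))
            mosaic[i * tile : (i + 1) * tile, j * tile : (j + 1) * tile] = image[
                y : y + tile, x : x + tile
            ]
            positions.append((y, x))
    return SampleMixResult(image=mosaic, removed=False, tile_edge=tile, positions=positions)


def zscore(image: np.ndarray) -> np.ndarray:
    """Standardize each color channel to zero mean and unit variance.

    Uses the population standard deviation over the image's own pixels; a
    constant channel maps to all zeros rather than dividing by zero.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    axes = (0, 1) if arr.ndim == 3 else None
    mean = arr.mean(axis=axes, keepdims=True)
    sd = arr.std(axis=axes, keepdims=True)
    return np.divide(arr - mean, sd, out=np.zeros_like(arr), where=sd > 0)
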