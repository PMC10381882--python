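"""Contrast-limited adaptive histogram equalization (CLAHE).

The image is divided into a rectangular grid of tiles; each tile's
histogram is clipped at ``clip_limit × tile_pixels`` with the excess
redistributed, equalized through its CDF, and pixels are remapped by
bilinear interpolation between the four surrounding tile mappings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import GreyImage


@dataclass(frozen=True)
class ClaheConfig:
    tiles: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    n_bins: int = 256

    def __post_init__(self) -> None:
        tr, tc = self.tiles
        if tr < 1 or tc < 1:
            raise ValueError("tile grid must be at least 1×1")
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError("clip_limit must lie in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be ≥ 2")


def clip_histogram(hist: np.ndarray, clip_limit: float, tile_pixels: int) -> np.ndarray:
    """Clip histogram bins at ceil(clip_limit × tile_pixels), redistributing
    the excess uniformly over the bins still below the cap until the
    residual excess is < 1 count; the (sub-unit) remainder is then spread
    over all bins so total mass is conserved exactly.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    cap = math.ceil(clip_limit * tile_pixels)
    h = np.asarray(hist, dtype=float).copy()
    excess = float(np.clip(h - cap, 0, None).sum())
    h = np.minimum(h, cap)
    while excess >= 1.0:
        under = h < cap
        if not under.any():
            break
        h[under] += excess / under.sum()
        excess = float(np.clip(h - cap, 0, None).sum())
        h = np.minimum(h, cap)
    if excess > 0:
        h += excess / h.size
    return h


def _tile_lut(tile: np.ndarray, cfg: ClaheConfig, max_value: int) -> np.ndarray:
    """Equalization lookup table (bin index → output level) for one tile."""
    hist = np.bincount(tile.ravel(), minlength=cfg.n_bins).astype(float)
    hist = clip_histogram(hist, cfg.clip_limit, tile.size)
    cdf = np.cumsum(hist) / hist.sum()
    return np.rint(cdf * max_value)


def clahe(image: GreyImage, cfg: ClaheConfig = ClaheConfig()) -> GreyImage:
    """Tile-wise clipped equalization with bilinear blending of tiles.

    The image is padded symmetrically to a multiple of the tile size and
    the result cropped back, so edge tiles need no special casing.  Output
    has the same shape and bit depth; range [0, 2^bitdepth − 1].
    """
    px = image.pixels
    h, w = px.shape
    tr, tc = cfg.tiles
    if h < tr or w < tc:
        raise ValueError(f"image {px.shape} smaller than the {tr}×{tc} tile grid")
    th, tw = math.ceil(h / tr), math.ceil(w / tc)
    pad_r, pad_c = tr * th - h, tc * tw - w
    top, left = pad_r // 2, pad_c // 2
    padded = np.pad(px, ((top, pad_r - top), (left, pad_c - left)), mode="symmetric")

    # bin pixels over the full dynamic range (identity for 8-bit/256 bins)
    span = 1 << image.bitdepth
    binned = (padded.astype(np.int64) * cfg.n_bins) // span
    binned = np.clip(binned, 0, cfg.n_bins - 1)

    luts = np.empty((tr, tc, cfg.n_bins))
    for i in range(tr):
        for j in range(tc):
            tile = binned[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_lut(tile, cfg, image.max_value)

    # bilinear interpolation between the four surrounding tile centres,
    # clamped at the image edges (corner/edge pixels use the nearest tiles)
    ty = (np.arange(padded.shape[0]) + 0.5) / th - 0.5
    tx = (np.arange(padded.shape[1]) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(ty).astype(int), 0, tr - 1)
    x0 = np.clip(np.floor(tx).astype(int), 0, tc - 1)
    y1 = np.clip(y0 + 1, 0, tr - 1)
    x1 = np.clip(x0 + 1, 0, tc - 1)
    wy = np.clip(ty - np.floor(ty), 0.0, 1.0)[:, None]
    wx = np.clip(tx - np.floor(tx), 0.0, 1.0)[None, :]

    def gather(yi: np.ndarray, xi: np.ndarray) -> np.ndarray:
        return luts[yi[:, None], xi[None, :], binned]

    out = (
        (1 - wy) * (1 - wx) * gather(y0, x0)
        + (1 - wy) * wx * gather(y0, x1)
        + wy * (1 - wx) * gather(y1, x0)
        + wy * wx * gather(y1, x1)
    )
    out = np.rint(out[top : top + h, left : left + w])
    out = np.clip(out, 0, image.max_value).astype(px.dtype)
    return GreyImage(pixels=out, bitdepth=image.bitdepth)
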