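"""Grey-level run length matrix (GLRLM) features.

Runs are maximal sequences of consecutive in-mask pixels with equal
level along a direction; a masked-out pixel breaks a run.  Features are
computed per direction (horizontal, vertical, diagonal, antidiagonal)
and averaged.
"""
from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRegion

DIRECTIONS = {
    "horizontal": (0, 1),
    "vertical": (1, 0),
    "diagonal": (1, 1),
    "antidiagonal": (1, -1),
}


def _lines(levels: np.ndarray, direction: tuple[int, int]):
    """Yield (level, in_mask) 1D line pairs along a direction."""
    if direction == (0, 1):
        yield from ((levels[r], None) for r in range(levels.shape[0]))
    elif direction == (1, 0):
        yield from ((levels[:, c], None) for c in range(levels.shape[1]))
    elif direction == (1, 1):
        h, w = levels.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(levels, offset=off), None
    elif direction == (1, -1):
        yield from _lines(levels[:, ::-1], (1, 1))
    else:  # pragma: no cover
        raise ValueError(f"unknown direction {direction}")


def run_length_matrix(
    region: DiscretizedRegion, direction: tuple[int, int]
) -> np.ndarray:
    """Counts P[level-1, run_length-1]; columns sized to the longest line."""
    max_len = max(region.levels.shape)
    counts = np.zeros((region.ng, max_len))
    for line, _ in _lines(region.levels, direction):
        run_level, run_len = 0, 0
        for lv in line:
            if lv == run_level and lv != 0:
                run_len += 1
            else:
                if run_level != 0:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = int(lv), 1
        if run_level != 0:
            counts[run_level - 1, run_len - 1] += 1
    return counts


def _glrlm_features_one(p: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = p.sum()
    jj = np.arange(1, p.shape[1] + 1)[None, :]
    row_sums = p.sum(axis=1)
    col_sums = p.sum(axis=0)
    return {
        "GLRLM.sre": float((p / jj**2).sum() / nr),
        "GLRLM.lre": float((p * jj**2).sum() / nr),
        "GLRLM.gln": float((row_sums**2).sum() / nr),
        "GLRLM.rln": float((col_sums**2).sum() / nr),
        "GLRLM.rp": float(nr / n_pixels),
    }


def glrlm_features(region: DiscretizedRegion) -> dict[str, float]:
    per_dir = [
        _glrlm_features_one(run_length_matrix(region, d), region.n_pixels)
        for d in DIRECTIONS.values()
    ]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in per_dir[0]}
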