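"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package implementations.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- morphology
def dilate_bruteforce(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    out[r, c] = True
                    break
    return out


def erode_bruteforce(mask: np.ndarray, offsets: set[tuple[int, int]]) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for r in range(h):
        for c in range(w):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def major_axis_bruteforce(mask: np.ndarray) -> float:
    pts = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    n = len(pts)
    mr = sum(p[0] for p in pts) / n
    mc = sum(p[1] for p in pts) / n
    srr = sum((p[0] - mr) ** 2 for p in pts) / n + 1 / 12
    scc = sum((p[1] - mc) ** 2 for p in pts) / n + 1 / 12
    src = sum((p[0] - mr) * (p[1] - mc) for p in pts) / n
    tr, det = srr + scc, srr * scc - src * src
    lam = tr / 2 + math.sqrt(max(tr * tr / 4 - det, 0.0))
    return 4 * math.sqrt(lam)


# ------------------------------------------------------------ texture matrices
def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int], ng: int) -> np.ndarray:
    """Symmetrized co-occurrence counts by looping over every pixel."""
    h, w = levels.shape
    counts = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            rr, cc = r + offset[0], c + offset[1]
            if mask[r, c] and 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                counts[levels[r, c] - 1, levels[rr, cc] - 1] += 1
    return counts + counts.T


def glrlm_bruteforce(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int], ng: int) -> np.ndarray:
    """Run-length counts by walking every line of the grid."""
    h, w = levels.shape
    dr, dc = direction
    counts = np.zeros((ng, max(h, w)))
    starts = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not (0 <= r - dr < h and 0 <= c - dc < w)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        run_level, run_len = 0, 0
        while 0 <= r < h and 0 <= c < w:
            lv = levels[r, c] if mask[r, c] else 0
            if lv == run_level and lv != 0:
                run_len += 1
            else:
                if run_level:
                    counts[run_level - 1, run_len - 1] += 1
                run_level, run_len = lv, 1
            r, c = r + dr, c + dc
        if run_level:
            counts[run_level - 1, run_len - 1] += 1
    return counts


def glszm_bruteforce(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """(level, size) per 8-connected equal-level zone, via explicit BFS."""
    h, w = levels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack, seen[r, c], size = [(r, c)], True, 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < h and 0 <= xx < w and mask[yy, xx]
                            and not seen[yy, xx] and levels[yy, xx] == level
                        ):
                            seen[yy, xx] = True
                            stack.append((yy, xx))
            zones.append((int(level), size))
    return sorted(zones)


def gldm_bruteforce(levels: np.ndarray, mask: np.ndarray, delta: int, alpha: int, ng: int) -> np.ndarray:
    h, w = levels.shape
    counts = np.zeros((ng, (2 * delta + 1) ** 2))
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in range(-delta, delta + 1):
                for dc in range(-delta, delta + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        if abs(int(levels[rr, cc]) - int(levels[r, c])) <= alpha:
                            dep += 1
            counts[levels[r, c] - 1, dep] += 1
    return counts


def ngtdm_bruteforce(levels: np.ndarray, mask: np.ndarray, delta: int, ng: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr in range(-delta, delta + 1):
                for dc in range(-delta, delta + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        nbrs.append(int(levels[rr, cc]))
            if nbrs:
                i = int(levels[r, c])
                n[i - 1] += 1
                s[i - 1] += abs(i - sum(nbrs) / len(nbrs))
    return n, s


# ------------------------------------------------------------------ statistics
def global_equalize(pixels: np.ndarray, max_value: int) -> np.ndarray:
    """Plain histogram equalization: v → round(P(X ≤ v) · max_value)."""
    flat = pixels.ravel()
    out = np.empty_like(flat, dtype=np.int64)
    for k, v in enumerate(flat):
        out[k] = round(np.count_nonzero(flat <= v) / flat.size * max_value)
    return out.reshape(pixels.shape)


def mwu_pvalue_enum(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann–Whitney p by enumerating every labeling."""
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    m = n1 * len(y) / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        grp = pooled[list(combo)]
        rest = np.delete(pooled, list(combo))
        u = sum(1 for xi in grp for yj in rest if xi > yj)
        total += 1
        if abs(u - m) >= abs(u_obs - m):
            extreme += 1
    return extreme / total
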