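"""Neighbourhood grey tone difference matrix (NGTDM) features.

For each level i: n_i counts the in-mask pixels at level i that have at
least one in-mask neighbour within Chebyshev distance ``delta``; s_i
sums |i − mean(neighbour levels)| over those pixels; p_i = n_i / N with
N = Σ n_i.

Feature formulas (with Ngp = number of levels having p_i > 0):

    coarseness = 1 / Σ p_i s_i                  (capped at 1e6 when Σ = 0)
    contrast   = [Σ_{i,j} p_i p_j (i−j)² / (Ngp(Ngp−1))] · [Σ s_i / N]
    busyness   = Σ p_i s_i / Σ_{i,j} |i p_i − j p_j|
    complexity = Σ_{i,j} |i−j| (p_i s_i + p_j s_j)/(p_i + p_j) / N
    strength   = Σ_{i,j} (p_i + p_j)(i−j)² / Σ s_i

sums over i,j restricted to p > 0; degenerate denominators yield 0
(coarseness: the documented cap).
"""
from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRegion

COARSENESS_CAP = 1e6


def tone_difference_table(
    region: DiscretizedRegion, delta: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) vectors indexed by level-1."""
    if delta < 1:
        raise ValueError("delta must be ≥ 1")
    lv, mk = region.levels, region.mask
    h, w = lv.shape
    nbr_sum = np.zeros(lv.shape)
    nbr_cnt = np.zeros(lv.shape)
    for dr in range(-delta, delta + 1):
        for dc in range(-delta, delta + 1):
            if (dr, dc) == (0, 0):
                continue
            src = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
            dst = (slice(max(0, dr), h + min(0, dr)), slice(max(0, dc), w + min(0, dc)))
            ok = mk[src] & mk[dst]
            nbr_sum[src] += np.where(ok, lv[dst], 0)
            nbr_cnt[src] += ok
    has_nbr = mk & (nbr_cnt > 0)
    n = np.zeros(region.ng)
    s = np.zeros(region.ng)
    idx = lv[has_nbr] - 1
    np.add.at(n, idx, 1.0)
    diffs = np.abs(lv[has_nbr] - nbr_sum[has_nbr] / nbr_cnt[has_nbr])
    np.add.at(s, idx, diffs)
    return n, s


def ngtdm_features(region: DiscretizedRegion, delta: int = 1) -> dict[str, float]:
    n, s = tone_difference_table(region, delta)
    total = n.sum()
    if total == 0:  # single isolated pixel: no neighbours at all
        return {
            "NGTDM.coarseness": COARSENESS_CAP,
            "NGTDM.contrast": 0.0,
            "NGTDM.busyness": 0.0,
            "NGTDM.complexity": 0.0,
            "NGTDM.strength": 0.0,
        }
    p = n / total
    present = p > 0
    i = np.arange(1, region.ng + 1, dtype=float)
    pi, si, ii = p[present], s[present], i[present]
    ngp = int(present.sum())

    ps = float((pi * si).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    di = ii[:, None] - ii[None, :]
    if ngp > 1:
        contrast = float(
            (pi[:, None] * pi[None, :] * di**2).sum() / (ngp * (ngp - 1))
        ) * float(s.sum() / total)
        denom_busy = float(np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        psum = pi[:, None] + pi[None, :]
        complexity = float(
            (np.abs(di) * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :]) / psum).sum()
        ) / float(total)
        strength = float((psum * di**2).sum()) / float(s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = strength = 0.0
        complexity = 0.0

    return {
        "NGTDM.coarseness": coarseness,
        "NGTDM.contrast": contrast,
        "NGTDM.busyness": busyness,
        "NGTDM.complexity": complexity,
        "NGTDM.strength": strength,
    }
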