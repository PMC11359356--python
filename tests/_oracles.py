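"""Independent brute-force oracles for the test suite.

Everything here is written with explicit loops and enumeration, kept
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Tuple

import numpy as np

# ---------------------------------------------------------------------------
# Mann-Whitney

def mw_u_oracle(g1, g2) -> float:
    """U as the direct count of g1 > g2 pairs plus half the ties."""
    u = 0.0
    for a in g1:
        for b in g2:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mw_exact_p_oracle(g1, g2) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    pooled = list(g1) + list(g2)
    n1 = len(g1)
    u_obs = mw_u_oracle(g1, g2)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        sel = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in sel]
        us.append(mw_u_oracle(a, b))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# texture matrices

_DIRS4 = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees


def glcm_matrix_oracle(levels, mask, ng) -> np.ndarray:
    h, w = levels.shape
    mats = []
    for dr, dc in _DIRS4:
        mat = np.zeros((ng, ng))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                    i, j = levels[r, c] - 1, levels[r2, c2] - 1
                    mat[i, j] += 1
                    mat[j, i] += 1  # symmetric
        mats.append(mat)
    avg = sum(mats) / len(mats)
    return avg / avg.sum()


def glcm_features_oracle(p: np.ndarray) -> List[float]:
    ng = p.shape[0]
    asm = con = ent = hom = dis = ac = 0.0
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * p[i, j]
    var = 0.0
    for i in range(ng):
        for j in range(ng):
            var += (i + 1 - mu) ** 2 * p[i, j]
    cor = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            asm += v * v
            con += (i - j) ** 2 * v
            if v > 0:
                ent -= v * math.log2(v)
            hom += v / (1.0 + (i - j) ** 2)
            dis += abs(i - j) * v
            ac += (i + 1) * (j + 1) * v
            if var > 1e-12:
                cor += (i + 1 - mu) * (j + 1 - mu) * v / var
    sa = 0.0
    for i in range(ng):
        for j in range(ng):
            sa += (i + 1 + j + 1) * p[i, j]
    return [asm, con, ent, mu, var, cor, hom, dis, ac, sa]


def glrlm_matrix_oracle(levels, mask, ng, direction="mean") -> np.ndarray:
    h, w = levels.shape
    dir_steps = {
        "horizontal": (0, 1),
        "vertical": (1, 0),
        "diag45": (-1, 1),
        "diag135": (1, 1),
    }
    chosen = list(dir_steps) if direction == "mean" else [direction]
    per_dir = []
    for d in chosen:
        dr, dc = dir_steps[d]
        runs: List[Tuple[int, int]] = []
        seen = np.zeros_like(mask, dtype=bool)
        # walk every maximal line in this direction
        for r in range(h):
            for c in range(w):
                pr, pc = r - dr, c - dc
                starts_line = not (0 <= pr < h and 0 <= pc < w)
                if not starts_line:
                    continue
                rr, cc = r, c
                current = None
                length = 0
                while 0 <= rr < h and 0 <= cc < w:
                    if mask[rr, cc]:
                        lv = levels[rr, cc]
                        if lv == current:
                            length += 1
                        else:
                            if current is not None:
                                runs.append((current, length))
                            current, length = lv, 1
                    else:
                        if current is not None:
                            runs.append((current, length))
                        current, length = None, 0
                    rr += dr
                    cc += dc
                if current is not None:
                    runs.append((current, length))
        max_len = max((l for _, l in runs), default=1)
        mat = np.zeros((ng, max_len))
        for lv, l in runs:
            mat[lv - 1, l - 1] += 1
        per_dir.append(mat)
    width = max(m.shape[1] for m in per_dir)
    total = np.zeros((ng, width))
    for m in per_dir:
        total[:, : m.shape[1]] += m
    return total / len(per_dir)


def glszm_matrix_oracle(levels, mask, ng) -> np.ndarray:
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones: List[Tuple[int, int]] = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                lv = levels[r, c]
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (
                                0 <= r2 < h and 0 <= c2 < w
                                and mask[r2, c2] and not seen[r2, c2]
                                and levels[r2, c2] == lv
                            ):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((lv, size))
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size))
    for lv, s in zones:
        mat[lv - 1, s - 1] += 1
    return mat


def run_zone_features_oracle(mat: np.ndarray, n_pixels: int) -> List[float]:
    ng, width = mat.shape
    nr = mat.sum()
    sre = lre = lglre = hgre = srlgle = srhgle = lrlgle = lrhgle = 0.0
    for i in range(ng):
        for j in range(width):
            v = mat[i, j]
            gi, rj = i + 1, j + 1
            sre += v / rj**2
            lre += v * rj**2
            lglre += v / gi**2
            hgre += v * gi**2
            srlgle += v / (gi**2 * rj**2)
            srhgle += v * gi**2 / rj**2
            lrlgle += v * rj**2 / gi**2
            lrhgle += v * gi**2 * rj**2
    gln = sum(mat[i, :].sum() ** 2 for i in range(ng))
    rln = sum(mat[:, j].sum() ** 2 for j in range(width))
    mu_i = sum((i + 1) * mat[i, :].sum() / nr for i in range(ng))
    glv = sum((i + 1 - mu_i) ** 2 * mat[i, :].sum() / nr for i in range(ng))
    mu_j = sum((j + 1) * mat[:, j].sum() / nr for j in range(width))
    rv = sum((j + 1 - mu_j) ** 2 * mat[:, j].sum() / nr for j in range(width))
    return [
        sre / nr, lre / nr, gln / nr, rln / nr, nr / n_pixels,
        lglre / nr, hgre / nr, srlgle / nr, srhgle / nr,
        lrlgle / nr, lrhgle / nr, glv, rv,
    ]


def ngtdm_features_oracle(levels, mask, ng) -> List[float]:
    h, w = levels.shape
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        nbrs.append(levels[r2, c2])
            if not nbrs:
                continue
            n_valid += 1
            lv = levels[r, c]
            n_i[lv - 1] += 1
            s[lv - 1] += abs(lv - sum(nbrs) / len(nbrs))
    if n_valid == 0:
        return [0.0] * 5
    p = n_i / n_valid
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    psi = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1.0 / psi, 1e6) if psi > 1e-12 else 1e6
    if ngp <= 1:
        return [coarseness, 0.0, 0.0, 0.0, 0.0]
    contrast = 0.0
    for i in present:
        for j in present:
            contrast += p[i] * p[j] * (i - j) ** 2
    contrast *= sum(s) / (ngp * (ngp - 1) * n_valid)
    denom = 0.0
    for i in present:
        for j in present:
            denom += abs((i + 1) * p[i] - (j + 1) * p[j])
    busyness = psi / denom if denom > 1e-12 else 0.0
    complexity = 0.0
    for i in present:
        for j in present:
            complexity += (
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            )
    complexity /= n_valid
    s_total = sum(s)
    strength = 0.0
    if s_total > 1e-12:
        for i in present:
            for j in present:
                strength += (p[i] + p[j]) * (i - j) ** 2
        strength /= s_total
    return [coarseness, contrast, busyness, complexity, strength]
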