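"""Visual feature battery: 87 features per camera view.

63 texture features computed on the mouth region of interest (lips plus
mouth-interior labels, 32 gray levels):

* histogram (6) + intensity (16) global features,
* GLCM (10), GLRLM (13), GLSZM (13), NGTDM (5) matrix features,

plus 8 shape descriptors for each of mouth, lips and tongue (24).  The
teeth label is ignored throughout.  Matrix constructions follow common
radiomics conventions: GLCM distance 1 averaged over 4 directions
(symmetric, normalized), GLRLM averaged over 4 directions, GLSZM with
8-connected zones, NGTDM over the 3x3 neighborhood with in-mask neighbors
only.  An absent articulator (empty mask) yields all-zero shape features,
which deliberately encodes how often the organ is visible into the
per-speaker averages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import graycomatrix
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton

from .containers import (
    MaskFrame,
    LABEL_LIPS,
    LABEL_MOUTH_INTERIOR,
    LABEL_TONGUE,
)

log = logging.getLogger("articulab")

_EPS = 1e-12
_COARSENESS_CAP = 1e6

HISTOGRAM_NAMES = ["hist_E", "hist_H", "hist_Var", "hist_SD", "hist_S", "hist_K"]
INTENSITY_NAMES = [
    "int_E", "int_Var", "int_SD", "int_min", "int_max", "int_mean",
    "int_med", "int_R", "int_MAD", "int_rMAD", "int_RMS", "int_p10",
    "int_p90", "int_IQR", "int_S", "int_K",
]
GLCM_NAMES = [
    "glcm_ASM", "glcm_Con", "glcm_Ent", "glcm_Mean", "glcm_Var",
    "glcm_Cor", "glcm_Hom", "glcm_Dis", "glcm_AC", "glcm_SA",
]
GLRLM_NAMES = [
    "glrlm_SRE", "glrlm_LRE", "glrlm_GLN", "glrlm_RLN", "glrlm_RP",
    "glrlm_LGLRE", "glrlm_HGRE", "glrlm_SRLGLE", "glrlm_SRHGLE",
    "glrlm_LRLGLE", "glrlm_LRHGLE", "glrlm_GLV", "glrlm_RV",
]
GLSZM_NAMES = [
    "glszm_SZE", "glszm_LZE", "glszm_GLN", "glszm_ZSN", "glszm_ZP",
    "glszm_LGZE", "glszm_HGZE", "glszm_SZLGE", "glszm_SZHGE",
    "glszm_LZLGE", "glszm_LZHGE", "glszm_GLV", "glszm_ZSV",
]
NGTDM_NAMES = ["ngtdm_Coar", "ngtdm_Con", "ngtdm_Bus", "ngtdm_Com", "ngtdm_TS"]
SHAPE_NAMES = ["Ap", "P", "S", "SD", "Axmajor", "Axminor", "E", "DFeret"]

TEXTURE_NAMES = (
    HISTOGRAM_NAMES + INTENSITY_NAMES + GLCM_NAMES + GLRLM_NAMES
    + GLSZM_NAMES + NGTDM_NAMES
)
VISUAL_FEATURE_NAMES = TEXTURE_NAMES + [
    f"{organ}_{name}"
    for organ in ("mouth", "lips", "tongue")
    for name in SHAPE_NAMES
]
assert len(TEXTURE_NAMES) == 63
assert len(VISUAL_FEATURE_NAMES) == 87

#: Category per base visual feature name (texture vs organ shape).
VISUAL_CATEGORY = {
    **{n: "texture" for n in TEXTURE_NAMES},
    **{f"{organ}_{n}": organ for organ in ("mouth", "lips", "tongue") for n in SHAPE_NAMES},
}


# ---------------------------------------------------------------------------
# quantization

@dataclass
class QuantizedROI:
    """ROI gray levels uniformly binned to 1..Ng (0 outside the mask)."""

    levels: np.ndarray
    mask: np.ndarray
    Ng: int


def quantize_roi(gray_image: np.ndarray, mask: np.ndarray, Ng: int = 32) -> QuantizedROI:
    """Uniformly bin in-mask intensities from [min, max] into Ng levels.

    A constant ROI maps to level 1 everywhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot quantize an empty ROI")
    gray = np.asarray(gray_image, dtype=float)
    vals = gray[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(gray.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = np.floor((gray[mask] - lo) / (hi - lo) * Ng).astype(np.int32) + 1
        levels[mask] = np.clip(scaled, 1, Ng)
    return QuantizedROI(levels=levels, mask=mask, Ng=Ng)


# ---------------------------------------------------------------------------
# global features

def _moments(x: np.ndarray) -> Tuple[float, float, float, float]:
    """mean, variance, skewness, kurtosis (population; 0 when degenerate)."""
    mu = float(np.mean(x))
    d = x - mu
    var = float(np.mean(d**2))
    if var <= _EPS:
        return mu, 0.0, 0.0, 0.0
    sd = math.sqrt(var)
    skew = float(np.mean(d**3)) / sd**3
    kurt = float(np.mean(d**4)) / var**2
    return mu, var, skew, kurt


def global_features(
    gray_image: np.ndarray, mask: np.ndarray, q: QuantizedROI
) -> List[float]:
    """22 global features: 6 from the quantized-level histogram plus 16
    from the raw in-mask intensities."""
    lv = q.levels[q.mask]
    counts = np.bincount(lv, minlength=q.Ng + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    hist_E = float(np.sum(p**2))
    hist_H = float(-np.sum(nz * np.log2(nz)))
    centers = np.arange(1, q.Ng + 1, dtype=float)
    mu_h = float(np.sum(centers * p))
    var_h = float(np.sum((centers - mu_h) ** 2 * p))
    sd_h = math.sqrt(var_h)
    if var_h > _EPS:
        s_h = float(np.sum((centers - mu_h) ** 3 * p)) / sd_h**3
        k_h = float(np.sum((centers - mu_h) ** 4 * p)) / var_h**2
    else:
        s_h, k_h = 0.0, 0.0

    x = np.asarray(gray_image, dtype=float)[np.asarray(mask, dtype=bool)]
    mu, var, skew, kurt = _moments(x)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(sub - np.mean(sub)))) if len(sub) else 0.0
    return [
        hist_E, hist_H, var_h, sd_h, s_h, k_h,
        float(np.sum(x**2)), var, math.sqrt(var), float(x.min()), float(x.max()),
        mu, float(med), float(x.max() - x.min()),
        float(np.mean(np.abs(x - mu))), rmad,
        float(np.sqrt(np.mean(x**2))), float(p10), float(p90),
        float(p75 - p25), skew, kurt,
    ]


# ---------------------------------------------------------------------------
# GLCM

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def glcm_matrix(q: QuantizedROI, angles: Optional[Tuple[float, ...]] = None) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix averaged over the four
    distance-1 directions (or the given angles), restricted to in-mask
    pixel pairs."""
    img = q.levels.astype(np.uint8)  # 0 = outside mask
    glcm = graycomatrix(
        img,
        distances=[1],
        angles=list(angles or _GLCM_ANGLES),
        levels=q.Ng + 1,
        symmetric=True,
        normed=False,
    )[1:, 1:, 0, :].astype(float)  # drop out-of-mask row/col
    mat = glcm.mean(axis=-1)
    total = mat.sum()
    if total <= 0:
        raise ValueError("no valid in-mask pixel pairs for GLCM")
    return mat / total


def glcm_features(q: QuantizedROI, angles: Optional[Tuple[float, ...]] = None) -> List[float]:
    p = glcm_matrix(q, angles)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    asm = float(np.sum(p**2))
    con = float(np.sum((ii - jj) ** 2 * p))
    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log2(nz)))
    px = p.sum(axis=1)
    mu_x = float(np.sum(i * px))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    # symmetric matrix: marginals coincide
    if var_x > _EPS:
        cor = float(np.sum((ii - mu_x) * (jj - mu_x) * p)) / var_x
    else:
        cor = 0.0
    hom = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    dis = float(np.sum(np.abs(ii - jj) * p))
    ac = float(np.sum(ii * jj * p))
    # p_{x+y}: marginal over the diagonal sum i+j (values 2..2*ng)
    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel())
    sa = float(np.sum(np.arange(len(psum)) * psum))
    return [asm, con, ent, mu_x, var_x, cor, hom, dis, ac, sa]


# ---------------------------------------------------------------------------
# run-length (GLRLM)

def _column_runs(levels: np.ndarray, valid: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Run values and lengths scanning each column downward."""
    lv = levels.T
    vd = valid.T
    same_prev = np.zeros_like(vd)
    same_prev[:, 1:] = vd[:, 1:] & vd[:, :-1] & (lv[:, 1:] == lv[:, :-1])
    starts = vd & ~same_prev
    flat_valid = vd.ravel()
    flat_starts = starts.ravel()
    run_id = np.cumsum(flat_starts) - 1
    lengths = np.bincount(run_id[flat_valid])
    values = lv.ravel()[flat_starts]
    return values, lengths


def _shear(levels: np.ndarray, valid: np.ndarray, anti: bool):
    h, w = levels.shape
    lv = np.zeros((h, w + h), dtype=levels.dtype)
    vd = np.zeros((h, w + h), dtype=bool)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    shifted = cols + rows if anti else cols - rows + (h - 1)
    lv[rows, shifted] = levels
    vd[rows, shifted] = valid
    return lv, vd


def run_length_matrix(q: QuantizedROI, direction: str = "mean") -> np.ndarray:
    """GLRLM P[i-1, l-1] = number of runs of level i and length l.

    ``direction`` is one of ``horizontal, vertical, diag45, diag135`` or
    ``mean`` (matrices averaged over the four directions).
    """
    lv, vd = q.levels, q.mask
    per_dir = {
        "horizontal": lambda: _column_runs(lv.T, vd.T),
        "vertical": lambda: _column_runs(lv, vd),
        "diag45": lambda: _column_runs(*_shear(lv, vd, anti=True)),
        "diag135": lambda: _column_runs(*_shear(lv, vd, anti=False)),
    }
    dirs = list(per_dir) if direction == "mean" else [direction]
    results = [per_dir[d]() for d in dirs]
    max_len = max(int(lengths.max()) for _, lengths in results)
    mat = np.zeros((q.Ng, max_len))
    for values, lengths in results:
        np.add.at(mat, (values - 1, lengths - 1), 1.0)
    return mat / len(dirs)


def _run_zone_features(mat: np.ndarray, n_pixels: int) -> List[float]:
    """Shared 13-feature set over a run-length or size-zone matrix."""
    nr = mat.sum()
    if nr <= 0:
        return [0.0] * 13
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    p = mat / nr
    sre = float(np.sum(mat / j**2)) / nr
    lre = float(np.sum(mat * j**2)) / nr
    gln = float(np.sum(mat.sum(axis=1) ** 2)) / nr
    rln = float(np.sum(mat.sum(axis=0) ** 2)) / nr
    rp = float(nr) / n_pixels
    lglre = float(np.sum(mat / i**2)) / nr
    hgre = float(np.sum(mat * i**2)) / nr
    srlgle = float(np.sum(mat / (i**2 * j**2))) / nr
    srhgle = float(np.sum(mat * i**2 / j**2)) / nr
    lrlgle = float(np.sum(mat * j**2 / i**2)) / nr
    lrhgle = float(np.sum(mat * i**2 * j**2)) / nr
    mu_i = float(np.sum(p * i))
    glv = float(np.sum(p * (i - mu_i) ** 2))
    mu_j = float(np.sum(p * j))
    rv = float(np.sum(p * (j - mu_j) ** 2))
    return [sre, lre, gln, rln, rp, lglre, hgre, srlgle, srhgle, lrlgle, lrhgle, glv, rv]


def glrlm_features(q: QuantizedROI, direction: str = "mean") -> List[float]:
    return _run_zone_features(run_length_matrix(q, direction), int(q.mask.sum()))


# ---------------------------------------------------------------------------
# size-zone (GLSZM)

_STRUCT8 = np.ones((3, 3), dtype=bool)


def size_zone_matrix(q: QuantizedROI) -> np.ndarray:
    """GLSZM P[i-1, s-1] = number of 8-connected zones of level i, size s.

    Zones are connected components of equal gray level; a single labeling
    pass over the level image finds them all (level 0 = outside mask).
    """
    lab, n_zones = sk_label(
        q.levels, background=0, connectivity=2, return_num=True
    )
    if n_zones == 0:
        raise ValueError("empty ROI has no zones")
    flat_lab = lab.ravel()
    sizes = np.bincount(flat_lab)[1:]
    first_idx = np.full(n_zones + 1, -1, dtype=np.int64)
    nz = np.flatnonzero(flat_lab)
    # first occurrence of each zone id gives its gray level
    first_idx[flat_lab[nz[::-1]]] = nz[::-1]
    zone_levels = q.levels.ravel()[first_idx[1:]]
    mat = np.zeros((q.Ng, int(sizes.max())))
    np.add.at(mat, (zone_levels - 1, sizes - 1), 1.0)
    return mat


def glszm_features(q: QuantizedROI) -> List[float]:
    return _run_zone_features(size_zone_matrix(q), int(q.mask.sum()))


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(q: QuantizedROI) -> List[float]:
    """Amadasun-King NGTDM features over the 3x3 neighborhood.

    For every in-mask pixel with at least one in-mask neighbor, the
    absolute difference between its level and the average level of its
    in-mask neighbors contributes to its gray level's s_i.
    """
    mask_f = q.mask.astype(float)
    lv_f = (q.levels * q.mask).astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv_f, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(mask_f, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nbr_cnt > 0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return [0.0] * 5
    avg = nbr_sum[valid] / nbr_cnt[valid]
    lv = q.levels[valid]
    diff = np.abs(lv - avg)
    s = np.bincount(lv, weights=diff, minlength=q.Ng + 1)[1:]
    n_i = np.bincount(lv, minlength=q.Ng + 1)[1:]
    p = n_i / n_valid
    present = p > 0
    i = np.arange(1, q.Ng + 1, dtype=float)
    ngp = int(present.sum())

    psi = float(np.sum(p * s))
    coarseness = min(1.0 / psi, _COARSENESS_CAP) if psi > _EPS else _COARSENESS_CAP

    if ngp > 1:
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        contrast = (
            float(np.sum(pi * pj * (ii - jj) ** 2)) / (ngp * (ngp - 1))
        ) * (float(np.sum(s)) / n_valid)
        ipi = i[present] * p[present]
        denom_b = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = psi / denom_b if denom_b > _EPS else 0.0
        ps = (p * s)[present]
        complexity = float(
            np.sum(
                np.abs(ii - jj) * (ps[:, None] + ps[None, :]) / (pi + pj)
            )
        ) / n_valid
        s_total = float(np.sum(s))
        strength = (
            float(np.sum((pi + pj) * (ii - jj) ** 2)) / s_total
            if s_total > _EPS
            else 0.0
        )
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return [coarseness, contrast, busyness, complexity, strength]


# ---------------------------------------------------------------------------
# shape

def shape_features(mask: np.ndarray) -> List[float]:
    """8 shape descriptors of a binary region; all zero for an empty mask.

    Sphericity is realized as 2D circularity ``2*sqrt(pi*Ap)/P`` with the
    Crofton perimeter; axes derive from the ellipse of equal second
    central moments; the maximum Feret diameter is the largest pairwise
    distance between boundary pixel centres.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        return [0.0] * 8
    per = float(perimeter_crofton(mask, directions=4))
    if per > 0:
        sph = 2.0 * math.sqrt(math.pi * area) / per
        sd = 1.0 / sph
    else:
        sph, sd = 0.0, 0.0
    rr, cc = np.nonzero(mask)
    mu_r, mu_c = rr.mean(), cc.mean()
    dr, dc = rr - mu_r, cc - mu_c
    cov = np.array(
        [[np.mean(dr * dr), np.mean(dr * dc)], [np.mean(dr * dc), np.mean(dc * dc)]]
    )
    eigs = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    ax_minor = 4.0 * math.sqrt(eigs[0])
    ax_major = 4.0 * math.sqrt(eigs[1])
    elong = ax_minor / ax_major if ax_major > 0 else 0.0
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0)
    pts = np.column_stack(np.nonzero(boundary)).astype(float)
    if len(pts) < 2:
        feret = 0.0
    else:
        if len(pts) > 16:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except QhullError:
                pass  # collinear points: brute-force below
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        feret = float(math.sqrt(d2.max()))
    return [area, per, sph, sd, ax_major, ax_minor, elong, feret]


# ---------------------------------------------------------------------------
# frame driver

def _crop_to_bbox(*arrays: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Crop arrays to the bounding box of the first (boolean) one.

    All computed features are translation invariant, so tight cropping is
    purely a speed optimization.
    """
    ref = arrays[0]
    rr, cc = np.nonzero(ref)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    return tuple(a[r0:r1, c0:c1] for a in arrays)


def extract_visual(frame: MaskFrame, gray_levels: int = 32) -> Dict[str, float]:
    """All 87 visual features of one camera frame.

    Texture is computed on the mouth ROI (lips plus mouth-interior
    labels); shape blocks cover the whole mouth region, the lips and the
    tongue.  The teeth label is ignored.
    """
    labels = frame.label_mask
    lips = labels == LABEL_LIPS
    interior = labels == LABEL_MOUTH_INTERIOR
    roi = lips | interior
    if not roi.any():
        raise ValueError(
            f"frame {frame.frame_index} ({frame.camera}): no mouth region in mask"
        )
    roi_c, gray_c = _crop_to_bbox(roi, frame.gray_image)
    q = quantize_roi(gray_c, roi_c, gray_levels)
    values: List[float] = []
    values += global_features(gray_c, roi_c, q)
    values += glcm_features(q)
    values += glrlm_features(q)
    values += glszm_features(q)
    values += ngtdm_features(q)
    for organ_mask in (labels > 0, lips, labels == LABEL_TONGUE):
        if organ_mask.any():
            values += shape_features(_crop_to_bbox(organ_mask)[0])
        else:
            values += shape_features(organ_mask)
    return dict(zip(VISUAL_FEATURE_NAMES, values))
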