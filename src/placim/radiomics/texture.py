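"""Texture-matrix features on a discretized ROI.

Five families over gray levels 1..N_g (pixels outside the ROI never enter
any count):

* GLCM — symmetric co-occurrence at distance delta over the four 2D angle
  offsets 0/45/90/135 degrees; the 22 features are computed per angle and
  averaged.
* GLRLM — run lengths of equal-level pixels along the same four angles,
  runs broken by the ROI boundary; 16 features, angle-averaged.
* GLSZM — sizes of 8-connected equal-level zones; 16 features, single
  matrix (no direction).
* NGTDM — per-level absolute difference from the mean of in-ROI
  8-neighbours; 5 features.
* GLDM — dependence counts: for each pixel, 1 + the number of in-ROI
  8-neighbours whose level differs by at most ``alpha`` (default 0);
  14 features.

Degenerate conventions for a constant ROI: correlation-type GLCM features
(correlation, imc1, imc2) are 0 and all entropies are 0, so vectors stay
finite.

Angle offsets (row, col): 0 deg -> (0, d); 45 deg -> (-d, d);
90 deg -> (-d, 0); 135 deg -> (-d, -d).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .catalog import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    TEXTURE_NAMES,
)
from .discretize import DiscretizedRoi

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
_EPS = np.finfo(np.float64).tiny


def _xlog2x(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(p + _EPS), 0.0)


def _shifted_pairs(levels: np.ndarray, offset: tuple[int, int]):
    """Level pairs (a, b) for all in-ROI pixel pairs at the given offset."""
    dr, dc = offset
    h, w = levels.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


# ---------------------------------------------------------------- GLCM

def glcm_matrix(d: DiscretizedRoi, distance: int = 1,
                angles=(0, 45, 90, 135)) -> dict[int, np.ndarray]:
    """Symmetric, normalised co-occurrence matrix per angle.

    An angle with no valid pair inside the ROI yields the degenerate
    matrix [[1]] extended with zeros (all mass at level 1), keeping the
    features defined.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = max(d.n_levels, 1)
    out = {}
    for ang in angles:
        dr, dc = ANGLE_OFFSETS[ang]
        a, b = _shifted_pairs(d.levels, (dr * distance, dc * distance))
        p = np.zeros((ng, ng), dtype=np.float64)
        if a.size:
            np.add.at(p, (a - 1, b - 1), 1.0)
            p = p + p.T                      # symmetric accumulation
            p /= p.sum()
        else:
            p[0, 0] = 1.0
        out[ang] = p
    return out


def glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """The 22 GLCM features of one normalised symmetric matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())               # = mu_x = mu_y by symmetry
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=np.float64)            # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)  # i+j = 2..2ng
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    autocorr = float((p * ii * jj).sum())
    contrast = float((p * (ii - jj) ** 2).sum())
    correlation = (autocorr - mu * mu) / sigma2 if sigma2 > 0 else 0.0
    diff_avg = float((k_diff * p_diff).sum())
    joint_ent = float(-_xlog2x(p).sum())
    hx = float(-_xlog2x(px).sum())
    pxpy = np.outer(px, px)
    hxy1 = float(-(p * np.where(pxpy > 0, np.log2(pxpy + _EPS), 0.0)).sum())
    hxy2 = float(-_xlog2x(pxpy).sum())
    imc1 = (joint_ent - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_ent)))))
    off_diag = ii != jj
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()) if off_diag.any() else 0.0
    return {
        "glcm_autocorrelation": autocorr,
        "glcm_joint_average": mu,
        "glcm_cluster_prominence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "glcm_cluster_shade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "glcm_cluster_tendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": float(-_xlog2x(p_diff).sum()),
        "glcm_difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": joint_ent,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "glcm_id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_variance": inv_var,
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_entropy": float(-_xlog2x(p_sum).sum()),
        "glcm_sum_squares": float((p * (ii - mu) ** 2).sum()),
    }


def glcm_features(d: DiscretizedRoi, distance: int = 1) -> dict[str, float]:
    """Angle-averaged GLCM features."""
    mats = glcm_matrix(d, distance=distance)
    per_angle = [glcm_features_single(p) for p in mats.values()]
    return {k: float(np.mean([f[k] for f in per_angle])) for k in GLCM_NAMES}


# ---------------------------------------------------------------- GLRLM

def _lines_along(levels: np.ndarray, angle: int):
    """All scan lines of the array along one of the four angles."""
    if angle == 0:
        yield from levels
    elif angle == 90:
        yield from levels.T
    elif angle == 45:
        flipped = levels[:, ::-1]
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(flipped, offset=off)
    elif angle == 135:
        for off in range(-levels.shape[0] + 1, levels.shape[1]):
            yield np.diagonal(levels, offset=off)
    else:
        raise ValueError(f"unsupported angle {angle}")


def run_lengths(levels: np.ndarray, angle: int) -> list[tuple[int, int]]:
    """(gray level, run length) of every maximal run along an angle.

    Runs are maximal stretches of equal non-zero level; a zero (outside
    the ROI) terminates a run.
    """
    runs = []
    for line in _lines_along(levels, angle):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # boundaries where the value changes
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            if line[s] > 0:
                runs.append((int(line[s]), int(e - s)))
    return runs


def glrlm_matrix(d: DiscretizedRoi, angle: int) -> np.ndarray:
    """Run-length count matrix P[i-1, r-1] for one angle."""
    ng = max(d.n_levels, 1)
    runs = run_lengths(d.levels, angle)
    rmax = max((r for _, r in runs), default=1)
    p = np.zeros((ng, rmax), dtype=np.float64)
    for g, r in runs:
        p[g - 1, r - 1] += 1.0
    return p


def _size_distribution_features(p: np.ndarray, n_pixels: int, prefix: str,
                                size_names: tuple[str, str]) -> dict[str, float]:
    """Shared GLRLM/GLSZM/GLDM feature formulas on a (level x size) matrix.

    ``p`` holds raw counts; ``size_names`` are the family-specific stems
    for the size-axis marginal features (e.g. run vs zone vs dependence).
    """
    nr = p.sum()
    if nr == 0:
        p = p.copy()
        p[0, 0] = 1.0
        nr = 1.0
    ng, rmax = p.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    r = np.arange(1, rmax + 1, dtype=np.float64)
    pn = p / nr
    pg = pn.sum(axis=1)       # gray-level marginal
    pr = pn.sum(axis=0)       # size marginal
    mu_i = float((i * pg).sum())
    mu_r = float((r * pr).sum())
    ii = i[:, None]
    rr = r[None, :]
    short_stem, long_stem = size_names
    return {
        f"{prefix}_{short_stem}": float((pn / rr**2).sum()),
        f"{prefix}_{long_stem}": float((pn * rr**2).sum()),
        f"{prefix}_gray_level_nonuniformity": float((p.sum(axis=1) ** 2).sum() / nr),
        f"{prefix}_gray_level_nonuniformity_normalized": float((pg**2).sum()),
        f"{prefix}_size_nonuniformity": float((p.sum(axis=0) ** 2).sum() / nr),
        f"{prefix}_size_nonuniformity_normalized": float((pr**2).sum()),
        f"{prefix}_percentage": float(nr / n_pixels),
        f"{prefix}_gray_level_variance": float((pn * (ii - mu_i) ** 2).sum()),
        f"{prefix}_size_variance": float((pn * (rr - mu_r) ** 2).sum()),
        f"{prefix}_entropy": float(-_xlog2x(pn).sum()),
        f"{prefix}_low_gray_level": float((pg / i**2).sum()),
        f"{prefix}_high_gray_level": float((pg * i**2).sum()),
        f"{prefix}_short_low": float((pn / (ii**2 * rr**2)).sum()),
        f"{prefix}_short_high": float((pn * ii**2 / rr**2).sum()),
        f"{prefix}_long_low": float((pn * rr**2 / ii**2).sum()),
        f"{prefix}_long_high": float((pn * ii**2 * rr**2).sum()),
    }


_GLRLM_KEYMAP = {
    "glrlm_short_run_emphasis": "g_short_run_emphasis",
    "glrlm_long_run_emphasis": "g_long_run_emphasis",
    "glrlm_gray_level_nonuniformity": "g_gray_level_nonuniformity",
    "glrlm_gray_level_nonuniformity_normalized": "g_gray_level_nonuniformity_normalized",
    "glrlm_run_length_nonuniformity": "g_size_nonuniformity",
    "glrlm_run_length_nonuniformity_normalized": "g_size_nonuniformity_normalized",
    "glrlm_run_percentage": "g_percentage",
    "glrlm_gray_level_variance": "g_gray_level_variance",
    "glrlm_run_variance": "g_size_variance",
    "glrlm_run_entropy": "g_entropy",
    "glrlm_low_gray_level_run_emphasis": "g_low_gray_level",
    "glrlm_high_gray_level_run_emphasis": "g_high_gray_level",
    "glrlm_short_run_low_gray_level_emphasis": "g_short_low",
    "glrlm_short_run_high_gray_level_emphasis": "g_short_high",
    "glrlm_long_run_low_gray_level_emphasis": "g_long_low",
    "glrlm_long_run_high_gray_level_emphasis": "g_long_high",
}


def glrlm_features(d: DiscretizedRoi) -> dict[str, float]:
    """Angle-averaged run-length features."""
    per_angle = []
    for ang in ANGLE_OFFSETS:
        p = glrlm_matrix(d, ang)
        per_angle.append(_size_distribution_features(
            p, d.n_pixels, "g", ("short_run_emphasis", "long_run_emphasis")))
    return {out: float(np.mean([f[key] for f in per_angle]))
            for out, key in _GLRLM_KEYMAP.items()}


# ---------------------------------------------------------------- GLSZM

def glszm_matrix(d: DiscretizedRoi) -> np.ndarray:
    """Zone-size count matrix over 8-connected equal-level zones."""
    ng = max(d.n_levels, 1)
    structure = np.ones((3, 3), dtype=int)
    zones = []
    for g in range(1, ng + 1):
        lab, n = ndimage.label(d.levels == g, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((g, int(s)) for s in sizes)
    zmax = max((s for _, s in zones), default=1)
    p = np.zeros((ng, zmax), dtype=np.float64)
    for g, s in zones:
        p[g - 1, s - 1] += 1.0
    return p


_GLSZM_KEYMAP = {
    "glszm_small_area_emphasis": "z_small_area_emphasis",
    "glszm_large_area_emphasis": "z_large_area_emphasis",
    "glszm_gray_level_nonuniformity": "z_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized": "z_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity": "z_size_nonuniformity",
    "glszm_size_zone_nonuniformity_normalized": "z_size_nonuniformity_normalized",
    "glszm_zone_percentage": "z_percentage",
    "glszm_gray_level_variance": "z_gray_level_variance",
    "glszm_zone_variance": "z_size_variance",
    "glszm_zone_entropy": "z_entropy",
    "glszm_low_gray_level_zone_emphasis": "z_low_gray_level",
    "glszm_high_gray_level_zone_emphasis": "z_high_gray_level",
    "glszm_small_area_low_gray_level_emphasis": "z_short_low",
    "glszm_small_area_high_gray_level_emphasis": "z_short_high",
    "glszm_large_area_low_gray_level_emphasis": "z_long_low",
    "glszm_large_area_high_gray_level_emphasis": "z_long_high",
}


def glszm_features(d: DiscretizedRoi) -> dict[str, float]:
    feats = _size_distribution_features(
        glszm_matrix(d), d.n_pixels, "z", ("small_area_emphasis", "large_area_emphasis"))
    return {out: feats[key] for out, key in _GLSZM_KEYMAP.items()}


# ---------------------------------------------------------------- NGTDM

_NEIGHBOUR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                      (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbour_sums(levels: np.ndarray):
    """Sum of in-ROI neighbour levels and neighbour counts per pixel."""
    inside = levels > 0
    vals = np.where(inside, levels, 0).astype(np.float64)
    total = np.zeros(levels.shape, dtype=np.float64)
    count = np.zeros(levels.shape, dtype=np.float64)
    h, w = levels.shape
    for dr, dc in _NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        total[r0:r1, c0:c1] += vals[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        count[r0:r1, c0:c1] += inside[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return total, count


def ngtdm_table(d: DiscretizedRoi):
    """(n_i, p_i, s_i) per level 1..N_g.

    ``s_i`` sums |level - mean of in-ROI neighbours| over the level's
    pixels; pixels with no in-ROI neighbour contribute 0.
    """
    levels = d.levels
    inside = levels > 0
    total, count = _neighbour_sums(levels)
    nvp = int(inside.sum())
    ng = max(d.n_levels, 1)
    diff = np.zeros(levels.shape, dtype=np.float64)
    has_nb = count > 0
    sel = inside & has_nb
    diff[sel] = np.abs(levels[sel] - total[sel] / count[sel])
    n_i = np.bincount(levels[inside], minlength=ng + 1)[1:].astype(np.float64)
    s_i = np.zeros(ng)
    np.add.at(s_i, levels[inside] - 1, diff[inside])
    return n_i, n_i / nvp, s_i


def ngtdm_features(d: DiscretizedRoi) -> dict[str, float]:
    n_i, p_i, s_i = ngtdm_table(d)
    nvp = n_i.sum()
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, len(p_i) + 1, dtype=np.float64)
    ip, pp, sp = i[present], p_i[present], s_i[present]
    coarse_den = float((pp * sp).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        pair = pp[:, None] * pp[None, :] * (ip[:, None] - ip[None, :]) ** 2
        contrast = pair.sum() / (ngp * (ngp - 1)) * sp.sum() / nvp
        busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        comp = (np.abs(ip[:, None] - ip[None, :])
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :]))
        complexity = comp.sum() / nvp
        strength_num = ((pp[:, None] + pp[None, :]) * (ip[:, None] - ip[None, :]) ** 2).sum()
        strength = strength_num / sp.sum() if sp.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": float(complexity),
        "ngtdm_strength": float(strength),
    }


# ---------------------------------------------------------------- GLDM

def gldm_matrix(d: DiscretizedRoi, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P[i-1, k-1].

    The dependence of a pixel is 1 (itself) plus the number of in-ROI
    8-neighbours whose level differs from it by at most ``alpha``.
    """
    levels = d.levels
    inside = levels > 0
    h, w = levels.shape
    dep = np.ones(levels.shape, dtype=np.int64)
    for dr, dc in _NEIGHBOUR_OFFSETS:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        nb = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (nb > 0) & (np.abs(levels[r0:r1, c0:c1] - nb) <= alpha)
        dep[r0:r1, c0:c1] += ok
    ng = max(d.n_levels, 1)
    dmax = int(dep[inside].max()) if inside.any() else 1
    p = np.zeros((ng, dmax), dtype=np.float64)
    np.add.at(p, (levels[inside] - 1, dep[inside] - 1), 1.0)
    return p


_GLDM_KEYMAP = {
    "gldm_small_dependence_emphasis": "d_small_dependence_emphasis",
    "gldm_large_dependence_emphasis": "d_large_dependence_emphasis",
    "gldm_gray_level_nonuniformity": "d_gray_level_nonuniformity",
    "gldm_dependence_nonuniformity": "d_size_nonuniformity",
    "gldm_dependence_nonuniformity_normalized": "d_size_nonuniformity_normalized",
    "gldm_gray_level_variance": "d_gray_level_variance",
    "gldm_dependence_variance": "d_size_variance",
    "gldm_dependence_entropy": "d_entropy",
    "gldm_low_gray_level_emphasis": "d_low_gray_level",
    "gldm_high_gray_level_emphasis": "d_high_gray_level",
    "gldm_small_dependence_low_gray_level_emphasis": "d_short_low",
    "gldm_small_dependence_high_gray_level_emphasis": "d_short_high",
    "gldm_large_dependence_low_gray_level_emphasis": "d_long_low",
    "gldm_large_dependence_high_gray_level_emphasis": "d_long_high",
}


def gldm_features(d: DiscretizedRoi, alpha: int = 0) -> dict[str, float]:
    feats = _size_distribution_features(
        gldm_matrix(d, alpha), d.n_pixels, "d",
        ("small_dependence_emphasis", "large_dependence_emphasis"))
    return {out: feats[key] for out, key in _GLDM_KEYMAP.items()}


# ---------------------------------------------------------------- all

def texture_features(d: DiscretizedRoi, glcm_distance: int = 1,
                     gldm_alpha: int = 0) -> dict[str, float]:
    """All 73 texture features in catalog order."""
    out: dict[str, float] = {}
    out.update(glcm_features(d, distance=glcm_distance))
    out.update(glrlm_features(d))
    out.update(glszm_features(d))
    out.update(ngtdm_features(d))
    out.update(gldm_features(d, alpha=gldm_alpha))
    return {k: out[k] for k in TEXTURE_NAMES}
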