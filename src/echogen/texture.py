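"""GLCM texture quantification of QUS parametric maps.

Each map is linearly quantized into 16 gray levels over its own valid range,
then symmetric gray-level co-occurrence matrices are accumulated at
inter-pixel distances 1-5 and angles 0/45/90/135 degrees. Contrast,
correlation, energy and homogeneity are averaged over the 20 GLCMs; together
with the map mean this yields the 25-dimensional per-lesion feature vector
({MBF,SS,SI,ESD,EAC} x {MEAN,CON,COR,ENE,HOM}).

The GLCM here is mask-aware: pixel pairs with either member outside the
validity mask are skipped, which is why it is computed on the raw
window-center grid rather than display-interpolated maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qus import MAP_NAMES, ParametricMapSet, mean_value_features

__all__ = [
    "QuantizedMap", "GLCMatrix", "FEATURE_NAMES",
    "quantize_map", "compute_glcm", "glcm_features", "texture_vector",
    "lesion_feature_vector",
]

DEFAULT_LEVELS = 16
DISTANCES = (1, 2, 3, 4, 5)
ANGLES_DEG = (0, 45, 90, 135)

# offsets as (d_row, d_col) per angle, row axis pointing down
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

TEXTURE_NAMES = ("CON", "COR", "ENE", "HOM")
FEATURE_NAMES = tuple(f"{m}-{t}" for m in MAP_NAMES
                      for t in ("MEAN",) + TEXTURE_NAMES)


@dataclass
class QuantizedMap:
    levels_img: np.ndarray   # int, in [0, levels-1]
    valid: np.ndarray
    levels: int
    source: str = ""


@dataclass
class GLCMatrix:
    p: np.ndarray            # [L, L], sums to 1, symmetric
    distance: int
    angle_deg: int
    symmetric: bool = True


def quantize_map(map_values: np.ndarray, valid: np.ndarray,
                 levels: int = DEFAULT_LEVELS, source: str = "") -> QuantizedMap:
    """Linear scaling of the valid range into ``levels`` bins (floor binning,
    maximum mapped to the top level); a constant map maps to all zeros."""
    m = np.asarray(map_values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if m.shape != valid.shape:
        raise ValueError("map and mask shapes differ")
    if not valid.any():
        raise ValueError("empty validity mask")
    vals = m[valid]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(m.shape, dtype=np.int64)
    if hi > lo:
        scaled = (vals - lo) / (hi - lo) * levels
        q[valid] = np.minimum(np.floor(scaled), levels - 1).astype(np.int64)
    return QuantizedMap(q, valid, levels, source)


def compute_glcm(q: QuantizedMap, distance: int, angle_deg: int,
                 symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence probabilities at one (distance, angle) offset.

    Counts ordered pairs at the offset whose both pixels are valid, adds the
    transpose when symmetric, and normalizes to sum 1.
    """
    if angle_deg not in _ANGLE_OFFSETS:
        raise ValueError("angle must be one of 0, 45, 90, 135 degrees")
    dr, dc = (o * distance for o in _ANGLE_OFFSETS[angle_deg])
    img, valid, L = q.levels_img, q.valid, q.levels
    rows, cols = img.shape

    r0_lo, r0_hi = max(0, -dr), min(rows, rows - dr)
    c0_lo, c0_hi = max(0, -dc), min(cols, cols - dc)
    counts = np.zeros((L, L), dtype=np.float64)
    if r0_hi > r0_lo and c0_hi > c0_lo:
        a = img[r0_lo:r0_hi, c0_lo:c0_hi]
        b = img[r0_lo + dr:r0_hi + dr, c0_lo + dc:c0_hi + dc]
        ok = (valid[r0_lo:r0_hi, c0_lo:c0_hi]
              & valid[r0_lo + dr:r0_hi + dr, c0_lo + dc:c0_hi + dc])
        np.add.at(counts, (a[ok], b[ok]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs at this offset")
    return GLCMatrix(counts / total, distance, angle_deg, symmetric)


def glcm_features(g: GLCMatrix) -> dict:
    """Contrast, correlation, energy, homogeneity of one GLCM.

    CON = sum p(i,j) (i-j)^2; COR = sum p(i,j)(i-mu_i)(j-mu_j)/(s_i s_j);
    ENE = sum p^2; HOM = sum p/(1+|i-j|). Degenerate correlation (zero
    marginal spread) is defined as 1.
    """
    p = g.p
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized")
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    con = float(np.sum(p * (i - j) ** 2))
    ene = float(np.sum(p ** 2))
    hom = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(L) * pi))
    mu_j = float(np.sum(np.arange(L) * pj))
    var_i = float(np.sum((np.arange(L) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(L) - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        cor = 1.0
    else:
        cor = float(np.sum(p * (i - mu_i) * (j - mu_j))
                    / np.sqrt(var_i * var_j))
    return {"CON": con, "COR": cor, "ENE": ene, "HOM": hom}


def texture_vector(map_values: np.ndarray, valid: np.ndarray,
                   levels: int = DEFAULT_LEVELS,
                   distances: Sequence[int] = DISTANCES,
                   angles_deg: Sequence[int] = ANGLES_DEG) -> dict:
    """Four texture features averaged over all distance x angle GLCMs
    (default 5 x 4 = 20)."""
    q = quantize_map(map_values, valid, levels)
    acc = {name: [] for name in TEXTURE_NAMES}
    for d in distances:
        for ang in angles_deg:
            try:
                feats = glcm_features(compute_glcm(q, d, ang))
            except ValueError:
                continue  # no valid pairs at this offset (tiny ROI)
            for name in TEXTURE_NAMES:
                acc[name].append(feats[name])
    if not acc["CON"]:
        raise ValueError("no GLCM could be computed for this map")
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


def lesion_feature_vector(plane_maps: Sequence[ParametricMapSet],
                          region: str = "both",
                          levels: int = DEFAULT_LEVELS) -> dict:
    """25 named QUS features for one lesion, averaged across imaging planes.

    Per plane: the mean of each parametric map plus its four GLCM textures;
    the 25 values are then averaged elementwise over the planes, emulating
    averaging across the lesion volume.
    """
    if not plane_maps:
        raise ValueError("need at least one imaging plane")
    rows = []
    for maps in plane_maps:
        means = mean_value_features(maps, region=region)
        feats = {}
        if region == "core":
            rsel = maps.region == 2
        elif region == "margin":
            rsel = maps.region == 1
        else:
            rsel = maps.region > 0
        for name in MAP_NAMES:
            feats[f"{name}-MEAN"] = means[name]
            tex = texture_vector(maps.maps[name], maps.valid & rsel, levels)
            for tname, val in tex.items():
                feats[f"{name}-{tname}"] = val
        rows.append(feats)
    return {key: float(np.mean([r[key] for r in rows]))
            for key in FEATURE_NAMES}
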