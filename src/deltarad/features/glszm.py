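"""Gray-level size-zone matrix features (16).

A zone is a 26-connected component of equal gray level inside the ROI;
the matrix counts zones by (gray level, zone size).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_zones(levels: np.ndarray, n_levels: int) -> list[tuple[int, int]]:
    """(gray level, zone size) for every 26-connected equal-level zone."""
    zones: list[tuple[int, int]] = []
    for lev in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == lev, structure=_STRUCT26)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((lev, int(s)) for s in sizes)
    return zones


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = glszm_zones(levels, n_levels)
    smax = max(s for _, s in zones)
    mat = np.zeros((n_levels, smax), dtype=np.float64)
    for lev, s in zones:
        mat[lev - 1, s - 1] += 1.0
    return mat


def glszm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    g, smax = mat.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, smax + 1, dtype=np.float64)[None, :]
    nz = mat.sum()
    p = mat / nz
    zi = mat.sum(axis=1)
    zj = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nzp = p > 0
    return {
        "SmallAreaEmphasis": float((mat / j**2).sum() / nz),
        "LargeAreaEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((zi**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((zi**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((zj**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((zj**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (j - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(p[nzp] * np.log2(p[nzp])).sum()),
        "LowGrayLevelZoneEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((mat * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def glszm_features(levels: np.ndarray, n_levels: int, params=None) -> dict[str, float]:
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty mask")
    mat = glszm_matrix(levels, n_levels)
    return glszm_features_from_matrix(mat, n_voxels)
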