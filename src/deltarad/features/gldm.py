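"""Gray-level dependence matrix features (14).

The dependence of a voxel is the number of its 26-neighbours inside the ROI
whose gray level differs from the centre level by at most alpha.  The
matrix column index is the dependence count plus one (the centre voxel
itself), so the smallest dependence size is 1 and product weights such as
large-dependence high-gray-level emphasis are non-degenerate.
"""

from __future__ import annotations

import numpy as np

from .params import FeatureParams

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_NEIGHBORS = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]


def _shift(arr, off, fill=0):
    out = np.full_like(arr, fill)
    src, dst = [], []
    for o in off:
        if o == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif o > 0:
            src.append(slice(o, None)); dst.append(slice(None, -o))
        else:
            src.append(slice(None, o)); dst.append(slice(-o, None))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix, shape (G, 27)."""
    inmask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _NEIGHBORS:
        nb = _shift(levels, off)
        dep += (inmask & (nb > 0) & (np.abs(nb - levels) <= alpha)).astype(np.int64)
    mat = np.zeros((n_levels, 27), dtype=np.float64)
    np.add.at(mat, (levels[inmask] - 1, dep[inmask]), 1.0)
    nz_cols = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : nz_cols[-1] + 1]


def gldm_features_from_matrix(mat: np.ndarray) -> dict[str, float]:
    g, dmax = mat.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, dmax + 1, dtype=np.float64)[None, :]  # dependence size = count + 1
    nz = mat.sum()
    p = mat / nz
    gi = mat.sum(axis=1)
    dj = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nzp = p > 0
    return {
        "SmallDependenceEmphasis": float((mat / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((gi**2).sum() / nz),
        "DependenceNonUniformity": float((dj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((dj**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[nzp] * np.log2(p[nzp])).sum()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def gldm_features(levels: np.ndarray, n_levels: int, params: FeatureParams) -> dict[str, float]:
    if not (levels > 0).any():
        raise ValueError("empty mask")
    mat = gldm_matrix(levels, n_levels, alpha=params.gldm_alpha)
    return gldm_features_from_matrix(mat)
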