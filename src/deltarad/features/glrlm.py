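"""Gray-level run-length matrix features (16).

Runs are maximal straight segments of equal gray level counted along the 13
unique 3D directions; per-direction count matrices are averaged and the 16
emphasis/uniformity statistics are computed on the averaged matrix.
"""

from __future__ import annotations

import numpy as np

from .params import DIRECTIONS_3D, FeatureParams

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def _shift(arr: np.ndarray, off, fill=0) -> np.ndarray:
    """arr shifted so that out[v] = arr[v + off] (out-of-bounds -> fill)."""
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


def glrlm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Direction-averaged run-length count matrix, shape (G, max_run)."""
    g = n_levels
    max_run = int(max(levels.shape)) * 2  # generous bound; trimmed below
    mats = []
    for off in DIRECTIONS_3D:
        same_next = (levels > 0) & (levels == _shift(levels, off))
        # fixed-point scan: rl[v] = 1 + (same_next[v] ? rl[v+off] : 0)
        rl = np.ones(levels.shape, dtype=np.int64)
        changed = True
        while changed:
            nxt = 1 + np.where(same_next, _shift(rl, off), 0)
            changed = bool((nxt != rl).any())
            rl = nxt
        back = tuple(-o for o in off)
        is_start = (levels > 0) & ~((levels == _shift(levels, back)) & (_shift(levels, back) > 0))
        lv = levels[is_start] - 1
        ln = rl[is_start] - 1
        m = np.zeros((g, max_run), dtype=np.float64)
        np.add.at(m, (lv, ln), 1.0)
        mats.append(m)
    mat = np.mean(mats, axis=0)
    nz_cols = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : (nz_cols[-1] + 1)] if len(nz_cols) else mat[:, :1]


def glrlm_features_from_matrix(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    g, rmax = mat.shape
    i = np.arange(1, g + 1, dtype=np.float64)[:, None]
    j = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    nr = mat.sum()
    if nr <= 0:
        raise ValueError("empty run-length matrix")
    p = mat / nr
    ri = mat.sum(axis=1)  # per gray level
    rj = mat.sum(axis=0)  # per run length
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    nzp = p > 0
    return {
        "ShortRunEmphasis": float((mat / j**2).sum() / nr),
        "LongRunEmphasis": float((mat * j**2).sum() / nr),
        "GrayLevelNonUniformity": float((ri**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((ri**2).sum() / nr**2),
        "RunLengthNonUniformity": float((rj**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((rj**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - mu_j) ** 2).sum()),
        "RunEntropy": float(-(p[nzp] * np.log2(p[nzp])).sum()),
        "LowGrayLevelRunEmphasis": float((mat / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((mat * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nr),
    }


def glrlm_features(levels: np.ndarray, n_levels: int, params: FeatureParams) -> dict[str, float]:
    mask_count = int((levels > 0).sum())
    if mask_count == 0:
        raise ValueError("empty mask")
    mat = glrlm_matrix(levels, n_levels)
    return glrlm_features_from_matrix(mat, mask_count)
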