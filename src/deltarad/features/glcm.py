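"""Gray-level co-occurrence matrix features (24).

Co-occurrences are counted for the 13 unique 3D directions at Chebyshev
distance 1, each matrix is symmetrized and normalized, and features are
computed on the direction-averaged matrix.
"""

from __future__ import annotations

import numpy as np

from .params import DIRECTIONS_3D, FeatureParams

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
    "SumAverage",  # equals 2x JointAverage on a symmetric matrix; kept explicit
)


def _pair_slices(offset):
    """Slices (src, dst) so that arr[src] and arr[dst] are voxel pairs at `offset`."""
    src, dst = [], []
    for o in offset:
        if o == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif o > 0:
            src.append(slice(None, -o)); dst.append(slice(o, None))
        else:
            src.append(slice(-o, None)); dst.append(slice(None, o))
    return tuple(src), tuple(dst)


def glcm_matrix(levels: np.ndarray, n_levels: int, params: FeatureParams) -> np.ndarray:
    """Direction-averaged, symmetric, normalized co-occurrence matrix (G x G)."""
    g = n_levels
    mats = []
    for off in DIRECTIONS_3D:
        s, d = _pair_slices(off)
        a, b = levels[s].ravel(), levels[d].ravel()
        keep = (a > 0) & (b > 0)
        m = np.zeros((g, g), dtype=np.float64)
        np.add.at(m, (a[keep] - 1, b[keep] - 1), 1.0)
        if params.symmetric_glcm:
            m = m + m.T
        tot = m.sum()
        if tot > 0:
            mats.append(m / tot)
    if not mats:  # single in-mask voxel: no pairs in any direction
        m = np.zeros((g, g))
        m[0, 0] = 1.0
        mats = [m]
    return np.mean(mats, axis=0)


def glcm_features_from_matrix(p: np.ndarray) -> dict[str, float]:
    g = p.shape[0]
    i = np.arange(1, g + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((px * i).sum())
    muy = float((py * i).sum())
    sigx = float(np.sqrt((px * (i - mux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i - muy) ** 2).sum()))

    # diagonal (difference) and cross (sum) marginal distributions
    k_diff = np.arange(0, g)
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * g + 1)
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())

    eps = np.finfo(float).eps
    nz = p > 0
    hxy = float(-(p[nz] * np.log2(p[nz])).sum())
    pxpy = np.outer(px, py)
    nzj = pxpy > 0
    hxy1 = float(-(p[nzj] * np.log2(pxpy[nzj])).sum())
    hxy2 = float(-(pxpy[nzj] * np.log2(pxpy[nzj])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())

    diff_avg = float((k_diff * p_diff).sum())
    nzd = p_diff > 0
    diff_ent = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    nzs = p_sum > 0
    sum_ent = float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum())

    if sigx > 0 and sigy > 0:
        correlation = float(((ii - mux) * (jj - muy) * p).sum() / (sigx * sigy))
    else:
        correlation = 1.0  # degenerate single-level matrix

    # maximal correlation coefficient: sqrt of second-largest eigenvalue of Q
    mcc = 1.0
    if g > 1 and sigx > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.einsum("ik,jk->ij", p / np.where(px[:, None] > 0, px[:, None], 1.0),
                          p / np.where(py[:, None] > 0, py[:, None], 1.0))
        eigs = np.sort(np.abs(np.linalg.eigvals(q)))
        if len(eigs) >= 2:
            mcc = float(np.sqrt(np.clip(eigs[-2], 0.0, 1.0)))

    offdiag = ii != jj
    inv_var = float((p[offdiag] / (ii[offdiag] - jj[offdiag]) ** 2).sum())

    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "JointAverage": mux,
        "ClusterProminence": float((p * (ii + jj - mux - muy) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - mux - muy) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - mux - muy) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var,
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / g) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / g)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumEntropy": sum_ent,
        "SumSquares": float((p * (ii - mux) ** 2).sum()),
        "SumAverage": float((k_sum * p_sum).sum()),
    }


def glcm_features(levels: np.ndarray, n_levels: int, params: FeatureParams) -> dict[str, float]:
    p = glcm_matrix(levels, n_levels, params)
    return glcm_features_from_matrix(p)
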