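"""First-order (intensity-histogram) statistics: 18 features.

Energy uses no intensity shift (c = 0); subtraction images may be negative
and the convention is documented in the methods note.  Entropy and
Uniformity are computed on the discretized in-ROI histogram.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .params import FeatureParams, discretize

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    values: np.ndarray, mask: np.ndarray, params: FeatureParams, voxel_volume: float = 1.0
) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(values, dtype=np.float64)[mask]

    levels, _ = discretize(values, mask, params)
    counts = np.bincount(levels[mask])[1:]
    p = counts[counts > 0] / counts.sum()

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    mean = float(x.mean())
    var = float(x.var())  # population variance
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=False))
    else:
        skew, kurt = 0.0, 0.0

    return {
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean())
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
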