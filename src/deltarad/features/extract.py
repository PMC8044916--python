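"""Whole-ROI feature extraction: 102 named radiomic features.

Family sizes: shape 14, first-order 18, GLCM 24, GLRLM 16, GLSZM 16,
GLDM 14.  The name registry is frozen so feature vectors from different
runs and image sources align column-by-column.
"""

from __future__ import annotations

import numpy as np

from ..image import BinaryMask, ImageVolume
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .gldm import GLDM_NAMES, gldm_features
from .glcm import GLCM_NAMES, glcm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .params import FeatureParams, discretize
from .shape import SHAPE_NAMES, shape_features

FAMILY_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FAMILY_NAMES.items() for name in names
)
assert len(FEATURE_NAMES) == 102

FAMILY_COUNTS = {family: len(names) for family, names in FAMILY_NAMES.items()}


def _crop_to_bbox(values: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return values[sl], mask[sl]


def extract_all(
    volume: ImageVolume, mask: BinaryMask, params: FeatureParams | None = None
) -> dict[str, float]:
    """Compute all 102 features of one ROI on one image source.

    Texture families run on the gray-level-discretized image restricted to
    the mask bounding box; shape features use only the mask and spacing.
    """
    params = params or FeatureParams()
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    mb = mask.as_bool()
    if not mb.any():
        raise ValueError("empty ROI mask")

    vals, mcrop = _crop_to_bbox(np.asarray(volume.values, dtype=np.float64), mb)
    levels, n_levels = discretize(vals, mcrop, params)

    out: dict[str, float] = {}
    stages = (
        ("shape", lambda: shape_features(mb, volume.spacing)),
        ("firstorder", lambda: first_order_features(vals, mcrop, params, volume.voxel_volume)),
        ("glcm", lambda: glcm_features(levels, n_levels, params)),
        ("glrlm", lambda: glrlm_features(levels, n_levels, params)),
        ("glszm", lambda: glszm_features(levels, n_levels, params)),
        ("gldm", lambda: gldm_features(levels, n_levels, params)),
    )
    for family, fn in stages:
        try:
            feats = fn()
        except Exception as exc:  # annotate which family failed
            raise RuntimeError(f"feature family {family!r} failed: {exc}") from exc
        for name in FAMILY_NAMES[family]:
            out[f"{family}_{name}"] = float(feats[name])

    assert len(out) == 102
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise RuntimeError(f"non-finite features: {bad}")
    return out
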