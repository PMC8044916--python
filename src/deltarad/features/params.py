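"""Feature-extraction parameters and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# the 13 unique 3D direction vectors at Chebyshev distance 1
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13


@dataclass(frozen=True)
class FeatureParams:
    """Settings shared by all texture families.

    bin_mode: 'count' (fixed number of bins inside the ROI) or 'width'
        (fixed bin width on the intensity axis).
    bin_value: number of bins (count mode) or bin width (width mode).
    gldm_alpha: dependence tolerance — a neighbour is dependent when its
        gray level differs from the centre by at most alpha.
    """

    bin_mode: str = "count"
    bin_value: float = 32
    gldm_alpha: int = 0
    symmetric_glcm: bool = True

    def __post_init__(self):
        if self.bin_mode not in ("count", "width"):
            raise ValueError(f"bin_mode must be 'count' or 'width', got {self.bin_mode!r}")
        if self.bin_mode == "count" and int(self.bin_value) < 2:
            raise ValueError("fixed bin count must be >= 2")
        if self.bin_mode == "width" and self.bin_value <= 0:
            raise ValueError("bin width must be positive")
        if self.gldm_alpha < 0:
            raise ValueError("gldm_alpha must be >= 0")


def discretize(values: np.ndarray, mask: np.ndarray, params: FeatureParams):
    """Map in-mask intensities to integer gray levels 1..G (0 outside the mask).

    Fixed-bin-count mode maps the in-mask minimum to level 1 and the maximum
    to level G; the mapping is monotone.  Constant regions collapse to a
    single level (G = 1), which callers treat as a flagged degenerate case.

    Returns
    -------
    levels : int array, same shape as ``values``
    n_levels : int
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(values, dtype=np.float64)
    inm = x[mask]
    lo, hi = float(inm.min()), float(inm.max())
    levels = np.zeros(x.shape, dtype=np.int64)
    if params.bin_mode == "count":
        g = int(params.bin_value)
        if hi == lo:
            levels[mask] = 1
            return levels, 1
        width = (hi - lo) / g
        lev = np.floor((x[mask] - lo) / width).astype(np.int64) + 1
        np.clip(lev, 1, g, out=lev)
        levels[mask] = lev
        return levels, g
    # fixed bin width
    w = float(params.bin_value)
    lev = np.floor(x[mask] / w).astype(np.int64)
    lev -= int(np.floor(lo / w)) - 1
    levels[mask] = lev
    return levels, int(lev.max())
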