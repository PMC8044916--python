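"""Preprocessing: bias-field correction, enhancement-frame selection and
subtraction, and spatial fuzzy C-means tumor segmentation.

The bias corrector is a log-domain smooth-field estimator: a low-order
polynomial is fitted to the logarithm of the (positivity-shifted) image
over the foreground by least squares, taken as the log of a multiplicative
bias field, and normalized to unit mean over the foreground.  Because the
fit is a linear projection the correction is idempotent.  It targets the
same smooth multiplicative shading as standard MR inhomogeneity
correctors and is deliberately small and swappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import BinaryMask, DceSeries, ImageVolume

__all__ = [
    "FcmConfig",
    "correct_bias",
    "select_enhancement_frame",
    "segment_tumor_fcm",
    "FcmResult",
]


def _poly_basis(shape, degree):
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    g = np.meshgrid(*coords, indexing="ij")
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((g[0] ** i) * (g[1] ** j) * (g[2] ** k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias(
    volume: ImageVolume, degree: int = 3
) -> tuple[ImageVolume, ImageVolume]:
    """Estimate and remove a smooth multiplicative bias field.

    Returns ``(corrected, field)`` with ``corrected = input / field``; the
    field is ``exp`` of a degree-``degree`` polynomial fitted to the log
    image over the foreground (half-mean threshold) and normalized to unit
    mean over the foreground.
    """
    x = np.asarray(volume.values, dtype=np.float64)
    if not np.any(x != 0):
        raise ValueError("all-zero volume: no bias field to estimate")
    shift = 0.0
    xmin = x.min()
    if xmin <= 0:
        shift = -xmin + 1.0
    work = x + shift
    fg = (work > 0.5 * work.mean()).ravel()

    basis = _poly_basis(volume.shape, degree)
    logi = np.log(work).ravel()
    coef, *_ = np.linalg.lstsq(basis[fg], logi[fg], rcond=None)
    log_field = basis @ coef
    log_field -= log_field[fg].mean()  # zero-mean log field over the foreground

    fld = np.exp(log_field).reshape(volume.shape)
    fld /= fld.ravel()[fg].mean()
    corrected = work / fld - shift
    return (
        volume.with_values(corrected.astype(np.float32)),
        volume.with_values(fld.astype(np.float32)),
    )


def select_enhancement_frame(
    series: DceSeries, region: BinaryMask | None = None
) -> tuple[int, ImageVolume]:
    """Pick the postcontrast frame with maximum mean enhancement and subtract S0.

    Returns ``(frame_index, frame - precontrast)``; index is into
    ``series.frames`` (so >= 1).  Ties break toward the earliest frame.
    """
    if series.n_postcontrast < 1:
        raise ValueError("series must contain at least one postcontrast frame")
    if region is not None:
        sel = region.as_bool()
        if not sel.any():
            raise ValueError("empty evaluation region")
    else:
        sel = np.ones(series.precontrast.shape, dtype=bool)
    means = [float(f.values[sel].mean()) for f in series.frames[1:]]
    idx = int(np.argmax(means)) + 1  # argmax returns the first maximum
    frame = series.frames[idx]
    sub = frame.values.astype(np.float64) - series.precontrast.values.astype(np.float64)
    return idx, frame.with_values(sub.astype(np.float32))


@dataclass(frozen=True)
class FcmConfig:
    """Spatial fuzzy C-means settings.

    ``spatial_weight`` is the exponent of the neighbourhood-membership term
    (0 reduces to plain FCM); ``neighborhood_radius`` is the half-width of
    the cubic averaging window in voxels.
    """

    n_clusters: int = 3
    fuzzifier: float = 2.0
    spatial_weight: float = 1.0
    neighborhood_radius: int = 1
    max_iterations: int = 200
    tolerance: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.fuzzifier <= 1.0:
            raise ValueError("fuzzifier must be > 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FcmResult:
    mask: BinaryMask
    memberships: np.ndarray  # (c, *shape)
    centers: np.ndarray
    n_iterations: int
    objective_trace: tuple[float, ...]
    converged: bool


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update; x flat (N,), centers (c,)."""
    d2 = (x[None, :] - centers[:, None]) ** 2
    d2 = np.maximum(d2, 1e-12)
    expo = 1.0 / (m - 1.0)
    inv = d2 ** (-expo)
    return inv / inv.sum(axis=0, keepdims=True)


def _fcm_objective(x, u, centers, m) -> float:
    d2 = (x[None, :] - centers[:, None]) ** 2
    return float((u**m * d2).sum())


def segment_tumor_fcm(
    volume: ImageVolume,
    config: FcmConfig | None = None,
    seed_point: tuple[int, int, int] | None = None,
    bounding_box: tuple[slice, slice, slice] | None = None,
) -> FcmResult:
    """Segment the enhancing tumor with spatial fuzzy C-means.

    Clustering runs on the scalar intensities (optionally inside a bounding
    box); voxel memberships of the brightest cluster above 0.5 form the
    candidate mask, restricted to the 26-connected component containing the
    seed point (or the largest component when no seed is given).

    The segmentation is invariant to affine intensity rescaling: cluster
    centers are initialized from intensity quantiles and every update is
    equivariant under ``x -> a*x + b`` (a > 0).
    """
    config = config or FcmConfig()
    region = bounding_box or tuple(slice(None) for _ in range(3))
    sub = np.asarray(volume.values, dtype=np.float64)[region]
    x = sub.ravel()
    if float(x.max() - x.min()) == 0.0:
        raise ValueError("degenerate (constant) input: clusters are undefined")

    c, mfuzz = config.n_clusters, config.fuzzifier
    centers = np.quantile(x, np.linspace(0.05, 0.95, c))
    # jitter duplicate quantile centers deterministically from the seed
    if len(np.unique(centers)) < c:
        rng = np.random.default_rng(config.seed)
        centers = centers + (x.max() - x.min()) * 1e-6 * rng.standard_normal(c)

    size = 2 * config.neighborhood_radius + 1
    trace = []
    converged = False
    u = _fcm_memberships(x, centers, mfuzz)
    it = 0
    for it in range(1, config.max_iterations + 1):
        um = u**mfuzz
        new_centers = (um @ x) / np.maximum(um.sum(axis=1), 1e-300)
        u = _fcm_memberships(x, new_centers, mfuzz)
        if config.spatial_weight > 0:
            h = np.stack(
                [
                    ndimage.uniform_filter(u[k].reshape(sub.shape), size=size).ravel()
                    for k in range(c)
                ]
            )
            uw = u * np.maximum(h, 1e-300) ** config.spatial_weight
            u = uw / uw.sum(axis=0, keepdims=True)
        trace.append(_fcm_objective(x, u, new_centers, mfuzz))
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < config.tolerance * max(1.0, float(np.abs(centers).max())):
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"spatial FCM did not converge in {config.max_iterations} iterations; "
            f"objective trace tail: {trace[-5:]}"
        )

    order = np.argsort(centers)
    tumor_k = order[-1]  # brightest cluster
    memb = u.reshape(c, *sub.shape)
    cand = memb[tumor_k] > 0.5

    full_cand = np.zeros(volume.shape, dtype=bool)
    full_cand[region] = cand
    lab, n = ndimage.label(full_cand, structure=_STRUCT26)
    if n == 0:
        raise RuntimeError("no voxel exceeded 0.5 tumor membership")
    if seed_point is not None:
        want = lab[tuple(int(v) for v in seed_point)]
        if want == 0:
            # snap to the component nearest to the seed
            pts = np.argwhere(full_cand)
            d = ((pts - np.asarray(seed_point)) ** 2).sum(axis=1)
            want = lab[tuple(pts[int(np.argmin(d))])]
        keep = lab == want
    else:
        sizes = np.bincount(lab.ravel())[1:]
        keep = lab == (int(np.argmax(sizes)) + 1)

    mask = BinaryMask(keep.astype(np.uint8), volume.spacing, volume.origin)
    return FcmResult(
        mask=mask,
        memberships=memb,
        centers=centers,
        n_iterations=it,
        objective_trace=tuple(trace),
        converged=converged,
    )
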