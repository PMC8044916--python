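"""Deformable registration and Jacobian determinant maps.

Alignment of the follow-up scan to the baseline uses multi-resolution
Gaussian-regularized demons (symmetric-forces update scheme, SimpleITK
backend).  The displacement field lives on the baseline lattice and maps
baseline coordinates to follow-up coordinates, so the Jacobian determinant
is below 1 where tissue shrank between the two time points.

The Jacobian map itself is computed in-package: per voxel, the determinant
of (identity + spatial gradient of the displacement), with central
differences taken in millimetres so anisotropic spacings are handled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .image import BinaryMask, DisplacementField, ImageVolume, JacobianMap

__all__ = [
    "RegistrationConfig",
    "ConvergenceReport",
    "register_deformable",
    "compute_jacobian_map",
    "warp",
    "summarize_jacobian",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Multi-resolution demons settings.

    ``shrink_factors`` and ``iterations`` run coarse to fine; smoothing
    scales are Gaussian standard deviations in mm applied to the update
    field and the accumulated total field.
    """

    shrink_factors: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (50, 30, 20)
    update_smoothing_mm: float = 2.0
    field_smoothing_mm: float = 1.0
    intensity_difference_threshold: float = 0.001

    def __post_init__(self):
        if len(self.shrink_factors) < 1:
            raise ValueError("need at least one pyramid level")
        if len(self.shrink_factors) != len(self.iterations):
            raise ValueError("shrink_factors and iterations must align")
        if self.update_smoothing_mm < 0 or self.field_smoothing_mm < 0:
            raise ValueError("smoothing scales must be >= 0")


@dataclass
class ConvergenceReport:
    level_metrics: list[float]  # mean-squared intensity difference after each level
    initial_metric: float
    final_metric: float
    iterations: tuple[int, ...]
    improved: bool


def _to_sitk(volume: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T.astype(np.float64)))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    return img


def _field_from_sitk(img: sitk.Image) -> np.ndarray:
    # sitk array layout: (z, y, x, 3) with components (x, y, z) in world mm;
    # our layout: (n0, n1, n2, 3) with component k along array axis k
    arr = sitk.GetArrayFromImage(img)
    return np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)))


def register_deformable(
    baseline: ImageVolume,
    followup: ImageVolume,
    config: RegistrationConfig | None = None,
) -> tuple[DisplacementField, ImageVolume, ConvergenceReport]:
    """Align the follow-up image to the baseline image.

    Returns the displacement field on the baseline lattice, the follow-up
    image warped into baseline space, and a convergence report.  If the
    similarity metric fails to improve over the identity alignment the
    report's ``improved`` flag is False but the field is still returned.
    """
    config = config or RegistrationConfig()
    if not baseline.same_lattice(followup):
        raise ValueError("baseline and follow-up must share the working lattice")

    fixed = _to_sitk(baseline)
    moving = _to_sitk(followup)

    b = np.asarray(baseline.values, dtype=np.float64)
    f = np.asarray(followup.values, dtype=np.float64)
    initial_metric = float(np.mean((b - f) ** 2))

    fld = None
    level_metrics: list[float] = []
    for shrink, n_iter in zip(config.shrink_factors, config.iterations):
        if shrink > 1:
            fixed_l = sitk.Shrink(fixed, [int(shrink)] * 3)
            moving_l = sitk.Shrink(moving, [int(shrink)] * 3)
        else:
            fixed_l, moving_l = fixed, moving
        dem = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        dem.SetNumberOfIterations(int(n_iter))
        dem.SetIntensityDifferenceThreshold(config.intensity_difference_threshold)
        dem.SetSmoothDisplacementField(config.field_smoothing_mm > 0)
        if config.field_smoothing_mm > 0:
            dem.SetStandardDeviations(config.field_smoothing_mm)
        dem.SetSmoothUpdateField(config.update_smoothing_mm > 0)
        if config.update_smoothing_mm > 0:
            dem.SetUpdateFieldStandardDeviations(config.update_smoothing_mm)
        if fld is None:
            fld = dem.Execute(fixed_l, moving_l)
        else:
            init = sitk.Resample(
                fld, fixed_l, sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64
            )
            fld = dem.Execute(fixed_l, moving_l, init)
        level_metrics.append(float(dem.GetMetric()))  # MSD at that level's resolution

    fld = sitk.Resample(fld, fixed, sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkVectorFloat64)
    disp = DisplacementField(_field_from_sitk(fld), baseline.spacing, baseline.origin)
    warped = warp(followup, disp)
    final_metric = float(np.mean((b - warped.values.astype(np.float64)) ** 2))
    report = ConvergenceReport(
        level_metrics=level_metrics,
        initial_metric=initial_metric,
        final_metric=final_metric,
        iterations=tuple(config.iterations),
        improved=final_metric < initial_metric,
    )
    return disp, warped, report


def warp(volume: ImageVolume, fld: DisplacementField, order: int = 1) -> ImageVolume:
    """Pull-back resampling: output(x) = volume(x + u(x))."""
    if volume.shape != fld.shape:
        raise ValueError("volume and field must share a lattice")
    idx = np.indices(volume.shape, dtype=np.float64)
    coords = [
        idx[k] + fld.field[..., k] / volume.spacing[k] for k in range(3)
    ]
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=np.float64), coords, order=order, mode="nearest"
    )
    return volume.with_values(out.astype(np.float32))


def compute_jacobian_map(
    fld: DisplacementField, spacing=None, clamp_epsilon: float = 1e-3
) -> JacobianMap:
    """Determinant of (I + du/dx), gradients by central differences in mm.

    An identity field gives exactly 1 everywhere.  Non-positive values mark
    a folded transformation; they are counted, reported, and clamped to
    ``clamp_epsilon`` so downstream gray-level discretization stays defined.
    """
    if spacing is None:
        spacing = fld.spacing
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))
    if len(spacing) == 1:
        spacing = spacing * 3
    if not np.allclose(spacing, fld.spacing):
        raise ValueError(
            f"stated spacing {spacing} does not match field spacing {fld.spacing}"
        )
    u = fld.field
    grad = np.empty(u.shape[:3] + (3, 3), dtype=np.float64)
    for comp in range(3):
        for ax in range(3):
            grad[..., comp, ax] = np.gradient(u[..., comp], spacing[ax], axis=ax)
    jac = grad + np.eye(3)
    det = np.linalg.det(jac)
    n_nonpos = int((det <= 0).sum())
    det = np.maximum(det, clamp_epsilon)
    vol = ImageVolume(det.astype(np.float32), spacing, fld.origin)
    return JacobianMap(volume=vol, n_nonpositive=n_nonpos)


def summarize_jacobian(jmap: JacobianMap, roi: BinaryMask) -> dict[str, float]:
    """Mean/median/SD of the Jacobian map over an ROI on the same lattice."""
    if jmap.volume.shape != roi.shape:
        raise ValueError("ROI must live on the Jacobian map's lattice")
    sel = roi.as_bool()
    if not sel.any():
        raise ValueError("empty ROI")
    v = jmap.values[sel].astype(np.float64)
    return {
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std()),
        "n_voxels": int(sel.sum()),
        "n_nonpositive": int(jmap.n_nonpositive),
    }
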