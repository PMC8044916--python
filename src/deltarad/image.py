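"""Image data model and NIfTI I/O.

All volumetric data in the package flows through :class:`ImageVolume`: a 3D
scalar lattice with physical voxel spacing (mm) and a world origin (mm).
World coordinates follow ``world = origin + index * spacing`` with 0-based
voxel indices; axis ``k`` of the value array corresponds to spacing axis
``k``.  Displacement fields are stored in millimetres on the baseline
lattice, so Jacobian computations are spacing-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "DceSeries",
    "DisplacementField",
    "JacobianMap",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "resample_volume",
    "resample_mask",
]


def _as_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(np.asarray(x, dtype=float)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar image with physical spacing and origin (both mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got {values.ndim}D")
        if values.size == 0:
            raise ValueError("ImageVolume lattice is empty")
        if not np.all(np.isfinite(values)):
            raise ValueError("ImageVolume values must be finite")
        spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", _as_triple(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        return replace(self, values=values)

    def same_lattice(self, other: "ImageVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class BinaryMask:
    """Binary ROI mask sharing the lattice of a paired :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"BinaryMask requires a 3D array, got {values.ndim}D")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        object.__setattr__(self, "values", values.astype(np.uint8))
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def num_foreground(self) -> int:
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def physical_volume(self) -> float:
        """Foreground volume in mm^3 (voxel count x voxel volume)."""
        return float(self.values.sum() * np.prod(self.spacing))


@dataclass(frozen=True)
class DceSeries:
    """Ordered DCE frames: one precontrast frame followed by postcontrast frames."""

    frames: tuple[ImageVolume, ...]
    acquisition_times: tuple[float, ...]  # seconds from injection; frame 0 precontrast

    def __post_init__(self):
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise ValueError("DceSeries needs a precontrast frame and >=1 postcontrast frame")
        if len(frames) != len(self.acquisition_times):
            raise ValueError("frames and acquisition_times length mismatch")
        for f in frames[1:]:
            if not frames[0].same_lattice(f):
                raise ValueError("all DCE frames must share one lattice")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "acquisition_times", tuple(float(t) for t in self.acquisition_times))

    @property
    def precontrast(self) -> ImageVolume:
        return self.frames[0]

    @property
    def n_postcontrast(self) -> int:
        return len(self.frames) - 1


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel displacement (mm) on the baseline lattice.

    ``field[i, j, k, c]`` is the mm displacement along axis ``c`` that maps
    baseline voxel ``(i, j, k)`` to its location in the follow-up image,
    i.e. follow-up position = baseline world position + displacement.
    """

    field: np.ndarray  # (n0, n1, n2, 3)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.field, dtype=np.float64)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"DisplacementField requires shape (n0,n1,n2,3), got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("DisplacementField components must be finite")
        object.__setattr__(self, "field", arr)
        object.__setattr__(self, "spacing", _as_triple(self.spacing))
        object.__setattr__(self, "origin", _as_triple(self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.field.shape[:3]  # type: ignore[return-value]


@dataclass(frozen=True)
class JacobianMap:
    """Unitless Jacobian determinant map of a displacement field.

    Values below 1 mark local volume shrinkage, above 1 expansion, exactly 1
    preservation.  Non-positive determinants indicate a folded field and are
    counted in ``n_nonpositive``.
    """

    volume: ImageVolume
    n_nonpositive: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume | BinaryMask, path: str | Path) -> Path:
    """Write a volume or mask to NIfTI (.nii / .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI volume; spacing/origin from the (diagonal) affine."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D payload, file {path} has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(values=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(values=(vol.values > 0.5).astype(np.uint8), spacing=vol.spacing, origin=vol.origin)


def write_field(fld: DisplacementField, path: str | Path) -> Path:
    """Write a displacement field as a 4D NIfTI with 3 components on the last axis."""
    path = Path(path)
    img = nib.Nifti1Image(fld.field.astype(np.float64), _affine(fld.spacing, fld.origin))
    nib.save(img, str(path))
    return path


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such field file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"expected a (n0,n1,n2,3) field payload, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DisplacementField(field=data, spacing=tuple(float(z) for z in zooms), origin=origin)


# ---------------------------------------------------------------------------
# Resampling


def _target_grid(volume, target_spacing):
    target_spacing = _as_triple(target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing, target_spacing)
    )
    return target_spacing, new_shape


def resample_volume(
    volume: ImageVolume, target_spacing: Sequence[float] | float, order: int = 1
) -> ImageVolume:
    """Resample onto a new lattice with the requested spacing.

    The output preserves the physical extent of the input to within one
    voxel; intensities are interpolated with the requested spline order.
    """
    target_spacing, new_shape = _target_grid(volume, target_spacing)
    if np.allclose(target_spacing, volume.spacing):
        return volume
    idx = np.indices(new_shape, dtype=np.float64)
    coords = [idx[k] * target_spacing[k] / volume.spacing[k] for k in range(3)]
    out = ndimage.map_coordinates(
        volume.values.astype(np.float64), coords, order=order, mode="nearest"
    )
    return ImageVolume(out.astype(np.float32), spacing=target_spacing, origin=volume.origin)


def resample_mask(mask: BinaryMask, target_spacing: Sequence[float] | float) -> BinaryMask:
    """Resample a mask with nearest-neighbour interpolation (values stay in {0,1})."""
    vol = ImageVolume(mask.values.astype(np.float32), mask.spacing, mask.origin)
    out = resample_volume(vol, target_spacing, order=0)
    return BinaryMask((out.values > 0.5).astype(np.uint8), out.spacing, out.origin)
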