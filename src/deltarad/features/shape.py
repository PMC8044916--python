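"""Shape descriptors of a binary ROI (14 features, intensity-free).

Volume and surface area come from a marching-cubes mesh of the mask;
axis lengths from the eigenvalues of the voxel-coordinate covariance
(physical units), scaled by 4 as for an ellipsoid's principal axes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def _mesh(mask: np.ndarray, spacing):
    from scipy.ndimage import gaussian_filter

    # slight smoothing of the binary mask suppresses the staircase surface
    # that would otherwise inflate the meshed surface area
    padded = gaussian_filter(np.pad(mask.astype(np.float64), 2), 0.5)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - 2.0 * np.asarray(spacing)  # undo the pad offset
    return verts, faces

def _mesh_volume(verts, faces) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 8:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def _boundary_coords(mask: np.ndarray, spacing) -> np.ndarray:
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    return np.argwhere(boundary) * np.asarray(spacing)


def shape_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """Compute the 14 shape descriptors of a nonempty 3D mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in np.atleast_1d(spacing))

    verts, faces = _mesh(mask, spacing)
    mesh_volume = _mesh_volume(verts, faces)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    voxel_volume = float(mask.sum() * np.prod(spacing))

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    pts = _boundary_coords(mask, spacing)
    max3d = _max_pairwise(pts)
    # in-plane maximum diameters: pairs sharing one voxel index along the fixed axis
    diam2d = []
    for axis in range(3):
        best = 0.0
        vox = np.argwhere(mask)
        for sl in np.unique(vox[:, axis]):
            plane = vox[vox[:, axis] == sl]
            keep = [k for k in range(3) if k != axis]
            p2 = plane[:, keep] * np.asarray([spacing[k] for k in keep])
            best = max(best, _max_pairwise(p2))
        diam2d.append(best)

    coords = np.argwhere(mask) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(e) for e in eig)

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": diam2d[2],
        "Maximum2DDiameterColumn": diam2d[1],
        "Maximum2DDiameterRow": diam2d[0],
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0,
        "Flatness": float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0,
    }
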