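"""Shared voxel/world coordinate helpers.

All volumes carry a NIfTI-style 4x4 affine mapping voxel indices to world
coordinates in mm. Displacements are stored in mm in the world frame.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def grid_world_coords(shape, affine) -> np.ndarray:
    """World (mm) coordinates of every voxel center, shape (*shape, 3)."""
    idx = np.indices(shape, dtype=float)  # (3, X, Y, Z)
    lin = affine[:3, :3]
    out = np.einsum("mi,i...->...m", lin, idx)
    out += affine[:3, 3]
    return out


def world_to_voxel(points: np.ndarray, affine) -> np.ndarray:
    """Map world-coordinate points (..., 3) to (fractional) voxel indices."""
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def voxel_to_world(points: np.ndarray, affine) -> np.ndarray:
    return points @ affine[:3, :3].T + affine[:3, 3]


def sample_at_world(values: np.ndarray, affine, points_world: np.ndarray,
                    order: int = 1, mode: str = "nearest", cval: float = 0.0,
                    prefilter: bool = True) -> np.ndarray:
    """Interpolate a 3-D array at world-coordinate points (..., 3)."""
    vox = world_to_voxel(points_world, affine)
    coords = np.moveaxis(vox, -1, 0)
    return map_coordinates(values, coords, order=order, mode=mode, cval=cval,
                           prefilter=prefilter)


def sample_vector_at_world(values: np.ndarray, affine, points_world: np.ndarray,
                           order: int = 1, mode: str = "nearest") -> np.ndarray:
    """Interpolate a (..., C) vector field component-wise at world points."""
    vox = world_to_voxel(points_world, affine)
    coords = np.moveaxis(vox, -1, 0)
    comps = [map_coordinates(values[..., c], coords, order=order, mode=mode)
             for c in range(values.shape[-1])]
    return np.stack(comps, axis=-1)


def voxel_sizes(affine) -> np.ndarray:
    """Per-axis voxel edge length in mm."""
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
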