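"""Edema-corrected lesion volumetry in atlas space.

Expressing the T2-hyperintense lesion as a percentage of the hemisphere
volume, with both masks on the same atlas grid, removes the bias that
vasogenic edema introduces into absolute lesion volumes at 24 h after
stroke.  Because numerator and denominator live on the same grid the ratio
uses voxel counts and is independent of voxel size.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "hemisphere_masks",
    "edema_corrected_lesion_percent",
    "mask_volume_mm3",
]


def hemisphere_masks(
    grid_shape: Sequence[int],
    midline_index: int,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the grid at the midsagittal plane into (left, right) masks.

    The left mask contains voxel indices ``< midline_index`` along ``axis``;
    the two masks are disjoint and together cover the grid.  The midline must
    leave both halves non-empty.
    """
    shape = tuple(int(s) for s in grid_shape)
    if axis not in range(len(shape)):
        raise ValueError(f"axis {axis} invalid for shape {shape}")
    if not (0 < midline_index < shape[axis]):
        raise ValueError(
            f"midline index {midline_index} outside grid axis of size {shape[axis]}"
        )
    coords = np.arange(shape[axis]).reshape(
        [-1 if i == axis else 1 for i in range(len(shape))]
    )
    left = np.broadcast_to(coords < midline_index, shape).copy()
    return left, ~left


def edema_corrected_lesion_percent(
    lesion_mask: np.ndarray,
    hemisphere_mask: np.ndarray,
) -> float:
    """Lesion volume as percent of hemisphere volume (voxel counts).

    The lesion must lie entirely within the hemisphere: stray voxels indicate
    a registration or delineation problem and raise an error reporting their
    count rather than silently producing a ratio above 100%.
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    hemi = np.asarray(hemisphere_mask, dtype=bool)
    if lesion.shape != hemi.shape:
        raise ValueError(f"mask shapes differ: {lesion.shape} vs {hemi.shape}")
    n_hemi = int(hemi.sum())
    if n_hemi == 0:
        raise ValueError("hemisphere mask is empty")
    outside = int((lesion & ~hemi).sum())
    if outside:
        raise ValueError(f"{outside} lesion voxels lie outside the hemisphere mask")
    return 100.0 * int(lesion.sum()) / n_hemi


def mask_volume_mm3(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """Absolute volume of a binary mask in mm^3 from the voxel edge lengths."""
    voxel = float(np.prod(np.asarray(voxel_size, dtype=float)))
    if voxel <= 0:
        raise ValueError("voxel size must be positive")
    return float(np.asarray(mask, dtype=bool).sum()) * voxel
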