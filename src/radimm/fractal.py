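"""3D box-counting fractal dimension and threshold-averaged fractality.

The box-counting dimension of a binary 3D set is the least-squares slope
of log N(s) against log(1/s), where N(s) counts the s×s×s boxes of a grid
partition of the set's bounding box that contain at least one foreground
voxel. The "fractality" texture feature extends this to grayscale ROIs by
binarizing the masked intensities at several equally spaced thresholds
between the ROI minimum and maximum (endpoints excluded) and averaging the
dimension over the nonempty level sets: rough, spatially complex signal
produces level sets with higher average dimension than smooth signal.
"""

from __future__ import annotations

import numpy as np

DEFAULT_N_THRESHOLDS = 9


def default_box_sizes(bbox_shape: tuple[int, ...]) -> list[int]:
    """Powers of 2 from 1 up to half the bounding box's shortest side.

    Thin boxes (shortest side < 4) fall back to sizes [1, 2] so that a
    slope is always defined.
    """
    shortest = min(bbox_shape)
    sizes = [1]
    s = 2
    while s <= shortest / 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        sizes = [1, 2]
    return sizes


def _bbox_slices(mask: np.ndarray) -> tuple[slice, ...]:
    """Bounding-box slices from per-axis any-projections (cheap)."""
    slices = []
    for ax in range(mask.ndim):
        other = tuple(a for a in range(mask.ndim) if a != ax)
        proj = np.flatnonzero(mask.any(axis=other))
        slices.append(slice(int(proj[0]), int(proj[-1]) + 1))
    return tuple(slices)


def _crop_to_bbox(mask: np.ndarray) -> np.ndarray:
    return mask[_bbox_slices(mask)]


def _count_cropped(crop: np.ndarray, size: int) -> int:
    """Occupied boxes of a mask already cropped to its bounding box."""
    if size == 1:
        return int(crop.sum())
    pad = [(0, (-d) % size) for d in crop.shape]
    if any(p[1] for p in pad):
        crop = np.pad(crop, pad)
    nx, ny, nz = (d // size for d in crop.shape)
    blocks = crop.reshape(nx, size, ny, size, nz, size)
    return int(blocks.any(axis=(1, 3, 5)).sum())


def box_count(mask: np.ndarray, size: int) -> int:
    """Number of occupied size³ boxes tiling the mask's bounding box.

    The partition is anchored at the bounding box's minimal corner; the
    grid is padded (with background) up to a multiple of ``size``.
    """
    if size < 1:
        raise ValueError(f"box size must be >= 1, got {size}")
    return _count_cropped(_crop_to_bbox(np.asarray(mask).astype(bool)), size)


def fractal_dimension_mask(mask: np.ndarray, box_sizes: list[int] | None = None) -> float:
    """Box-counting dimension of a binary mask.

    Returns the least-squares slope of log N(s) vs log(1/s) over the given
    (or default) box sizes, clipped to the admissible range [0, 3].
    Returns NaN for an empty mask; a single box size is an error.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return float("nan")
    crop = _crop_to_bbox(mask)
    if box_sizes is None:
        box_sizes = default_box_sizes(crop.shape)
    sizes = sorted(set(int(s) for s in box_sizes))
    if len(sizes) < 2:
        raise ValueError(f"need at least 2 distinct box sizes, got {sizes}")
    counts = np.array([_count_cropped(crop, s) for s in sizes], dtype=np.float64)
    x = np.log(1.0 / np.array(sizes, dtype=np.float64))
    y = np.log(counts)
    slope = np.polyfit(x, y, 1)[0]
    return float(np.clip(slope, 0.0, 3.0))


def fractality(
    data: np.ndarray,
    mask: np.ndarray,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    box_sizes: list[int] | None = None,
) -> float:
    """Threshold-averaged box-counting dimension of a grayscale ROI.

    Binarizes the masked intensities at ``n_thresholds`` equally spaced
    levels strictly between the ROI's intensity minimum and maximum and
    averages ``fractal_dimension_mask`` over the nonempty level sets
    (voxels with intensity >= level, within the ROI). A constant-intensity
    ROI falls back to the dimension of the ROI mask itself. Returns NaN
    for an empty mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return float("nan")
    if n_thresholds < 1:
        raise ValueError(f"n_thresholds must be >= 1, got {n_thresholds}")
    # work on the ROI bounding box only: level sets are subsets of the ROI
    roi_slices = _bbox_slices(mask)
    mask_c = mask[roi_slices]
    data_c = np.asarray(data, dtype=np.float64)[roi_slices]
    vals = data_c[mask_c]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        return fractal_dimension_mask(mask_c, box_sizes)
    levels = lo + (hi - lo) * np.arange(1, n_thresholds + 1) / (n_thresholds + 1)
    dims = []
    for level in levels:
        level_set = mask_c & (data_c >= level)
        if level_set.any():
            dims.append(fractal_dimension_mask(level_set, box_sizes))
    # endpoints are excluded, so the lowest level set is always nonempty
    return float(np.mean(dims))
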