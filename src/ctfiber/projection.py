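"""Depth-coded X-ray projections and plane slices for visual inspection.

A depth-coded projection collapses the mask along one axis: each foreground
voxel contributes the colormap colour of its normalised depth, overlapping
colours are averaged, and pixel brightness scales with the column's
foreground count relative to the image-wide maximum (one global scale, so
projections of different volumes remain comparable).
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .volume_io import RGBVolume, Volume3D

__all__ = ["depth_xray", "slice_image", "save_png"]

_PLANES = {"axial": 2, "coronal": 1, "sagittal": 0}


def depth_xray(mask: Volume3D, axis: int = 1, colormap: str = "viridis") -> np.ndarray:
    """Colour projection of a binary mask along ``axis``; returns (H, W, 3) uint8.

    Pixel colour is the mean of colormap(depth/(D-1)) over the column's
    foreground voxels; brightness is scaled by foreground count / maximum
    count.  Empty columns (and an empty mask) are black.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    fg = (np.asarray(mask.values) > 0).astype(np.float64)
    fg = np.moveaxis(fg, axis, -1)  # (H, W, D)
    depth = fg.shape[-1]
    positions = np.linspace(0.0, 1.0, depth) if depth > 1 else np.zeros(1)
    cmap = colormaps[colormap]
    colors = cmap(positions)[:, :3]  # (D, 3)

    counts = fg.sum(axis=-1)  # (H, W)
    summed = fg @ colors  # (H, W, 3)
    img = np.zeros_like(summed)
    nz = counts > 0
    img[nz] = summed[nz] / counts[nz, None]
    max_count = counts.max(initial=0)
    if max_count > 0:
        img *= (counts / max_count)[..., None]
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def slice_image(vol, plane: str = "axial", index: int = 0) -> np.ndarray:
    """Extract one plane as a 2D image (RGB passthrough, scalar -> greyscale).

    Planes: sagittal = fixed x, coronal = fixed y, axial = fixed z.  The
    returned image is transposed so the volume's z axis (superior) runs up
    for sagittal/coronal slices.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    axis = _PLANES[plane]
    values = np.asarray(vol.values)
    shape3 = values.shape[:3]
    if not (0 <= index < shape3[axis]):
        raise IndexError(f"slice index {index} out of range [0, {shape3[axis]}) for {plane}")
    sl = np.take(values, index, axis=axis)
    if isinstance(vol, RGBVolume):
        img = sl
    else:
        sl = sl.astype(np.float64)
        vmax = sl.max(initial=0)
        grey = (sl / vmax * 255.0) if vmax > 0 else sl
        img = np.clip(np.rint(grey), 0, 255).astype(np.uint8)
    if plane in ("sagittal", "coronal"):
        # put z (superior) up: rows = reversed z, columns = remaining axis
        img = img.swapaxes(0, 1)[::-1]
    else:
        img = img.swapaxes(0, 1)
    return np.ascontiguousarray(img)


def save_png(image: np.ndarray, path: str) -> str:
    import imageio.v3 as iio

    iio.imwrite(path, image)
    return path
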