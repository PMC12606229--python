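"""Isometric binning of anisotropic voxel stacks.

Cryo-section stacks have fine in-plane resolution and coarse cutting
thickness; direction-unbiased ray casting needs cubic voxels.  Binning sums
source voxels into target voxels, producing *count* volumes: each output
value counts the (possibly fractional, then rounded) number of foreground
source voxels falling inside it.  The count sum is conserved — exactly when
the target spacing is an integer multiple of every source spacing, to within
one count otherwise.
"""

from __future__ import annotations

import numpy as np

from .volume_io import Volume3D

__all__ = ["isometric_bin"]

_COUNT_DTYPE = np.uint16


def _axis_overlap_weights(n_in: int, ratio: float) -> np.ndarray:
    """Overlap lengths (in source-voxel units) between output and input cells.

    Output cell o spans [o*ratio, (o+1)*ratio) on an axis measured in source
    voxel widths; entry [o, i] is the length of its overlap with source cell
    [i, i+1).  Rows sum to ratio (except a trailing partial cell), columns
    sum to 1, so the product of the three axis matrices conserves mass.
    """
    n_out = int(np.ceil(n_in / ratio - 1e-9))
    w = np.zeros((n_out, n_in))
    for o in range(n_out):
        lo, hi = o * ratio, min((o + 1) * ratio, n_in)
        i0, i1 = int(np.floor(lo + 1e-12)), int(np.ceil(hi - 1e-12))
        for i in range(i0, min(i1, n_in)):
            w[o, i] = min(hi, i + 1) - max(lo, i)
    return w


def _carry_round(flat: np.ndarray) -> np.ndarray:
    """Deterministic rounding that conserves the running sum.

    Rounds the cumulative sum half-up and differences it, so every element
    is within one count of its exact value and the total is conserved to
    within half a count — a plain per-element rounding of a uniform
    fractional density would bias the total.
    """
    cum = np.floor(np.cumsum(flat) + 0.5)
    out = np.diff(cum, prepend=0.0)
    return out


def isometric_bin(vol: Volume3D, target_spacing: float) -> Volume3D:
    """Downsample a binary/count volume to cubic voxels of edge ``target_spacing``.

    Integer spacing ratios use exact non-overlapping block summation
    (summative binning).  Non-integer ratios distribute each source voxel's
    value over the output voxels it geometrically overlaps, then round to
    integer counts with a sum-conserving carry.  Upsampling is refused.
    """
    t = float(target_spacing)
    if t <= 0:
        raise ValueError("target spacing must be positive")
    values = np.asarray(vol.values)
    if np.issubdtype(values.dtype, np.floating):
        if not np.allclose(values, np.rint(values)):
            raise ValueError("isometric_bin expects integer (binary or count) values")
        values = np.rint(values).astype(np.int64)
    ratios = [t / s for s in vol.spacing]
    for r, s in zip(ratios, vol.spacing):
        if r < 1.0 - 1e-9:
            raise ValueError(
                f"target spacing {t} mm is finer than source spacing {s} mm; "
                "only downsampling is supported"
            )
    int_ratios = [int(round(r)) for r in ratios]
    is_integer = all(abs(r - ir) <= 1e-9 * r for r, ir in zip(ratios, int_ratios))

    if is_integer:
        counts = _block_sum(values, int_ratios)
        exact = True
    else:
        wx = _axis_overlap_weights(values.shape[0], ratios[0])
        wy = _axis_overlap_weights(values.shape[1], ratios[1])
        wz = _axis_overlap_weights(values.shape[2], ratios[2])
        dense = np.einsum("oi,pj,qk,ijk->opq", wx, wy, wz, values.astype(np.float64))
        counts = _carry_round(dense.ravel()).reshape(dense.shape)
        exact = False

    if counts.max(initial=0) > np.iinfo(_COUNT_DTYPE).max:
        raise OverflowError(
            f"bin count {int(counts.max())} exceeds the uint16 range; "
            "use a smaller spacing ratio"
        )
    if counts.min(initial=0) < 0:
        raise ValueError("negative count produced; input values must be non-negative")
    out = Volume3D(counts.astype(_COUNT_DTYPE), (t, t, t), vol.origin)
    if exact and out.values.sum(dtype=np.int64) != values.sum(dtype=np.int64):
        raise AssertionError("count conservation violated in integer binning")
    return out


def _block_sum(values: np.ndarray, factors: list[int]) -> np.ndarray:
    """Sum non-overlapping blocks; trailing partial blocks are zero-padded."""
    padded_shape = [int(np.ceil(n / f)) * f for n, f in zip(values.shape, factors)]
    if tuple(padded_shape) != values.shape:
        pad = [(0, p - n) for p, n in zip(padded_shape, values.shape)]
        values = np.pad(values, pad)
    fx, fy, fz = factors
    nx, ny, nz = (p // f for p, f in zip(padded_shape, factors))
    v = values.reshape(nx, fx, ny, fy, nz, fz)
    return v.sum(axis=(1, 3, 5), dtype=np.int64)
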