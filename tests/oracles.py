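"""Independent brute-force oracles used to cross-check the vectorised code.

These deliberately re-derive results with naive per-voxel loops (and no
shared code with the package internals beyond the direction-set container),
so agreement is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np


def naive_run(values: np.ndarray, start, g, cap: int) -> int:
    """Walk voxel by voxel along g, counting consecutive foreground steps.

    Background stops the walk; out-of-grid samples replicate the nearest
    in-grid voxel (the crop-boundary convention).
    """
    x, y, z = (int(v) for v in start)
    run = 0
    for _ in range(cap):
        x, y, z = x + g[0], y + g[1], z + g[2]
        cx = min(max(x, 0), values.shape[0] - 1)
        cy = min(max(y, 0), values.shape[1] - 1)
        cz = min(max(z, 0), values.shape[2] - 1)
        if values[cx, cy, cz] == 0:
            break
        run += 1
    return run


def naive_thickness(values: np.ndarray, generators, cap: int, s: float) -> np.ndarray:
    """Per-voxel minimum chord over the axis set, triple loop."""
    out = np.zeros(values.shape, dtype=np.float64)
    gens = [tuple(int(v) for v in g) for g in generators]
    norms = [float(np.linalg.norm(g)) for g in gens]
    for idx in np.argwhere(values > 0):
        start = tuple(idx)
        best = np.inf
        for g, norm in zip(gens, norms):
            neg = (-g[0], -g[1], -g[2])
            chord = (naive_run(values, start, g, cap) + naive_run(values, start, neg, cap) + 1) * norm * s
            if chord < best:
                best = chord
        out[start] = best
    return out


def naive_orientation_tensor(values: np.ndarray, voxel, generators, cap: int) -> np.ndarray:
    """A = sum_i r_i^2 d_i d_i^T evaluated with explicit loops."""
    A = np.zeros((3, 3))
    for g in generators:
        g = tuple(int(v) for v in g)
        r = 1 + naive_run(values, voxel, g, cap)
        d = np.asarray(g, dtype=float) / np.linalg.norm(g)
        A += (r * r) * np.outer(d, d)
    return A


def ball_lattice_count(center, radius: float, shape) -> int:
    """Number of integer lattice points of the grid inside the ball."""
    count = 0
    cx, cy, cz = center
    r2 = radius * radius
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r2:
                    count += 1
    return count


def overlap_bin_oracle(values: np.ndarray, spacing, target: float) -> np.ndarray:
    """Exact (pre-rounding) geometric overlap binning, brute force."""
    ratios = [target / s for s in spacing]
    out_shape = [int(np.ceil(n / r - 1e-9)) for n, r in zip(values.shape, ratios)]
    out = np.zeros(out_shape)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                v = values[i, j, k]
                if v == 0:
                    continue
                # distribute the source cell [i,i+1)x... over overlapped targets
                for oi, wi in _cell_overlaps(i, ratios[0], out_shape[0]):
                    for oj, wj in _cell_overlaps(j, ratios[1], out_shape[1]):
                        for ok, wk in _cell_overlaps(k, ratios[2], out_shape[2]):
                            out[oi, oj, ok] += v * wi * wj * wk
    return out


def _cell_overlaps(i: int, ratio: float, n_out: int):
    o0 = int(np.floor(i / ratio))
    o1 = min(int(np.floor((i + 1) / ratio - 1e-12)), n_out - 1)
    for o in range(o0, o1 + 1):
        lo = max(i, o * ratio)
        hi = min(i + 1, (o + 1) * ratio)
        if hi > lo:
            yield o, hi - lo
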