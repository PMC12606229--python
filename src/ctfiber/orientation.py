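"""Dyadic orientation tensors, Westin measures, structural classification.

At each connective-tissue voxel, rays are cast along every direction of an
unreduced lattice direction set (both signs of every axis, so each voxel
sees the same number of orientations).  Ray i yields a scan vector
x_i = r_i * d_i, where d_i is the unit direction and r_i counts the centre
voxel plus the capped foreground run length.  The local second-moment
(orientation) tensor is the dyadic sum

    A = sum_i x_i (x) x_i = sum_i r_i^2 d_i d_i^T,

a symmetric positive-semidefinite 3x3 matrix whose eigenvectors are the
principal material axes and whose eigenvalue contrasts quantify anisotropy.
The sum-normalised Westin measures

    c_l = (l1 - l2)/S,   c_p = 2(l2 - l3)/S,   c_s = 3 l3/S,   S = l1+l2+l3

form a partition of unity (c_l + c_p + c_s = 1) mapping directly to RGB:
fibrous structures (one dominant axis, e.g. tendon) are c_l-heavy, planar
structures (two strong axes, e.g. fascia sheets) c_p-heavy, and spatially
homogeneous collections c_s-heavy.  The default scan range is 16 voxels,
so structures larger than the scan window read as spherical.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .thickness import DirectionSet, lattice_directions, run_length_field
from .volume_io import RGBVolume, TensorVolume, Volume3D

__all__ = [
    "TensorEigenSystem",
    "WestinTriple",
    "StructureClass",
    "orientation_tensor",
    "tensor_field",
    "eigensystem",
    "eigensystem_field",
    "westin_measures",
    "westin_field",
    "classify_structure",
    "classify_field",
    "encode_tensor_rgb",
]


class StructureClass(IntEnum):
    """Structural character of the local connective tissue."""

    UNCLASSIFIED = 0
    FIBROUS = 1
    PLANAR = 2
    SPHERICAL = 3


@dataclass(frozen=True)
class TensorEigenSystem:
    """Descending eigenvalues with orthonormal eigenvectors (columns)."""

    eigenvalues: np.ndarray  # (3,) l1 >= l2 >= l3 >= 0
    eigenvectors: np.ndarray  # (3, 3), column i pairs with eigenvalue i

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def e2(self) -> np.ndarray:
        return self.eigenvectors[:, 1]

    @property
    def e3(self) -> np.ndarray:
        return self.eigenvectors[:, 2]


@dataclass(frozen=True)
class WestinTriple:
    c_l: float
    c_p: float
    c_s: float

    @property
    def is_sentinel(self) -> bool:
        return self.c_l == 0.0 and self.c_p == 0.0 and self.c_s == 0.0


def _ray_counts(mask: Volume3D, directions: DirectionSet, cap: int) -> np.ndarray:
    """r_i = 1 + run length for every voxel and direction; shape (n, *grid)."""
    if directions.antipodal_reduced:
        raise ValueError("orientation tensors need an unreduced direction set")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    runs = [run_length_field(mask, g, cap) for g in directions.generators]
    return np.stack(runs, axis=0) + 1


def orientation_tensor(
    mask: Volume3D,
    voxel,
    directions: DirectionSet | None = None,
    cap: int = 16,
) -> np.ndarray:
    """Dyadic orientation tensor A = sum r_i^2 d_i d_i^T at one voxel."""
    if directions is None:
        directions = lattice_directions(2, antipodal_reduced=False)
    if directions.antipodal_reduced:
        raise ValueError("orientation tensors need an unreduced direction set")
    values = np.asarray(mask.values)
    voxel = tuple(int(x) for x in voxel)
    if not values[voxel]:
        raise ValueError(f"voxel {voxel} is background; tensors are defined on tissue")
    from .thickness import ray_run_length

    units = directions.units
    A = np.zeros((3, 3))
    for g, d in zip(directions.generators, units):
        r = 1 + ray_run_length(mask, voxel, g, cap)
        A += (r * r) * np.outer(d, d)
    return A


_PAIR_IDX = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


def _ray_mode_components(mask, directions, cap, fg):
    """Six tensor components of sum_i r_i^2 d_i d_i^T for every voxel."""
    r = _ray_counts(mask, directions, cap).astype(np.float64)  # (n, X, Y, Z)
    w = r * r
    units = directions.units  # (n, 3)
    comps = np.empty(mask.shape + (6,), dtype=np.float64)
    for c, (a, b) in enumerate(_PAIR_IDX):
        coeff = units[:, a] * units[:, b]  # (n,)
        comps[..., c] = np.tensordot(coeff, w, axes=(0, 0))
    comps[~fg] = 0.0
    return comps


def _neighborhood_mode_components(mask, directions, cap, fg, radius):
    """Aggregate each voxel's single best-chord direction over a box window.

    Every tissue voxel contributes one vector x = chord * d along the axis
    with the longest bidirectional chord (ties -> first axis in the
    deterministic lattice order); the tensor at a voxel is the dyadic sum of
    the vectors of all tissue voxels in the (2*radius+1)^3 window, truncated
    at the grid crop.
    """
    from scipy import ndimage

    axes = directions
    if not axes.antipodal_reduced:
        # chords are sign-symmetric: one representative per +/- pair suffices
        gens = axes.generators
        keep = []
        seen = set()
        for i, g in enumerate(gens):
            key = max(tuple(g), tuple(-g))
            if key not in seen:
                seen.add(key)
                keep.append(i)
        axes = DirectionSet(gens[keep], antipodal_reduced=True)
    best_chord = np.zeros(mask.shape)
    best_idx = np.zeros(mask.shape, dtype=np.int32)
    for i, (g, norm) in enumerate(zip(axes.generators, axes.norms)):
        chord = (
            run_length_field(mask, g, cap) + run_length_field(mask, -g, cap) + 1
        ).astype(np.float64) * norm
        upd = chord > best_chord
        best_chord[upd] = chord[upd]
        best_idx[upd] = i
    d = axes.units[best_idx]  # (X, Y, Z, 3)
    x = best_chord[..., None] * d
    comps = np.empty(mask.shape + (6,), dtype=np.float64)
    for c, (a, b) in enumerate(_PAIR_IDX):
        comps[..., c] = x[..., a] * x[..., b]
    comps[~fg] = 0.0
    size = 2 * radius + 1
    for c in range(6):
        comps[..., c] = ndimage.uniform_filter(
            comps[..., c], size=size, mode="constant", cval=0.0
        ) * float(size**3)
    comps[~fg] = 0.0
    return comps


def tensor_field(
    mask: Volume3D,
    directions: DirectionSet | None = None,
    cap: int = 16,
    output_bin: int = 1,
    mode: str = "rays",
    neighborhood_radius: int = 2,
) -> TensorVolume:
    """Per-voxel orientation tensors, optionally block-averaged.

    The default "rays" mode forms each voxel's tensor from its own
    run-length-weighted scan vectors (every voxel sees the same number of
    orientations).  The alternative "neighborhood" mode follows the
    fascicle-tracing tradition instead: each voxel contributes one
    best-chord direction vector, and tensors aggregate those vectors over a
    box window of ``neighborhood_radius``.  Tensors are computed on the full
    isometric grid, then averaged over ``output_bin``-cubed blocks (mean
    over the foreground member tensors; blocks without tissue get the zero
    tensor).  Output spacing is the input spacing times ``output_bin`` —
    whole-body deposits use bin 2.
    """
    if directions is None:
        directions = lattice_directions(2, antipodal_reduced=False)
    if not mask.is_isometric():
        raise ValueError(f"tensor_field requires isometric spacing, got {mask.spacing}")
    if output_bin < 1:
        raise ValueError("output_bin must be >= 1")
    fg = np.asarray(mask.values) > 0
    if mode == "rays":
        comps = _ray_mode_components(mask, directions, cap, fg)
    elif mode == "neighborhood":
        comps = _neighborhood_mode_components(
            mask, directions, cap, fg, neighborhood_radius
        )
    else:
        raise ValueError(f"unknown tensor mode {mode!r}; use 'rays' or 'neighborhood'")

    if output_bin == 1:
        out = comps
        counts = fg
        spacing = mask.spacing
    else:
        b = output_bin
        shape = mask.shape
        padded = [int(np.ceil(n / b)) * b for n in shape]
        pad = [(0, p - n) for p, n in zip(padded, shape)] + [(0, 0)]
        comps_p = np.pad(comps, pad)
        fg_p = np.pad(fg, [(0, p - n) for p, n in zip(padded, shape)])
        nx, ny, nz = (p // b for p in padded)
        sums = comps_p.reshape(nx, b, ny, b, nz, b, 6).sum(axis=(1, 3, 5))
        counts = fg_p.reshape(nx, b, ny, b, nz, b).sum(axis=(1, 3, 5))
        out = np.zeros_like(sums)
        nonzero = counts > 0
        out[nonzero] = sums[nonzero] / counts[nonzero, None]
        spacing = tuple(s * b for s in mask.spacing)
    return TensorVolume(out.astype(np.float32), spacing)


def eigensystem(A: np.ndarray, tol: float = 1e-9) -> TensorEigenSystem:
    """Eigendecomposition of a symmetric 3x3 tensor, sorted descending.

    Negative eigenvalues within -tol*l1 (numerical noise on PSD dyadic
    sums) are clamped to zero.  Eigenvector signs: largest-magnitude
    component positive for e1 and e2; e3 = e1 x e2 so the frame is
    right-handed.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if not np.allclose(A, A.T, atol=1e-9 * max(1.0, float(np.abs(A).max()))):
        raise ValueError("tensor is not symmetric")
    w, v = np.linalg.eigh(A)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    clamp = tol * max(w[0], 0.0)
    w = np.where(w < 0, np.where(w >= -clamp, 0.0, w), w)
    if w[2] < 0:
        raise ValueError(f"tensor is not positive semidefinite (l3 = {w[2]:g})")
    for i in (0, 1):
        col = v[:, i]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            v[:, i] = -col
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return TensorEigenSystem(w, v)


def eigensystem_field(field: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised eigendecomposition of every tensor in a field.

    Returns (eigenvalues, eigenvectors) of shapes (..., 3) and (..., 3, 3)
    with the same ordering and sign conventions as :func:`eigensystem`.
    Zero tensors yield zero eigenvalues with the identity frame.
    """
    m = field.as_matrices().astype(np.float64)
    w, v = np.linalg.eigh(m.reshape(-1, 3, 3))
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    w = np.where(w < 0, np.where(w >= -1e-9 * np.maximum(w[:, :1], 1e-300), 0.0, w), w)
    # sign convention on e1, e2; right-handed e3
    for i in (0, 1):
        col = v[:, :, i]
        j = np.argmax(np.abs(col), axis=1)
        sign = np.sign(col[np.arange(len(col)), j])
        sign[sign == 0] = 1.0
        v[:, :, i] = col * sign[:, None]
    v[:, :, 2] = np.cross(v[:, :, 0], v[:, :, 1])
    shape = field.shape
    return w.reshape(shape + (3,)), v.reshape(shape + (3, 3))


def westin_measures(eig: TensorEigenSystem | np.ndarray) -> WestinTriple:
    """Sum-normalised Westin linear/planar/spherical measures.

    A zero-trace tensor has no orientation content; it maps to the
    all-zero sentinel triple, which classifies as unclassified.
    """
    w = eig.eigenvalues if isinstance(eig, TensorEigenSystem) else np.asarray(eig)
    l1, l2, l3 = (float(x) for x in w)
    s = l1 + l2 + l3
    if s <= 0:
        return WestinTriple(0.0, 0.0, 0.0)
    return WestinTriple((l1 - l2) / s, 2.0 * (l2 - l3) / s, 3.0 * l3 / s)


def westin_field(eigenvalues: np.ndarray) -> np.ndarray:
    """Vectorised Westin triples from an (..., 3) eigenvalue array."""
    l1, l2, l3 = np.moveaxis(eigenvalues, -1, 0)
    s = l1 + l2 + l3
    out = np.zeros(eigenvalues.shape[:-1] + (3,))
    nz = s > 0
    out[nz, 0] = (l1[nz] - l2[nz]) / s[nz]
    out[nz, 1] = 2.0 * (l2[nz] - l3[nz]) / s[nz]
    out[nz, 2] = 3.0 * l3[nz] / s[nz]
    return out


def classify_structure(w: WestinTriple, threshold: float = 0.0) -> StructureClass:
    """Argmax classification with an optional dominance threshold.

    Ties break fibrous > planar > spherical; the zero sentinel and any
    triple whose maximum falls below ``threshold`` are unclassified.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    if w.is_sentinel:
        return StructureClass.UNCLASSIFIED
    triple = (w.c_l, w.c_p, w.c_s)
    best = max(triple)
    if best < threshold:
        return StructureClass.UNCLASSIFIED
    for value, cls in zip(
        triple, (StructureClass.FIBROUS, StructureClass.PLANAR, StructureClass.SPHERICAL)
    ):
        if value == best:
            return cls
    raise AssertionError("unreachable")


def classify_field(westin: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Vectorised :func:`classify_structure` on an (..., 3) Westin array."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    best = westin.max(axis=-1)
    cls = np.argmax(westin, axis=-1).astype(np.uint8) + 1  # ties -> lowest index
    cls[best < threshold] = 0
    cls[np.all(westin == 0, axis=-1)] = 0
    return cls


def _round_half_up_255(x: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(x * 255.0 + 0.5), 0, 255).astype(np.uint8)


def encode_tensor_rgb(
    field: TensorVolume, mode: str, threshold: float = 0.0
) -> RGBVolume:
    """Colour-code a tensor field.

    mode "e1"/"e2": absolute principal/secondary eigenvector components;
    mode "westin": (c_l, c_p, c_s) as red/green/blue; mode "rank": class
    colours red = fibrous, green = planar, blue = spherical, black =
    unclassified.  Zero tensors render black in every mode.
    """
    if mode not in ("e1", "e2", "westin", "rank"):
        raise ValueError(f"unknown encode mode {mode!r}")
    eigvals, eigvecs = eigensystem_field(field)
    nonzero = eigvals.sum(axis=-1) > 0
    if mode in ("e1", "e2"):
        k = 0 if mode == "e1" else 1
        rgb = _round_half_up_255(np.abs(eigvecs[..., :, k]))
        rgb[~nonzero] = 0
    elif mode == "westin":
        rgb = _round_half_up_255(westin_field(eigvals))
        rgb[~nonzero] = 0
    else:
        cls = classify_field(westin_field(eigvals), threshold)
        palette = np.array(
            [[0, 0, 0], [255, 0, 0], [0, 255, 0], [0, 0, 255]], dtype=np.uint8
        )
        rgb = palette[cls]
    return RGBVolume(rgb, field.spacing)
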