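"""Synthetic tissue phantoms with exactly known geometry.

Every pipeline stage is validated against volumes whose ground truth is known
by construction: slabs (sheet-like fascia analogues), cylinders (tendon/fibre
analogues), balls and cuboids (bulk isotropic regions).  A voxel is foreground
iff its *centre* lies inside at least one primitive, so foreground counts are
integer-exact against enumeration oracles.  All stochastic operations take an
explicit seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import LabelVolume, RGBVolume, Volume3D

__all__ = [
    "Primitive",
    "PhantomSpec",
    "make_phantom",
    "corrupt_mask",
    "colorize_phantom",
]

_KINDS = ("slab", "cylinder", "ball", "cuboid")


@dataclass
class Primitive:
    """One geometric primitive, parameters in voxel units.

    kind = "slab":     params axis (0/1/2), center (along axis), thickness
    kind = "cylinder": params axis, center (2-tuple in the orthogonal plane),
                       radius, optional extent (lo, hi) along the axis
    kind = "ball":     params center (3-tuple), radius
    kind = "cuboid":   params lo (3-tuple), hi (3-tuple), inclusive bounds
    """

    kind: str
    params: dict
    class_id: int = 1

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown primitive kind {self.kind!r}; expected one of {_KINDS}")
        if self.class_id < 1:
            raise ValueError("class_id must be a positive integer")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    primitives: list[Primitive] = field(default_factory=list)
    noise_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.noise_flip_rate < 0.5):
            raise ValueError("noise flip rate must lie in [0, 0.5)")


def _primitive_mask(prim: Primitive, shape) -> np.ndarray:
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", sparse=True
    )
    coords = (x, y, z)
    p = prim.params
    if prim.kind == "slab":
        axis, c, t = int(p["axis"]), float(p["center"]), float(p["thickness"])
        return np.abs(coords[axis] - c) <= t / 2.0 + np.zeros(shape, bool)
    if prim.kind == "cylinder":
        axis = int(p["axis"])
        cu, cv = (float(v) for v in p["center"])
        r = float(p["radius"])
        u_ax, v_ax = [a for a in range(3) if a != axis]
        d2 = (coords[u_ax] - cu) ** 2 + (coords[v_ax] - cv) ** 2
        inside = d2 <= r * r
        if "extent" in p and p["extent"] is not None:
            lo, hi = p["extent"]
            inside = inside & (coords[axis] >= lo) & (coords[axis] <= hi)
        return inside + np.zeros(shape, bool)
    if prim.kind == "ball":
        cx, cy, cz = (float(v) for v in p["center"])
        r = float(p["radius"])
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return (d2 <= r * r) + np.zeros(shape, bool)
    # cuboid
    lo = p["lo"]
    hi = p["hi"]
    out = np.ones(shape, bool)
    for a in range(3):
        out &= (coords[a] >= lo[a]) & (coords[a] <= hi[a])
    return out


def _check_fits(prim: Primitive, shape) -> None:
    p = prim.params
    if prim.kind == "slab":
        axis, c, t = int(p["axis"]), float(p["center"]), float(p["thickness"])
        if c - t / 2 < -0.5 or c + t / 2 > shape[axis] - 0.5:
            raise ValueError(f"slab {p} does not fit inside grid {shape}")
    elif prim.kind == "ball":
        c, r = p["center"], float(p["radius"])
        for a in range(3):
            if c[a] - r < -0.5 or c[a] + r > shape[a] - 0.5:
                raise ValueError(f"ball {p} does not fit inside grid {shape}")
    elif prim.kind == "cuboid":
        for a in range(3):
            if p["lo"][a] < 0 or p["hi"][a] > shape[a] - 1:
                raise ValueError(f"cuboid {p} does not fit inside grid {shape}")
    elif prim.kind == "cylinder":
        axis = int(p["axis"])
        cu, cv = p["center"]
        r = float(p["radius"])
        u_ax, v_ax = [a for a in range(3) if a != axis]
        if (
            cu - r < -0.5
            or cu + r > shape[u_ax] - 0.5
            or cv - r < -0.5
            or cv + r > shape[v_ax] - 0.5
        ):
            raise ValueError(f"cylinder {p} does not fit inside grid {shape}")


def make_phantom(spec: PhantomSpec) -> tuple[Volume3D, LabelVolume]:
    """Rasterise a phantom: binary mask plus class-truth label map.

    Later primitives overwrite earlier ones in the truth map.  Fully
    deterministic given the spec (the flip-rate noise is applied separately
    through :func:`corrupt_mask` so truth and corruption stay distinct).
    """
    shape = tuple(int(n) for n in spec.shape)
    truth = np.zeros(shape, dtype=np.uint16)
    for prim in spec.primitives:
        _check_fits(prim, shape)
        truth[_primitive_mask(prim, shape)] = prim.class_id
    mask = Volume3D((truth > 0).astype(np.uint8), spec.spacing)
    names = {p.class_id: f"class_{p.class_id}" for p in spec.primitives}
    return mask, LabelVolume(truth, spec.spacing, names)


def corrupt_mask(mask: Volume3D, p: float, seed: int) -> Volume3D:
    """Flip each voxel independently with probability ``p`` (seeded)."""
    if not (0.0 <= p < 0.5):
        raise ValueError("flip rate must lie in [0, 0.5)")
    values = np.asarray(mask.values) > 0
    if p == 0.0:
        return Volume3D(values.astype(np.uint8), mask.spacing, mask.origin)
    rng = np.random.default_rng(seed)
    flips = rng.random(values.shape) < p
    return Volume3D((values ^ flips).astype(np.uint8), mask.spacing, mask.origin)


def colorize_phantom(
    truth: LabelVolume,
    class_colors: dict[int, tuple[int, int, int]],
    background_color: tuple[int, int, int] = (0, 0, 0),
    color_noise_sd: float = 0.0,
    seed: int = 0,
) -> RGBVolume:
    """Render a truth label map as an RGB stack with optional channel noise.

    Each voxel receives its class colour (background voxels the background
    colour) plus independent Gaussian per-channel noise, rounded and clipped
    to [0, 255].  With ``color_noise_sd=0`` the colours are exact, so a
    matching colour model recovers the truth bit-exactly.
    """
    labels = truth.values
    present = set(int(v) for v in np.unique(labels)) - {0}
    missing = present - set(class_colors)
    if missing:
        raise ValueError(f"no colour given for classes {sorted(missing)}")

    rgb = np.empty(labels.shape + (3,), dtype=np.float64)
    rgb[...] = background_color
    for cls in sorted(present):
        rgb[labels == cls] = class_colors[cls]
    if color_noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, color_noise_sd, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return RGBVolume(rgb, truth.spacing)
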