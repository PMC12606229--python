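"""Colour-based collagen segmentation, artefact removal, slice in-filling.

Collagen-rich connective tissue occupies a narrow, near-white band of RGB
colour space in cryo-section photographs, and the tissue surrounding organs
differs slightly in hue from the tissue embedded in subcutaneous fat — hence
a multi-class nearest-reference classifier operating in a linearly
transformed colour space.  The transform matrix, per-class reference colours
and per-class acceptance radii together form a :class:`ColorModel`; the
default model uses the identity transform with whitish references and is
intended for phantom work (real stacks need a model fitted to their staining).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .volume_io import LabelVolume, RGBVolume, Volume3D

__all__ = [
    "ClassReference",
    "ColorModel",
    "default_color_model",
    "segment_collagen",
    "clean_artifacts",
    "fill_missing_slices",
]


@dataclass
class ClassReference:
    class_id: int
    reference: tuple[float, float, float]  # in transformed colour space
    max_distance: float

    def __post_init__(self):
        if self.class_id < 1:
            raise ValueError("class ids must be distinct positive integers")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


@dataclass
class ColorModel:
    """Linear colour transform plus nearest-reference classifier."""

    transform: np.ndarray = field(default_factory=lambda: np.eye(3))
    classes: list[ClassReference] = field(default_factory=list)

    def __post_init__(self):
        self.transform = np.asarray(self.transform, dtype=np.float64)
        if self.transform.shape != (3, 3):
            raise ValueError("transform must be a 3x3 matrix")
        ids = [c.class_id for c in self.classes]
        if len(ids) != len(set(ids)):
            raise ValueError("class ids must be distinct")

    def to_yaml(self, path: str) -> None:
        doc = {
            "transform": [[float(v) for v in row] for row in self.transform],
            "classes": [
                {
                    "id": c.class_id,
                    "reference": [float(v) for v in c.reference],
                    "max_distance": float(c.max_distance),
                }
                for c in self.classes
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path: str) -> "ColorModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        classes = [
            ClassReference(int(c["id"]), tuple(c["reference"]), float(c["max_distance"]))
            for c in doc["classes"]
        ]
        return ColorModel(np.asarray(doc["transform"], dtype=float), classes)


def default_color_model() -> ColorModel:
    """Identity transform, two whitish reference classes.

    Class 1 emulates the bright peri-organ connective tissue, class 2 the
    slightly darker tissue embedded in subcutaneous fat.  Radii of 60 units
    accept ordinary photographic noise while rejecting muscle/fat colours.
    """
    return ColorModel(
        np.eye(3),
        [
            ClassReference(1, (235.0, 230.0, 220.0), 60.0),
            ClassReference(2, (205.0, 190.0, 165.0), 60.0),
        ],
    )


def segment_collagen(rgb: RGBVolume, model: ColorModel) -> LabelVolume:
    """Per-voxel nearest-reference classification in transformed colour space.

    A voxel is assigned the class whose reference colour is nearest in
    Euclidean distance, provided that distance does not exceed the class's
    ``max_distance``; otherwise it is background (0).  Ties go to the lowest
    class id.  Deterministic and total on valid inputs.
    """
    if not model.classes:
        raise ValueError("colour model must define at least one class")
    flat = rgb.values.reshape(-1, 3).astype(np.float64)
    transformed = flat @ model.transform.T

    # stable ordering: ascending class id so argmin tie-break = lowest id
    refs = sorted(model.classes, key=lambda c: c.class_id)
    dists = np.stack(
        [np.linalg.norm(transformed - np.asarray(c.reference), axis=1) for c in refs],
        axis=1,
    )
    best = np.argmin(dists, axis=1)
    best_dist = dists[np.arange(len(flat)), best]
    radii = np.asarray([c.max_distance for c in refs])
    ids = np.asarray([c.class_id for c in refs], dtype=np.uint16)
    labels = np.where(best_dist <= radii[best], ids[best], 0).astype(np.uint16)

    names = {c.class_id: f"class_{c.class_id}" for c in refs}
    return LabelVolume(labels.reshape(rgb.shape), rgb.spacing, names)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def clean_artifacts(labels: LabelVolume, min_component_voxels: int) -> LabelVolume:
    """Drop 26-connected foreground components smaller than a voxel count.

    Connectivity is computed on the union of all classes, so a small
    class-2 fragment attached to a large class-1 body survives.  Never
    increases the foreground count; ``min_component_voxels=1`` is the
    identity.
    """
    if min_component_voxels < 1:
        raise ValueError("min_component_voxels must be >= 1")
    values = labels.values.copy()
    if min_component_voxels == 1:
        return LabelVolume(values, labels.spacing, dict(labels.label_names))
    fg = values > 0
    comp, ncomp = ndimage.label(fg, structure=_STRUCT26)
    if ncomp:
        sizes = np.bincount(comp.ravel())
        small = sizes < min_component_voxels
        small[0] = False
        values[small[comp]] = 0
    return LabelVolume(values, labels.spacing, dict(labels.label_names))


def _signed_distance(slice2d: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance of a binary slice, positive inside."""
    fg = slice2d > 0
    big = float(np.hypot(*slice2d.shape))  # farther than any in-plane distance
    if not fg.any():
        return np.full(slice2d.shape, -big)
    if fg.all():
        return np.full(slice2d.shape, big)
    return ndimage.distance_transform_edt(fg) - ndimage.distance_transform_edt(~fg)


def fill_missing_slices(vol: Volume3D, missing: list[int]) -> Volume3D:
    """Fill missing z-slices of a binary volume by shape interpolation.

    For a missing slice with valid neighbours on both sides, the signed
    Euclidean distance fields of the bounding valid slices are linearly
    interpolated at the slice's fractional position and re-thresholded at
    zero; this preserves shape topology across gaps (a disc shrinking from
    radius 10 to radius 6 passes through radius ~8).  A missing slice with
    a valid neighbour on one side only copies that neighbour.  Valid slices
    are returned bit-identical.
    """
    nz = vol.shape[2]
    missing_set = set(int(m) for m in missing)
    for m in missing_set:
        if not (0 <= m < nz):
            raise ValueError(f"missing slice index {m} out of range [0, {nz})")
    if len(missing_set) == nz:
        raise ValueError("cannot fill a volume in which every slice is missing")
    values = np.asarray(vol.values)
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("fill_missing_slices expects a binary volume")
    valid = sorted(set(range(nz)) - missing_set)

    out = values.copy()
    sdf_cache: dict[int, np.ndarray] = {}

    def sdf(idx: int) -> np.ndarray:
        if idx not in sdf_cache:
            sdf_cache[idx] = _signed_distance(values[:, :, idx])
        return sdf_cache[idx]

    valid_arr = np.asarray(valid)
    for m in sorted(missing_set):
        below = valid_arr[valid_arr < m]
        above = valid_arr[valid_arr > m]
        if below.size and above.size:
            lo, hi = int(below[-1]), int(above[0])
            t = (m - lo) / (hi - lo)
            interp = (1.0 - t) * sdf(lo) + t * sdf(hi)
            out[:, :, m] = (interp > 0).astype(values.dtype)
        elif below.size:
            out[:, :, m] = values[:, :, int(below[-1])]
        else:
            out[:, :, m] = values[:, :, int(above[0])]
    return Volume3D(out, vol.spacing, vol.origin)
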