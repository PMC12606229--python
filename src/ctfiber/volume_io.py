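"""Volumetric containers and compressed-NIFTI I/O.

All pipeline stages exchange data through four container types, each a thin
wrapper around a numpy grid with physical voxel spacing in millimetres:

``Volume3D``
    scalar grid (masks, counts, thickness fields),
``RGBVolume``
    3-channel byte colour grid (cryo-section stacks, colour-coded outputs),
``TensorVolume``
    per-voxel symmetric 3x3 orientation tensor, six stored components in the
    NIFTI lower-triangle order ``(a11, a21, a22, a31, a32, a33)``,
``LabelVolume``
    non-negative integer label map with a label -> name table.

Grids are indexed ``(x, y, z)``, matching NIFTI's fastest-to-slowest on-disk
axis order; every module in the package uses this one convention.  Files are
NIFTI-1, gzip-compressed.  Spacing is honoured through the header pixel
dimensions; orientation matrices (sform/qform rotations) are not interpreted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "RGBVolume",
    "TensorVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "label_sidecar_path",
]

# NIFTI-1 codes (nibabel exposes the data, we pin the constants we dispatch on)
_DT_RGB24 = 128
_INTENT_SYMMATRIX = 1005

_RGB_DTYPE = np.dtype([("R", "u1"), ("G", "u1"), ("B", "u1")])


def _check_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing)
    if len(s) != 3 or any(x <= 0 or not np.isfinite(x) for x in s):
        raise ValueError(f"spacing must be three positive finite values, got {spacing!r}")
    return s


@dataclass
class Volume3D:
    """Scalar voxel grid with isotropic-or-not physical spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("Volume3D requires a non-empty 3D grid")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("Volume3D values must be finite")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def is_isometric(self, rtol: float = 1e-6) -> bool:
        sx, sy, sz = self.spacing
        return abs(sy - sx) <= rtol * sx and abs(sz - sx) <= rtol * sx


@dataclass
class RGBVolume:
    """3-channel colour grid; ``values`` has shape (nx, ny, nz, 3), uint8."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 4 or v.shape[-1] != 3:
            raise ValueError("RGBVolume requires an (nx, ny, nz, 3) grid")
        if v.dtype != np.uint8:
            if v.min() < 0 or v.max() > 255:
                raise ValueError("RGB channel values must lie in [0, 255]")
            v = v.astype(np.uint8)
        self.values = v
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass
class TensorVolume:
    """Symmetric 3x3 tensor per voxel, stored as six components.

    ``values`` has shape (nx, ny, nz, 6) in lower-triangle order
    (a11, a21, a22, a31, a32, a33).  Tensors built from dyadic sums are
    positive semidefinite by construction.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 4 or v.shape[-1] != 6:
            raise ValueError("TensorVolume requires an (nx, ny, nz, 6) grid")
        self.values = v
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand to full (nx, ny, nz, 3, 3) symmetric matrices."""
        a11, a21, a22, a31, a32, a33 = np.moveaxis(self.values, -1, 0)
        m = np.empty(self.shape + (3, 3), dtype=self.values.dtype)
        m[..., 0, 0] = a11
        m[..., 1, 0] = m[..., 0, 1] = a21
        m[..., 1, 1] = a22
        m[..., 2, 0] = m[..., 0, 2] = a31
        m[..., 2, 1] = m[..., 1, 2] = a32
        m[..., 2, 2] = a33
        return m

    @staticmethod
    def from_matrices(m: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> "TensorVolume":
        m = np.asarray(m)
        comps = np.stack(
            [m[..., 0, 0], m[..., 1, 0], m[..., 1, 1], m[..., 2, 0], m[..., 2, 1], m[..., 2, 2]],
            axis=-1,
        )
        return TensorVolume(comps, spacing)


@dataclass
class LabelVolume:
    """Integer label map; label 0 is background, names map every nonzero label."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("LabelVolume requires a non-empty 3D grid")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("LabelVolume values must be integers")
        if v.min() < 0:
            raise ValueError("labels must be non-negative")
        self.values = v
        self.spacing = _check_spacing(self.spacing)
        present = set(int(x) for x in np.unique(v)) - {0}
        missing = present - set(self.label_names)
        for lab in sorted(missing):
            self.label_names[lab] = f"label_{lab}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def label_sidecar_path(path: str | os.PathLike) -> str:
    """Path of the two-column (label <TAB> name) table next to a label NIFTI."""
    p = str(path)
    for suffix in (".nii.gz", ".nii"):
        if p.endswith(suffix):
            return p[: -len(suffix)] + ".labels.tsv"
    return p + ".labels.tsv"


def write_volume(vol, path: str | os.PathLike) -> str:
    """Write any of the four volume kinds as gzip-compressed NIFTI-1.

    Integer grids round-trip bit-exactly; real grids are stored float32.
    ``TensorVolume`` is written with the symmetric-matrix intent (six
    components), ``RGBVolume`` with the 24-bit RGB datatype, and
    ``LabelVolume`` with a tab-separated label-name sidecar file.
    """
    path = str(path)
    affine = None

    if isinstance(vol, RGBVolume):
        rgb = np.ascontiguousarray(vol.values)
        structured = rgb.view(_RGB_DTYPE).reshape(vol.shape)
        img = nib.Nifti1Image(structured, affine)
        img.header.set_zooms(vol.spacing)
    elif isinstance(vol, TensorVolume):
        data = np.asarray(vol.values, dtype=np.float32)
        if not np.all(np.isfinite(data)):
            raise ValueError("tensor components must be finite")
        data5 = data.reshape(vol.shape + (1, 6))  # dim5 carries the 6 components
        img = nib.Nifti1Image(data5, affine)
        img.header.set_intent(_INTENT_SYMMATRIX, (3,), name="symmat")
        img.header.set_zooms(vol.spacing + (1.0, 1.0))
    elif isinstance(vol, LabelVolume):
        img = nib.Nifti1Image(vol.values, affine)
        img.header.set_zooms(vol.spacing)
        sidecar = label_sidecar_path(path)
        with open(sidecar, "w") as fh:
            for lab in sorted(vol.label_names):
                fh.write(f"{lab}\t{vol.label_names[lab]}\n")
    elif isinstance(vol, Volume3D):
        data = vol.values
        if np.issubdtype(data.dtype, np.floating):
            if not np.all(np.isfinite(data)):
                raise ValueError("real-valued grid contains non-finite values")
            data = data.astype(np.float32)
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.spacing)
    else:
        raise TypeError(f"unsupported volume type {type(vol).__name__}")

    img.header.set_qform(np.diag(list(_spacing_of(vol)) + [1.0]), code=1)
    nib.save(img, path)
    return path


def _spacing_of(vol) -> tuple[float, float, float]:
    return vol.spacing


def _read_label_sidecar(path: str) -> dict[int, str] | None:
    sidecar = label_sidecar_path(path)
    if not os.path.exists(sidecar):
        return None
    names: dict[int, str] = {}
    with open(sidecar) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            lab, name = line.split("\t", 1)
            names[int(lab)] = name
    return names


def read_volume(path: str | os.PathLike):
    """Read a NIFTI-1 file, dispatching to the matching volume kind.

    Dispatch order: RGB datatype -> :class:`RGBVolume`; symmetric-matrix
    intent with six components -> :class:`TensorVolume`; integer data with a
    label-name sidecar file -> :class:`LabelVolume`; anything else ->
    :class:`Volume3D`.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header error types
        raise ValueError(f"malformed or unreadable NIFTI file {path}: {exc}") from exc
    if isinstance(img, nib.Nifti2Image):
        raise ValueError("NIFTI-2 files are not supported; convert to NIFTI-1")
    if not isinstance(img, nib.Nifti1Image):
        raise ValueError(f"unsupported image format {type(img).__name__}; NIFTI-1 required")

    hdr = img.header
    zooms = hdr.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    datatype = int(hdr["datatype"])
    data = np.asanyarray(img.dataobj)

    if datatype == _DT_RGB24 or (data.dtype.fields is not None and len(data.dtype.fields) == 3):
        rgb = np.ascontiguousarray(data).view(np.uint8).reshape(data.shape + (3,))
        return RGBVolume(rgb, spacing)

    intent = int(hdr["intent_code"])
    if intent == _INTENT_SYMMATRIX:
        if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 6:
            comps = np.asarray(data, dtype=np.float32).reshape(data.shape[:3] + (6,))
        elif data.ndim == 4 and data.shape[3] == 6:
            comps = np.asarray(data, dtype=np.float32)
        else:
            raise ValueError(
                f"symmetric-matrix file must carry 6 components, got shape {data.shape}"
            )
        return TensorVolume(comps, spacing)

    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar grid, got shape {data.shape}")

    if np.issubdtype(data.dtype, np.integer):
        names = _read_label_sidecar(path)
        if names is not None:
            return LabelVolume(data, spacing, names)
        return Volume3D(data, spacing)
    if np.issubdtype(data.dtype, np.floating):
        return Volume3D(data, spacing)
    raise ValueError(f"unsupported NIFTI datatype {datatype} ({data.dtype})")
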