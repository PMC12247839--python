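"""Reading, writing and windowing of 3D micro-CT volumes and label maps.

All arrays use ``(z, y, x)`` index order.  Intensities are assumed to be in
Hounsfield units (HU); voxel spacing is carried in micrometres per axis.
Canonical on-disk interchange is NIfTI-1; DICOM series (read-only),
multi-page TIFF and uncompressed MetaImage MHA are also supported.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import tifffile

from . import _dicom, _mha

logger = logging.getLogger(__name__)

#: Default isotropic voxel edge in micrometres when file metadata is absent.
DEFAULT_SPACING_UM = 17.5

#: Default HU window used for bone masking.
HU_WINDOW = (2500.0, 20000.0)

COMPARTMENTS = (
    "tarsal/carpal",
    "metatarsal/metacarpal",
    "proximal_phalanx",
    "distal_phalanx",
    "sesamoid",
    "other",
)


class VolumeFormatError(RuntimeError):
    """Raised when a file cannot be parsed in its declared format."""


class GeometryError(RuntimeError):
    """Raised for inconsistent slice geometry (e.g. in a DICOM series)."""


@dataclass
class Volume3D:
    """A scalar 3D image with voxel spacing and physical origin.

    Parameters
    ----------
    data:
        3D array in ``(z, y, x)`` order, HU intensity semantics.
    spacing:
        Voxel size per axis ``(z, y, x)`` in micrometres.
    origin:
        Physical offset of voxel ``(0, 0, 0)`` in micrometres.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_UM,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """Integer-labeled segmentation; id 0 is reserved for background."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (DEFAULT_SPACING_UM,) * 3
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Sorted non-background label ids present in the map."""
        ids = np.unique(self.labels)
        return ids[ids != 0]


@dataclass
class BoneTable:
    """Maps label ids to bone names and anatomical compartments."""

    entries: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("label ids in a BoneTable must be unique")
        for _, _, comp in self.entries:
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}; expected one of {COMPARTMENTS}")

    def compartment_of(self, label_id: int) -> str:
        for lid, _, comp in self.entries:
            if lid == label_id:
                return comp
        raise KeyError(f"label id {label_id} not in table")

    def to_rows(self) -> list[dict]:
        return [
            {"label_id": lid, "bone_name": name, "compartment": comp}
            for lid, name, comp in self.entries
        ]


# ---------------------------------------------------------------------------
# format detection helpers

_FORMATS = ("dicom_series", "nifti", "tiff_stack", "mha")


def _detect_format(path: Path) -> str:
    if path.is_dir():
        if any(path.glob("*.dcm")):
            return "dicom_series"
        if any(path.glob("*.tif")) or any(path.glob("*.tiff")):
            return "tiff_stack"
        raise VolumeFormatError(f"cannot infer format of directory {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    if name.endswith(".mha"):
        return "mha"
    if name.endswith(".dcm"):
        return "dicom_series"
    raise VolumeFormatError(f"cannot infer format of {path}")


def _nifti_load(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error variety
        raise VolumeFormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D NIfTI, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    # nibabel stores (x, y, z); we use (z, y, x)
    data = np.ascontiguousarray(arr.T)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return data, spacing


def _nifti_save(data: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


_TIFF_META_KEY = "bonesep_spacing_um"


def _tiff_load(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:
        raise VolumeFormatError(f"unreadable TIFF file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a grayscale stack, got shape {data.shape}")
    spacing = None
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and _TIFF_META_KEY in meta:
            spacing = tuple(float(v) for v in meta[_TIFF_META_KEY])
    except (json.JSONDecodeError, TypeError, ValueError):
        pass
    return data, spacing  # type: ignore[return-value]


def _tiff_save(data: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    desc = json.dumps({_TIFF_META_KEY: list(spacing)})
    tifffile.imwrite(str(path), data, description=desc, photometric="minisblack")


def read_volume(
    path: str | os.PathLike,
    format: str | None = None,
    default_spacing: float | Sequence[float] = DEFAULT_SPACING_UM,
) -> Volume3D:
    """Read a 3D scalar volume.

    Parameters
    ----------
    path:
        File (NIfTI / TIFF / MHA) or directory (DICOM series, TIFF slices).
    format:
        One of ``dicom_series``, ``nifti``, ``tiff_stack``, ``mha``;
        auto-detected from the path when omitted.
    default_spacing:
        Spacing in µm used when the file carries no spacing metadata.
        Scalar values are broadcast isotropically.

    Returns
    -------
    Volume3D
        Data in ``(z, y, x)`` order.  DICOM stored values are rescaled with
        ``RescaleSlope``/``RescaleIntercept`` when present.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file or directory: {path}")
    fmt = format or _detect_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if np.isscalar(default_spacing):
        fallback = (float(default_spacing),) * 3  # type: ignore[arg-type]
    else:
        fallback = tuple(float(s) for s in default_spacing)  # type: ignore[assignment]

    if fmt == "nifti":
        data, spacing = _nifti_load(path)
    elif fmt == "tiff_stack":
        data, spacing = _tiff_load(path)
    elif fmt == "mha":
        data, spacing = _mha.read(path)
    else:  # dicom_series
        data, spacing = _dicom.read_series(path)

    if spacing is None:
        logger.warning(
            "%s: no spacing metadata; assuming %s um", path, fallback
        )
        spacing = fallback
    return Volume3D(data=np.asarray(data, dtype=np.float64), spacing=spacing)


def write_volume(volume: Volume3D, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a scalar volume as NIfTI, TIFF stack or MHA."""
    path = Path(path)
    fmt = format or _detect_format(path)
    data = np.asarray(volume.data, dtype=np.float32)
    if fmt == "nifti":
        _nifti_save(data, volume.spacing, path)
    elif fmt == "tiff_stack":
        _tiff_save(data, volume.spacing, path)
    elif fmt == "mha":
        _mha.write(path, data, volume.spacing)
    else:
        raise ValueError(f"unsupported output format {fmt!r}")


def _label_dtype(max_id: int) -> np.dtype:
    if max_id <= np.iinfo(np.uint16).max:
        return np.dtype(np.uint16)
    return np.dtype(np.uint32)


def write_labels(labels: LabelVolume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a label map integer-exactly (NIfTI, TIFF stack or MHA)."""
    path = Path(path)
    fmt = format or _detect_format(path)
    max_id = int(labels.labels.max(initial=0))
    data = labels.labels.astype(_label_dtype(max_id))
    try:
        if fmt == "nifti":
            _nifti_save(data, labels.spacing, path)
        elif fmt == "tiff_stack":
            _tiff_save(data, labels.spacing, path)
        elif fmt == "mha":
            _mha.write(path, data, labels.spacing)
        else:
            raise ValueError(f"unsupported label output format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write label map to {path}: {exc}") from exc


def read_labels(path: str | os.PathLike, format: str | None = None) -> LabelVolume:
    """Read a label map written by :func:`write_labels`."""
    vol = read_volume(path, format=format)
    rounded = np.rint(vol.data)
    if not np.array_equal(rounded, vol.data):
        raise VolumeFormatError(f"{path}: non-integer values in a label map")
    return LabelVolume(labels=rounded.astype(np.int64), spacing=vol.spacing, origin=vol.origin)


def window_mask(volume: Volume3D, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of voxels with ``lo <= intensity <= hi`` (both inclusive)."""
    if lo >= hi:
        raise ValueError(f"window lower bound must be < upper bound, got [{lo}, {hi}]")
    return (volume.data >= lo) & (volume.data <= hi)
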