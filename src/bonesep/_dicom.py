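"""Minimal DICOM series reader (and writer, for synthesizing fixtures).

Supports the common case of CT series stored as uncompressed,
explicit-VR little-endian files: 16-bit monochrome pixel data,
``RescaleSlope``/``RescaleIntercept`` applied on read, slices ordered by
``ImagePositionPatient`` along the slice normal.  Anything fancier
(compressed transfer syntaxes, implicit VR, big endian) is rejected with a
clear error — the pipeline's canonical interchange format is NIfTI.

DICOM distances are millimetres on disk; this module converts to/from the
package-wide micrometre convention at the boundary.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# tags we care about
TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IPP = (0x0020, 0x0032)
TAG_IOP = (0x0020, 0x0037)
TAG_SAMPLES = (0x0028, 0x0002)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)

_LONG_LENGTH_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


class DicomError(RuntimeError):
    pass


class DicomGeometryError(RuntimeError):
    pass


def _parse_elements(buf: bytes, path: Path) -> dict[tuple[int, int], bytes]:
    """Parse explicit-VR little-endian data elements into raw value bytes."""
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"{path}: missing DICM magic; not a part-10 DICOM file")
    out: dict[tuple[int, int], bytes] = {}
    pos = 132
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_LENGTH_VRS:
            if vr == b"SQ":
                raise DicomError(f"{path}: sequences are not supported")
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            value_off = pos + 12
        elif vr.isalpha() and vr.isupper():
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            value_off = pos + 8
        else:
            raise DicomError(
                f"{path}: unrecognized VR {vr!r} at offset {pos}; "
                "only explicit VR little endian is supported"
            )
        if length == 0xFFFFFFFF:
            raise DicomError(f"{path}: undefined-length elements are not supported")
        if value_off + length > n:
            raise DicomError(f"{path}: element ({group:04x},{elem:04x}) overruns file")
        out[(group, elem)] = buf[value_off : value_off + length]
        pos = value_off + length
    return out


def _decode_str(elements: dict, tag: tuple[int, int], default: str | None = None) -> str | None:
    raw = elements.get(tag)
    if raw is None:
        return default
    return raw.decode("ascii", errors="replace").strip("\x00 ")


def _decode_floats(elements: dict, tag: tuple[int, int]) -> list[float] | None:
    s = _decode_str(elements, tag)
    if s is None or s == "":
        return None
    return [float(v) for v in s.split("\\")]


def _decode_us(elements: dict, tag: tuple[int, int]) -> int | None:
    raw = elements.get(tag)
    if raw is None:
        return None
    return struct.unpack("<H", raw[:2])[0]


def _read_slice(path: Path) -> dict:
    buf = path.read_bytes()
    elements = _parse_elements(buf, path)
    ts = _decode_str(elements, TAG_TRANSFER_SYNTAX)
    if ts is not None and ts != EXPLICIT_VR_LE:
        raise DicomError(f"{path}: unsupported transfer syntax {ts}")
    rows = _decode_us(elements, TAG_ROWS)
    cols = _decode_us(elements, TAG_COLS)
    bits = _decode_us(elements, TAG_BITS_ALLOCATED) or 16
    signed = (_decode_us(elements, TAG_PIXEL_REPRESENTATION) or 0) == 1
    if rows is None or cols is None:
        raise DicomError(f"{path}: missing Rows/Columns")
    if bits not in (8, 16):
        raise DicomError(f"{path}: BitsAllocated={bits} not supported")
    raw = elements.get(TAG_PIXEL_DATA)
    if raw is None:
        raise DicomError(f"{path}: missing PixelData")
    dtype = {(8, False): np.uint8, (8, True): np.int8,
             (16, False): np.uint16, (16, True): np.int16}[(bits, signed)]
    expected = rows * cols * np.dtype(dtype).itemsize
    if len(raw) < expected:
        raise DicomError(f"{path}: PixelData shorter than Rows*Columns")
    pixels = np.frombuffer(raw[:expected], dtype=dtype).reshape(rows, cols)

    slope_v = _decode_floats(elements, TAG_RESCALE_SLOPE)
    intercept_v = _decode_floats(elements, TAG_RESCALE_INTERCEPT)
    spacing_mm = _decode_floats(elements, TAG_PIXEL_SPACING)
    ipp = _decode_floats(elements, TAG_IPP)
    instance = _decode_str(elements, TAG_INSTANCE_NUMBER)
    return {
        "pixels": pixels,
        "slope": slope_v[0] if slope_v else 1.0,
        "intercept": intercept_v[0] if intercept_v else 0.0,
        "pixel_spacing_mm": spacing_mm,  # [row, col] in mm
        "ipp": ipp,
        "instance": int(instance) if instance else None,
        "path": path,
    }


def read_series(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    """Read a directory of ``.dcm`` files (or a single file) as a volume.

    Returns data in ``(z, y, x)`` order with rescale slope/intercept applied,
    and spacing in micrometres (``None`` if the series has no spacing tags).
    """
    path = Path(path)
    files = sorted(path.glob("*.dcm")) if path.is_dir() else [path]
    if not files:
        raise DicomError(f"{path}: no .dcm files found")
    slices = [_read_slice(f) for f in files]

    shapes = {s["pixels"].shape for s in slices}
    if len(shapes) != 1:
        raise DicomGeometryError(f"{path}: inconsistent slice shapes {sorted(shapes)}")

    if all(s["ipp"] is not None for s in slices):
        slices.sort(key=lambda s: s["ipp"][2])
        zs = np.array([s["ipp"][2] for s in slices])
    elif all(s["instance"] is not None for s in slices):
        slices.sort(key=lambda s: s["instance"])
        zs = None
    else:
        zs = None

    data = np.stack(
        [s["pixels"].astype(np.float64) * s["slope"] + s["intercept"] for s in slices]
    )

    spacing = None
    ps = slices[0]["pixel_spacing_mm"]
    if ps is not None:
        dz_um = None
        if zs is not None and len(zs) > 1:
            steps = np.diff(zs)
            if steps.min() <= 0 or (steps.max() - steps.min()) > 1e-3 * abs(steps.mean()) + 1e-6:
                raise DicomGeometryError(
                    f"{path}: non-uniform or degenerate slice positions (steps {steps})"
                )
            dz_um = float(steps.mean()) * 1000.0
        row_um, col_um = ps[0] * 1000.0, ps[1] * 1000.0
        spacing = (dz_um if dz_um is not None else row_um, row_um, col_um)
    return data, spacing


# ---------------------------------------------------------------------------
# writer — used to synthesize test series (explicit VR little endian only)


def _element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != b"UI" else b"\x00"
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_LENGTH_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(values) -> bytes:
    return "\\".join(f"{v:g}" for v in np.atleast_1d(values)).encode("ascii")


def write_series(
    directory: str | Path,
    data: np.ndarray,
    spacing_um: tuple[float, float, float],
    slope: float = 1.0,
    intercept: float = 0.0,
) -> list[Path]:
    """Write ``data`` (z, y, x; stored as int16 after inverse rescale) as a series."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stored = np.rint((np.asarray(data, dtype=np.float64) - intercept) / slope)
    if stored.min() < np.iinfo(np.int16).min or stored.max() > np.iinfo(np.int16).max:
        raise ValueError("stored values exceed int16 range; adjust slope/intercept")
    stored = stored.astype(np.int16)
    sz, sy, sx = spacing_um
    paths = []
    meta_group = _element(0x0002, 0x0010, b"UI", EXPLICIT_VR_LE.encode("ascii"))
    for k in range(stored.shape[0]):
        body = b"".join(
            [
                _element(*TAG_INSTANCE_NUMBER, b"IS", str(k + 1).encode()),
                _element(*TAG_IPP, b"DS", _ds([0.0, 0.0, k * sz / 1000.0])),
                _element(*TAG_IOP, b"DS", _ds([1, 0, 0, 0, 1, 0])),
                _element(*TAG_SAMPLES, b"US", struct.pack("<H", 1)),
                _element(*TAG_ROWS, b"US", struct.pack("<H", stored.shape[1])),
                _element(*TAG_COLS, b"US", struct.pack("<H", stored.shape[2])),
                _element(*TAG_PIXEL_SPACING, b"DS", _ds([sy / 1000.0, sx / 1000.0])),
                _element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0101, b"US", struct.pack("<H", 16)),
                _element(0x0028, 0x0102, b"US", struct.pack("<H", 15)),
                _element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 1)),
                _element(*TAG_RESCALE_INTERCEPT, b"DS", _ds(intercept)),
                _element(*TAG_RESCALE_SLOPE, b"DS", _ds(slope)),
                _element(*TAG_PIXEL_DATA, b"OW", stored[k].tobytes()),
            ]
        )
        out = directory / f"slice_{k:04d}.dcm"
        out.write_bytes(b"\x00" * 128 + b"DICM" + meta_group + body)
        paths.append(out)
    return paths
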