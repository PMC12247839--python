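"""Minimal uncompressed MetaImage (.mha) reader/writer.

Covers the single-file, ``ElementDataFile = LOCAL`` dialect with raw
(uncompressed) pixel data — sufficient for pipeline interchange.  Arrays are
exposed in ``(z, y, x)`` order; the on-disk ``DimSize``/``ElementSpacing``
follow the MetaImage ``(x, y, z)`` convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_MET_TO_DTYPE = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_LONG": np.int64,
    "MET_ULONG": np.uint64,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_DTYPE_TO_MET = {np.dtype(v): k for k, v in _MET_TO_DTYPE.items()}


class MhaError(RuntimeError):
    pass


def read(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise MhaError(f"{path}: truncated MHA header")
            try:
                key, _, value = line.decode("ascii").partition("=")
            except UnicodeDecodeError as exc:
                raise MhaError(f"{path}: non-ASCII bytes in MHA header") from exc
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                if value != "LOCAL":
                    raise MhaError(f"{path}: only ElementDataFile = LOCAL is supported")
                break
        if header.get("CompressedData", "False").lower() == "true":
            raise MhaError(f"{path}: compressed MHA is not supported")
        ndims = int(header.get("NDims", "3"))
        if ndims != 3:
            raise MhaError(f"{path}: expected NDims = 3, got {ndims}")
        try:
            dims_xyz = [int(v) for v in header["DimSize"].split()]
            met_type = header["ElementType"]
        except KeyError as exc:
            raise MhaError(f"{path}: missing required MHA field {exc}") from exc
        if met_type not in _MET_TO_DTYPE:
            raise MhaError(f"{path}: unsupported ElementType {met_type}")
        dtype = np.dtype(_MET_TO_DTYPE[met_type])
        if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
            dtype = dtype.newbyteorder(">")
        count = int(np.prod(dims_xyz))
        raw = fh.read(count * dtype.itemsize)
        if len(raw) != count * dtype.itemsize:
            raise MhaError(f"{path}: pixel payload shorter than DimSize implies")
    data = np.frombuffer(raw, dtype=dtype).reshape(dims_xyz[::-1])  # (z, y, x)
    spacing = None
    if "ElementSpacing" in header:
        sp_xyz = [float(v) for v in header["ElementSpacing"].split()]
        spacing = (sp_xyz[2], sp_xyz[1], sp_xyz[0])
    return np.ascontiguousarray(data), spacing


def write(path: str | Path, data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    data = np.ascontiguousarray(data)
    if data.ndim != 3:
        raise MhaError(f"expected 3D array, got shape {data.shape}")
    dtype = data.dtype.newbyteorder("=")
    if np.dtype(dtype.type) not in _DTYPE_TO_MET:
        raise MhaError(f"dtype {data.dtype} has no MetaImage element type")
    met_type = _DTYPE_TO_MET[np.dtype(dtype.type)]
    nz, ny, nx = data.shape
    sz, sy, sx = spacing
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sx:g} {sy:g} {sz:g}\n"
        f"ElementType = {met_type}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.astype(dtype, copy=False).tobytes())
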