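"""Volume containers and I/O.

A :class:`Volume` is a 3D grid of unsigned 8- or 16-bit scalar samples
indexed ``(z, y, x)`` with explicit voxel size in micrometres — the raw CT
data.  Volumes are read either from a stack of single-channel TIFF slices
or from a raw binary payload accompanied by a plain-text JSON sidecar
header (dims, bit depth, endianness, voxel size).  :func:`normalize` maps
raw codes onto the unit interval, which is the domain on which gradient
measures and threshold specifications operate.

Axis order is fixed to ``(z, y, x)`` with 0-based indices throughout the
package; slice ``i`` of a stack becomes plane ``z = i``.  Raw payloads are
stored slice-major with ``x`` varying fastest (C order of a ``(nz, ny,
nx)`` array).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import (
    CorruptVolumeError,
    DimensionMismatchError,
    EmptyInputError,
    InvalidArgumentError,
    UnsupportedFormatError,
)

__all__ = [
    "Volume",
    "NormalizedVolume",
    "VolumeHeader",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_raw",
    "write_raw",
    "normalize",
]

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class Volume:
    """A 3D scalar grid with bit depth and voxel-size metadata.

    Parameters
    ----------
    data
        ``(nz, ny, nx)`` array of unsigned integers.
    voxel_size_um
        Edge lengths ``(dz, dy, dx)`` of one voxel in micrometres.
    bit_depth
        8 or 16; inferred from ``data.dtype`` when omitted.
    name
        Free-text label carried through sidecars and logs.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        if self.bit_depth is None:
            if self.data.dtype == np.uint8:
                self.bit_depth = 8
            elif self.data.dtype == np.uint16:
                self.bit_depth = 16
            else:
                raise UnsupportedFormatError(
                    f"unsupported sample dtype {self.data.dtype}; "
                    "only uint8/uint16 volumes are supported"
                )
        if self.bit_depth not in _DTYPES:
            raise UnsupportedFormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        self.data = self.data.astype(_DTYPES[self.bit_depth], copy=False)
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise DimensionMismatchError(
                f"voxel_size_um must be 3 positive reals, got {self.voxel_size_um}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        """``(nz, ny, nx)``."""
        return tuple(int(s) for s in self.data.shape)

    @property
    def max_code(self) -> int:
        """Largest representable raw code, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1


@dataclass
class NormalizedVolume:
    """A volume rescaled to real values in ``[0, 1]``."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        if self.data.size and (self.data.min() < 0.0 or self.data.max() > 1.0):
            raise InvalidArgumentError(
                "normalized values must lie in [0,1], got "
                f"[{self.data.min()}, {self.data.max()}]"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)


@dataclass
class VolumeHeader:
    """Plain-text sidecar describing a raw binary volume payload."""

    dims: tuple[int, int, int]
    bit_depth: int
    voxel_size_um: tuple[float, float, float]
    data_file: str
    endianness: str = "little"
    name: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def byte_count(self) -> int:
        nz, ny, nx = self.dims
        return nz * ny * nx * (self.bit_depth // 8)

    def to_json(self) -> str:
        doc = {
            "dims": list(self.dims),
            "bit_depth": self.bit_depth,
            "endianness": self.endianness,
            "voxel_size_um": list(self.voxel_size_um),
            "data_file": self.data_file,
            "name": self.name,
        }
        doc.update(self.extra)
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VolumeHeader":
        doc = json.loads(text)
        known = {"dims", "bit_depth", "endianness", "voxel_size_um", "data_file", "name"}
        return cls(
            dims=tuple(int(d) for d in doc["dims"]),
            bit_depth=int(doc["bit_depth"]),
            voxel_size_um=tuple(float(v) for v in doc["voxel_size_um"]),
            data_file=doc["data_file"],
            endianness=doc.get("endianness", "little"),
            name=doc.get("name", ""),
            extra={k: v for k, v in doc.items() if k not in known},
        )


def _check_slice(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: expected a single-channel 2D slice, got shape {arr.shape}"
        )
    if arr.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise UnsupportedFormatError(
            f"{path}: unsupported sample dtype {arr.dtype}; only uint8/uint16 supported"
        )
    return arr


def read_tiff_stack(
    paths: Sequence[str | Path],
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    name: str = "",
) -> Volume:
    """Read an ordered list of 2D TIFF slices into a volume (slice i → plane z=i)."""
    if len(paths) == 0:
        raise EmptyInputError("no TIFF slices given")
    slices = []
    for p in paths:
        arr = _check_slice(tifffile.imread(p), p)
        if slices and arr.shape != slices[0].shape:
            raise DimensionMismatchError(
                f"{p}: slice shape {arr.shape} differs from first slice {slices[0].shape}"
            )
        if slices and arr.dtype != slices[0].dtype:
            raise UnsupportedFormatError(
                f"{p}: slice dtype {arr.dtype} differs from first slice {slices[0].dtype}"
            )
        slices.append(arr)
    return Volume(np.stack(slices, axis=0), voxel_size_um=voxel_size_um, name=name)


def write_tiff_stack(vol: Volume, out_dir: str | Path, prefix: str = "slice") -> list[Path]:
    """Write each z-plane as ``<prefix>_0000.tif`` …; returns the ordered paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(vol.dims[0]):
        p = out_dir / f"{prefix}_{i:04d}.tif"
        tifffile.imwrite(p, vol.data[i])
        paths.append(p)
    return paths


def read_raw(header_path: str | Path) -> Volume:
    """Read a raw binary volume via its JSON sidecar header."""
    header_path = Path(header_path)
    header = VolumeHeader.from_json(header_path.read_text())
    if header.bit_depth not in _DTYPES:
        raise UnsupportedFormatError(f"unknown bit depth {header.bit_depth}")
    if header.endianness not in ("little", "big"):
        raise UnsupportedFormatError(f"unknown endianness {header.endianness!r}")
    data_path = header_path.parent / header.data_file
    payload = data_path.read_bytes()
    if len(payload) != header.byte_count:
        raise CorruptVolumeError(
            f"{data_path}: header declares {header.byte_count} bytes, file has {len(payload)}"
        )
    dtype = np.dtype(_DTYPES[header.bit_depth]).newbyteorder(
        "<" if header.endianness == "little" else ">"
    )
    data = np.frombuffer(payload, dtype=dtype).reshape(header.dims)
    # native byte order in memory
    data = data.astype(_DTYPES[header.bit_depth])
    return Volume(
        data,
        voxel_size_um=header.voxel_size_um,
        bit_depth=header.bit_depth,
        name=header.name,
    )


def write_raw(
    vol: Volume, out_prefix: str | Path, endianness: str = "little", extra: dict | None = None
) -> Path:
    """Write ``<prefix>.raw`` + ``<prefix>.json`` sidecar; returns the header path.

    ``read_raw(write_raw(vol))`` reproduces the volume bit-exactly.
    """
    if endianness not in ("little", "big"):
        raise UnsupportedFormatError(f"unknown endianness {endianness!r}")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    raw_path = out_prefix.with_suffix(".raw")
    header_path = out_prefix.with_suffix(".json")
    dtype = np.dtype(_DTYPES[vol.bit_depth]).newbyteorder(
        "<" if endianness == "little" else ">"
    )
    raw_path.write_bytes(np.ascontiguousarray(vol.data, dtype=dtype).tobytes())
    header = VolumeHeader(
        dims=vol.dims,
        bit_depth=vol.bit_depth,
        voxel_size_um=vol.voxel_size_um,
        data_file=raw_path.name,
        endianness=endianness,
        name=vol.name,
        extra=extra or {},
    )
    header_path.write_text(header.to_json())
    return header_path


def normalize(vol: Volume) -> NormalizedVolume:
    """Map raw codes to ``[0, 1]``: ``v / (2**bit_depth − 1)``.

    Strictly monotone on raw codes; 0 → 0.0 and the full-scale code → 1.0.
    """
    return NormalizedVolume(
        vol.data.astype(np.float64) / vol.max_code,
        voxel_size_um=vol.voxel_size_um,
        name=vol.name,
    )
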