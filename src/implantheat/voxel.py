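"""Regular-grid voxel fields and their container I/O.

Grids are cell-centered with 0-based indexing; ``origin`` is the physical
coordinate (meters) of the centre of voxel ``(0, 0, 0)`` and the z axis runs
along the scanner bore with the isocentre at the coordinate origin.

The on-disk container is an HDF5 file with datasets ``dims``, ``spacing``,
``origin``, ``values`` and a ``kind`` attribute, plus an optional JSON
sidecar for human inspection.  A raw-binary + JSON-header import path is
provided for externally produced arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from implantheat.errors import ValidationError

__all__ = [
    "VoxelField",
    "read_voxel_field",
    "write_voxel_field",
    "read_raw_field",
    "FIELD_KINDS",
]

FIELD_KINDS = (
    "b1_plus",
    "sar_nominal",
    "xi",
    "density",
    "conductivity",
    "mask",
    "temperature",
    "current_density",
    "generic",
)


@dataclass
class VoxelField:
    """Scalar, complex or 3-vector data on a regular grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (3, 4):
            raise ValidationError("values must be a 3-D scalar or (..., 3) vector array")
        if self.values.ndim == 4 and self.values.shape[-1] != 3:
            raise ValidationError("vector fields must have 3 components")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive lengths")
        if self.kind not in FIELD_KINDS:
            raise ValidationError(f"unknown field kind {self.kind!r}")
        if not np.all(np.isfinite(np.abs(self.values))):
            raise ValidationError("field values must be finite")
        if self.kind == "mask":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask fields must contain only {0, 1}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Cell-centre coordinates along one axis (meters)."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cell-centre coordinate arrays (ij indexing)."""
        return np.meshgrid(*(self.axis_coords(a) for a in range(3)), indexing="ij")

    def same_grid(self, other: "VoxelField") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_grid(self, other: "VoxelField", what: str = "fields") -> None:
        if not self.same_grid(other):
            raise ValidationError(f"{what} must share one grid")

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "VoxelField":
        return VoxelField(
            values=values,
            spacing=self.spacing,
            origin=self.origin,
            kind=kind or self.kind,
            meta=dict(self.meta),
        )


def write_voxel_field(fld: VoxelField, path: str | Path, sidecar: bool = True) -> None:
    """Write a field to the HDF5 container (lossless round-trip)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("dims", data=np.asarray(fld.dims, dtype=np.int64))
        h5.create_dataset("spacing", data=np.asarray(fld.spacing))
        h5.create_dataset("origin", data=np.asarray(fld.origin))
        h5.create_dataset("values", data=fld.values)
        h5.attrs["kind"] = fld.kind
        if fld.meta:
            h5.attrs["meta"] = json.dumps(fld.meta)
    if sidecar:
        info = {
            "dims": list(fld.dims),
            "spacing": list(fld.spacing),
            "origin": list(fld.origin),
            "kind": fld.kind,
            "dtype": str(fld.values.dtype),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(info, indent=2))


def read_voxel_field(path: str | Path) -> VoxelField:
    """Read a field from the HDF5 container, validating required entries."""
    path = Path(path)
    with h5py.File(path, "r") as h5:
        for name in ("dims", "spacing", "origin", "values"):
            if name not in h5:
                raise ValidationError(f"container {path} is missing {name!r}")
        if "kind" not in h5.attrs:
            raise ValidationError(f"container {path} is missing the 'kind' attribute")
        dims = tuple(int(d) for d in h5["dims"][()])
        values = h5["values"][()]
        if values.shape[:3] != dims:
            raise ValidationError(
                f"container {path}: values shape {values.shape[:3]} != dims {dims}"
            )
        meta = json.loads(h5.attrs["meta"]) if "meta" in h5.attrs else {}
        return VoxelField(
            values=values,
            spacing=tuple(h5["spacing"][()]),
            origin=tuple(h5["origin"][()]),
            kind=str(h5.attrs["kind"]),
            meta=meta,
        )


def read_raw_field(header_path: str | Path) -> VoxelField:
    """Import a raw binary array described by a JSON header.

    The header names the raw file plus ``dims``, ``spacing``, ``origin``,
    ``kind``, ``dtype`` and ``endianness`` ("little" or "big"); the array is
    stored in C order.
    """
    header_path = Path(header_path)
    info = json.loads(header_path.read_text())
    for key in ("raw_file", "dims", "spacing", "dtype", "endianness"):
        if key not in info:
            raise ValidationError(f"raw header is missing {key!r}")
    dtype = np.dtype(info["dtype"])
    dtype = dtype.newbyteorder("<" if info["endianness"] == "little" else ">")
    raw = (header_path.parent / info["raw_file"]).read_bytes()
    values = np.frombuffer(raw, dtype=dtype)
    dims = tuple(int(d) for d in info["dims"])
    ncomp = int(info.get("components", 1))
    shape = dims + ((ncomp,) if ncomp > 1 else ())
    if values.size != int(np.prod(shape)):
        raise ValidationError(
            f"raw payload has {values.size} elements, expected {int(np.prod(shape))}"
        )
    return VoxelField(
        values=values.reshape(shape).astype(dtype.newbyteorder("=")),
        spacing=tuple(info["spacing"]),
        origin=tuple(info.get("origin", (0.0, 0.0, 0.0))),
        kind=info.get("kind", "generic"),
    )
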