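"""Volume, table and configuration I/O with an explicit coordinate contract.

Coordinate convention used throughout the package
-------------------------------------------------
* Axis order is ``(slice, row, column)`` — axis 0 is the cutting/stacking
  direction of a block-face acquisition, axes 1 and 2 are the in-plane
  image axes.
* Voxel spacing is given in nanometres in the same axis order.  The
  default acquisition geometry is strongly anisotropic: 50 nm slice
  thickness and 15 nm in-plane pixels, i.e. ``(50, 15, 15)``.
* World coordinates are voxel-centre coordinates in nm with 0-based
  indices: ``world = (index + 0.5) * spacing`` per axis.

TIFF stacks do not carry physical spacing reliably, so spacing travels in
a JSON sidecar (``<path>.meta.json``) next to the stack; NRRD files are
self-describing and preferred for archival output.  A minimal NRRD codec
(raw and gzip encodings) is implemented here.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelGrid",
    "read_volume",
    "write_volume",
    "read_config",
    "index_to_world",
    "world_to_index",
]

SIDE_CAR_SUFFIX = ".meta.json"


def index_to_world(index, spacing_nm):
    """Map 0-based voxel indices to voxel-centre world coordinates in nm."""
    index = np.asarray(index, dtype=float)
    spacing = np.asarray(spacing_nm, dtype=float)
    return (index + 0.5) * spacing


def world_to_index(world_nm, spacing_nm):
    """Map world coordinates (nm) to the nearest 0-based voxel index."""
    world = np.asarray(world_nm, dtype=float)
    spacing = np.asarray(spacing_nm, dtype=float)
    return np.round(world / spacing - 0.5).astype(np.int64)


@dataclass
class VoxelGrid:
    """A 3D array of labels or intensities with anisotropic voxel spacing.

    Parameters
    ----------
    values
        3D array.  Integer label grids use 0 as background; intensity
        grids are 8-bit.
    spacing_nm
        Voxel spacing in nm, ordered ``(slice, row, column)`` to match
        the array axes.
    """

    values: np.ndarray
    spacing_nm: tuple[float, float, float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions, got {self.values.ndim}"
            )
        spacing = tuple(float(s) for s in self.spacing_nm)
        if len(spacing) != 3:
            raise ValueError("spacing_nm must have exactly 3 entries")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if np.issubdtype(self.values.dtype, np.signedinteger) and self.values.size:
            if self.values.min() < 0:
                raise ValueError("label grid contains negative values")
        self.spacing_nm = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_nm3(self) -> float:
        s = self.spacing_nm
        return s[0] * s[1] * s[2]

    def index_to_world(self, index):
        return index_to_world(index, self.spacing_nm)

    def world_to_index(self, world_nm):
        return world_to_index(world_nm, self.spacing_nm)

    def same_geometry_as(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_nm, other.spacing_nm
        )


# ---------------------------------------------------------------------------
# NRRD (minimal subset: 3D, raw/gzip encodings, little-endian)
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8,
    "uchar": np.uint8,
    "uint16": np.uint16,
    "unsigned short": np.uint16,
    "uint32": np.uint32,
    "int16": np.int16,
    "int32": np.int32,
    "short": np.int16,
    "int": np.int32,
    "float": np.float32,
    "double": np.float64,
}
_NRRD_TYPE_NAMES = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.uint16): "uint16",
    np.dtype(np.uint32): "uint32",
    np.dtype(np.int16): "int16",
    np.dtype(np.int32): "int32",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def _read_nrrd(path: Path):
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii").strip()
            if text.startswith("#"):
                continue
            if ":" not in text:
                raise ValueError(f"{path}: malformed NRRD header line {text!r}")
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        raw = fh.read()

    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(
            f"{path}: expected 3 dimensions, got {fields.get('dimension')}"
        )
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    # NRRD lists sizes fastest axis first; numpy C-order is slowest first.
    sizes = [int(s) for s in fields["sizes"].split()]
    shape = tuple(reversed(sizes))
    encoding = fields.get("encoding", "raw")
    if encoding in ("gzip", "gz"):
        raw = gzip.decompress(raw)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = fields.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    values = np.frombuffer(raw, dtype=dt).reshape(shape).astype(dtype)

    spacing = None
    if "spacings" in fields:
        sp = [float(s) for s in fields["spacings"].split()]
        spacing = tuple(reversed(sp))
    return values, spacing


def _write_nrrd(path: Path, values: np.ndarray, spacing_nm, encoding: str = "gzip"):
    dt = np.dtype(values.dtype)
    if dt not in _NRRD_TYPE_NAMES:
        raise ValueError(f"unsupported dtype for NRRD output: {dt}")
    sizes = " ".join(str(s) for s in reversed(values.shape))
    spacings = " ".join(format(s, "g") for s in reversed(tuple(spacing_nm)))
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_TYPE_NAMES[dt]}\n"
        "dimension: 3\n"
        f"sizes: {sizes}\n"
        f"spacings: {spacings}\n"
        f"encoding: {encoding}\n"
        "endian: little\n"
        "\n"
    )
    payload = np.ascontiguousarray(values.astype(dt.newbyteorder("<"))).tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload, compresslevel=1)
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def read_volume(path, spacing_override=None) -> VoxelGrid:
    """Read a multi-page TIFF stack or NRRD file into a :class:`VoxelGrid`.

    Spacing resolution order: ``spacing_override`` argument, then the NRRD
    header or TIFF JSON sidecar.  A volume with no spacing source at all is
    an error — downstream measurements are meaningless without it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    spacing = None
    if suffix == ".nrrd":
        values, spacing = _read_nrrd(path)
    elif suffix in (".tif", ".tiff"):
        try:
            values = tifffile.imread(path)
        except Exception as exc:  # pragma: no cover - depends on tifffile message
            raise ValueError(f"unreadable TIFF file {path}: {exc}") from exc
        sidecar = path.with_name(path.name + SIDE_CAR_SUFFIX)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(meta["spacing_nm"])
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")

    if values.ndim == 2:
        raise ValueError(f"{path}: expected 3 dimensions, got 2")
    if values.ndim != 3:
        raise ValueError(f"{path}: expected 3 dimensions, got {values.ndim}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing available — supply a spacing override, "
            f"a {SIDE_CAR_SUFFIX} sidecar, or use NRRD with a spacings header"
        )
    return VoxelGrid(values, spacing)


def write_volume(grid: VoxelGrid, path) -> None:
    """Write a grid losslessly.

    Integer label grids are stored as unsigned 16-bit (labels above 65535
    are an error); 8-bit grids are stored as-is.  Spacing is persisted in
    the NRRD header or in a TIFF JSON sidecar.
    """
    path = Path(path)
    values = grid.values
    if np.issubdtype(values.dtype, np.integer):
        if values.dtype == np.uint8:
            out = values
        else:
            if values.size and int(values.max()) > 65535:
                raise ValueError(
                    f"label {int(values.max())} overflows unsigned 16-bit storage"
                )
            out = values.astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype for volume output: {values.dtype}")

    suffix = path.suffix.lower()
    if suffix == ".nrrd":
        _write_nrrd(path, out, grid.spacing_nm)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, out, compression="zlib")
        sidecar = path.with_name(path.name + SIDE_CAR_SUFFIX)
        sidecar.write_text(
            json.dumps({"spacing_nm": list(grid.spacing_nm), "axis_order": "zyx"})
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _load_yaml_mapping(path) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: config parse failure: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data


def read_config(path, kind: str | None = None):
    """Read a scene or pipeline configuration from a YAML file.

    Unknown keys are an error (no silent typo tolerance); keys that are
    absent fall back to documented defaults, so an empty file yields the
    full default configuration.  ``kind`` may be ``"scene"`` or
    ``"pipeline"``; if omitted it is taken from a top-level ``kind`` key,
    defaulting to ``"scene"``.
    """
    data = _load_yaml_mapping(path)
    file_kind = data.pop("kind", None)
    kind = kind or file_kind or "scene"
    if kind == "scene":
        from .scene_sim import SceneConfig

        return SceneConfig.from_dict(data)
    if kind == "pipeline":
        from .pipeline import PipelineConfig

        return PipelineConfig.from_dict(data)
    raise ValueError(f"unknown config kind {kind!r} (expected 'scene' or 'pipeline')")


def check_keys(data: dict, allowed, context: str) -> None:
    """Reject unknown configuration keys with a message naming them."""
    unknown = sorted(set(data) - set(allowed))
    if unknown:
        raise ValueError(
            f"unknown key(s) in {context}: {', '.join(unknown)}; "
            f"allowed keys: {', '.join(sorted(allowed))}"
        )
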