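"""Readers/writers for point clouds, rasters, reports and the pipeline config.

Formats are deliberately plain: whitespace-separated ASCII XYZ, PLY
(vertex-only, ``ascii`` or ``binary_little_endian``, double precision),
ESRI ASCII grids for rasters, CSV/JSON for tables and reports, and a
YAML key-value file for the processing configuration.  Coordinates
round-trip losslessly at double precision for XYZ and binary PLY.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chm import NODATA, RasterGrid
from .geometry import DomainError, FrustumSpec, PointCloud

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_cloud",
    "write_cloud",
    "read_xyz",
    "write_xyz",
    "read_ply",
    "write_ply",
    "read_esri_ascii",
    "write_esri_ascii",
    "read_positions_csv",
    "write_positions_csv",
    "write_observations_csv",
    "write_json_report",
]


class ParseError(ValueError):
    """Malformed input file; the message carries line/record context."""


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Processing parameters of the height-model workflow.

    Defaults are the method's standard values: 0.25 m raster
    cells, SOR over the 5 nearest neighbours, a 0.125 m plant search
    radius, a 0.500 m minimum plant height, and blunders at 3x RMSE.
    """

    cell_size: float = 0.25
    sor_k: int = 5
    sor_multiplier: float = 1.0
    sor_literal: bool = False
    plant_radius: float = 0.125
    min_plant_height: float = 0.500
    blunder_factor: float = 3.0
    trim_rings: int = 1
    aoi: tuple[float, float, float, float] = (0.0, 0.0, 2.5, 8.0)
    frustum: FrustumSpec = field(default_factory=FrustumSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cell_size, self.plant_radius, self.min_plant_height) <= 0:
            raise DomainError("lengths in the configuration must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a key-value mapping")
        frustum = raw.pop("frustum", None)
        if frustum is not None:
            raw["frustum"] = FrustumSpec(**frustum)
        if "aoi" in raw:
            raw["aoi"] = tuple(raw["aoi"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["aoi"] = list(self.aoi)
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)


# ---------------------------------------------------------------------------
# Point clouds


def write_xyz(cloud: PointCloud, path) -> None:
    """Whitespace-separated x y z, full double precision, with header."""
    with open(path, "w") as handle:
        handle.write("x y z\n")
        np.savetxt(handle, cloud.xyz, fmt="%.17g")


def read_xyz(path) -> PointCloud:
    """Read whitespace-separated XYZ; a non-numeric header row is skipped."""
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if not first.strip():
            raise ParseError(f"{path}: empty file")
        try:
            values = [float(v) for v in first.split()]
            skip = 0
            if len(values) < 3:
                raise ParseError(
                    f"{path}, line 1: expected 3 coordinates, got {len(values)}"
                )
        except ValueError:
            skip = 1  # header row
    try:
        data = pd.read_csv(
            path, sep=r"\s+", skiprows=skip, header=None, dtype=float,
            comment="#", float_precision="round_trip",
        ).to_numpy()
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if data.shape[1] < 3:
        raise ParseError(f"{path}: expected >= 3 columns, got {data.shape[1]}")
    return PointCloud(data[:, :3])


def write_ply(cloud: PointCloud, path, binary: bool = True) -> None:
    """Vertex-only PLY with double-precision x, y, z properties."""
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(cloud)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        "end_header\n"
    )
    if binary:
        with open(path, "wb") as handle:
            handle.write(header.encode("ascii"))
            handle.write(np.ascontiguousarray(cloud.xyz, dtype="<f8").tobytes())
    else:
        with open(path, "w") as handle:
            handle.write(header)
            np.savetxt(handle, cloud.xyz, fmt="%.17g")


def read_ply(path) -> PointCloud:
    """Read a vertex-only PLY (ascii or binary_little_endian)."""
    path = Path(path)
    with open(path, "rb") as handle:
        magic = handle.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        n_vertex = None
        properties: list[tuple[str, str]] = []
        in_vertex = False
        for lineno, raw in enumerate(iter(handle.readline, b""), start=2):
            tokens = raw.decode("ascii", errors="replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                properties.append((tokens[1], tokens[2]))
            elif tokens[0] == "end_header":
                break
            elif tokens[0] not in ("comment", "obj_info", "property"):
                raise ParseError(f"{path}, line {lineno}: unexpected {tokens[0]!r}")
        else:
            raise ParseError(f"{path}: header not terminated by end_header")
        if fmt not in ("ascii", "binary_little_endian"):
            raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise ParseError(f"{path}: no vertex element")
        names = [name for _, name in properties]
        if names[:3] != ["x", "y", "z"]:
            raise ParseError(f"{path}: vertex properties must start with x, y, z")
        type_map = {
            "double": "f8", "float64": "f8", "float": "f4", "float32": "f4",
            "int": "i4", "int32": "i4", "uchar": "u1", "uint8": "u1",
        }
        try:
            dtypes = [type_map[t] for t, _ in properties]
        except KeyError as exc:
            raise ParseError(f"{path}: unsupported property type {exc}") from exc
        if fmt == "binary_little_endian":
            dtype = np.dtype([(n, "<" + t) for (n, t) in zip(names, dtypes)])
            body = handle.read(dtype.itemsize * n_vertex)
            if len(body) != dtype.itemsize * n_vertex:
                raise ParseError(
                    f"{path}: truncated body "
                    f"({len(body) // dtype.itemsize}/{n_vertex} vertices)"
                )
            data = np.frombuffer(body, dtype=dtype)
        else:
            text = handle.read().decode("ascii")
            arr = np.loadtxt(_io.StringIO(text), ndmin=2)
            if arr.shape[0] != n_vertex:
                raise ParseError(
                    f"{path}: expected {n_vertex} vertices, found {arr.shape[0]}"
                )
            data = np.rec.fromarrays(arr.T[: len(names)], names=names)
        xyz = np.column_stack([data["x"], data["y"], data["z"]]).astype(float)
        return PointCloud(xyz)


_CLOUD_FORMATS = {"xyz", "ply", "ply_ascii"}


def write_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    fmt = format or ("ply" if str(path).endswith(".ply") else "xyz")
    if fmt == "xyz":
        write_xyz(cloud, path)
    elif fmt == "ply":
        write_ply(cloud, path, binary=True)
    elif fmt == "ply_ascii":
        write_ply(cloud, path, binary=False)
    else:
        raise DomainError(f"unknown cloud format {fmt!r}; options: {_CLOUD_FORMATS}")


def read_cloud(path, format: str | None = None) -> PointCloud:
    fmt = format or ("ply" if str(path).endswith(".ply") else "xyz")
    if fmt == "xyz":
        return read_xyz(path)
    if fmt in ("ply", "ply_ascii"):
        return read_ply(path)
    raise DomainError(f"unknown cloud format {fmt!r}; options: {_CLOUD_FORMATS}")


# ---------------------------------------------------------------------------
# Rasters


def write_esri_ascii(grid: RasterGrid, path) -> None:
    """ESRI ASCII grid, row-major north-up, NODATA_value -9999."""
    values = grid.values.copy()
    values[~np.isfinite(values)] = NODATA
    with open(path, "w") as handle:
        handle.write(f"ncols {grid.n_cols}\n")
        handle.write(f"nrows {grid.n_rows}\n")
        handle.write(f"xllcorner {grid.origin[0]:.10g}\n")
        handle.write(f"yllcorner {grid.origin[1]:.10g}\n")
        handle.write(f"cellsize {grid.cell_size:.10g}\n")
        handle.write(f"NODATA_value {NODATA:g}\n")
        np.savetxt(handle, values, fmt="%.10g")


def read_esri_ascii(path) -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as handle:
        for lineno in range(1, 7):
            tokens = handle.readline().split()
            if len(tokens) != 2:
                raise ParseError(f"{path}, line {lineno}: malformed header line")
            header[tokens[0].lower()] = float(tokens[1])
        missing = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"} - set(header)
        if missing:
            raise ParseError(f"{path}: header lacks {sorted(missing)}")
        values = np.loadtxt(handle, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"{path}: body shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", NODATA)
    values[values == nodata] = np.nan
    return RasterGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
    )


# ---------------------------------------------------------------------------
# Tables and reports


def read_positions_csv(path) -> pd.DataFrame:
    """Plant positions as a 3-column CSV (id, x, y)."""
    table = pd.read_csv(path)
    missing = [c for c in ("id", "x", "y") if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: positions CSV lacks columns {missing}")
    return table[["id", "x", "y"]]


def write_positions_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_observations_csv(observations, path) -> None:
    """Plant observations as CSV (id, x, y, z_max, z_min, height)."""
    rows = [
        {
            "id": i + 1,
            "x": obs.position[0],
            "y": obs.position[1],
            "z_max": obs.z_max,
            "z_min": obs.z_min,
            "height": obs.height,
        }
        for i, obs in enumerate(observations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json_report(data: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as handle:
        json.dump(data, handle, indent=2, sort_keys=True, default=_default)
        handle.write("\n")
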