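"""Reading and writing electroanatomical maps.

Two on-disk dialects are supported:

* **VTK legacy polydata** (ASCII) — the primary format, matching the
  ParaView-centred provenance of mapping-system exports.  Scalar fields
  are stored as named point-data arrays ``activation_ms``,
  ``voltage_mV``, ``cutout`` and ``wall_label`` (wall labels as integer
  codes, see :data:`eamap.surface.WALL_CODES`).  Map metadata is encoded
  as compact JSON on the VTK title line.
* **Tabular bundle** — a directory with ``vertices.csv``,
  ``triangles.csv``, ``scalars.csv`` and ``meta.json``.  Diffable plain
  text, used for test fixtures.

Vertex indexing is 0-based in both dialects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import WALL_CODES, WALL_LABELS, MapMeta, SchemaError, SurfaceMap


class FormatError(ValueError):
    """The file is not a map encoding this package understands."""


_REQUIRED = ("activation_ms", "voltage_mV")


# ---------------------------------------------------------------------
# VTK legacy polydata
# ---------------------------------------------------------------------

def write_vtk(surface: SurfaceMap, path) -> None:
    """Write a map as ASCII legacy VTK polydata."""
    path = Path(path)
    meta_json = json.dumps(surface.meta.to_dict(), separators=(",", ":"))
    wall_codes = np.array([WALL_CODES[w] for w in surface.wall_label], dtype=int)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"eamap {meta_json}\n")
        fh.write("ASCII\nDATASET POLYDATA\n")
        n = surface.n_vertices
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, surface.vertices, fmt="%.17g")
        m = surface.n_triangles
        fh.write(f"POLYGONS {m} {4 * m}\n")
        cells = np.column_stack([np.full(m, 3, dtype=np.int64), surface.triangles])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr, fmt in (
            ("activation_ms", surface.activation, "%.17g"),
            ("voltage_mV", surface.voltage, "%.17g"),
            ("cutout", surface.cutout.astype(int), "%d"),
            ("wall_label", wall_codes, "%d"),
        ):
            dtype = "double" if fmt == "%.17g" else "int"
            fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.reshape(-1, 1), fmt=fmt)


def read_vtk(path) -> SurfaceMap:
    """Read an ASCII legacy VTK polydata map."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise FormatError(f"{path}: not a legacy VTK file")
    title = lines[1] if len(lines) > 1 else ""
    meta = MapMeta()
    if title.startswith("eamap "):
        try:
            meta = MapMeta.from_dict(json.loads(title[len("eamap "):]))
        except (json.JSONDecodeError, ValueError):
            pass
    if len(lines) < 4 or lines[2].strip().upper() != "ASCII":
        raise FormatError(f"{path}: only ASCII legacy VTK is supported")
    if lines[3].strip().upper() != "DATASET POLYDATA":
        raise FormatError(f"{path}: expected DATASET POLYDATA")

    # token stream from line 4 on; keyword-driven parsing
    tokens: list[str] = []
    for ln in lines[4:]:
        tokens.extend(ln.split())
    pos = 0

    def take(k: int) -> list[str]:
        nonlocal pos
        if pos + k > len(tokens):
            raise FormatError(f"{path}: truncated file")
        out = tokens[pos:pos + k]
        pos += k
        return out

    vertices = triangles = None
    scalars: dict[str, np.ndarray] = {}
    n_points = 0
    while pos < len(tokens):
        kw = tokens[pos].upper()
        pos += 1
        if kw == "POINTS":
            n_points = int(take(1)[0])
            take(1)  # dtype
            vertices = np.array(take(3 * n_points), dtype=float).reshape(n_points, 3)
        elif kw == "POLYGONS":
            m = int(take(1)[0])
            total = int(take(1)[0])
            cells = np.array(take(total), dtype=np.int64)
            tris = []
            i = 0
            for _ in range(m):
                k = cells[i]
                if k != 3:
                    raise FormatError(f"{path}: non-triangular cell with {k} vertices")
                tris.append(cells[i + 1:i + 4])
                i += k + 1
            triangles = np.array(tris, dtype=np.int64).reshape(m, 3)
        elif kw == "POINT_DATA":
            n_pd = int(take(1)[0])
            if n_pd != n_points:
                raise FormatError(f"{path}: POINT_DATA size mismatch")
        elif kw == "SCALARS":
            name, _dtype = take(2)
            # optional numComponents then LOOKUP_TABLE <name>
            if tokens[pos].upper() != "LOOKUP_TABLE":
                take(1)
            take(2)
            scalars[name] = np.array(take(n_points), dtype=float)
        elif kw in ("LOOKUP_TABLE",):  # stray table definitions
            take(1)
        else:
            raise FormatError(f"{path}: unsupported VTK section {kw!r}")
    if vertices is None or triangles is None:
        raise FormatError(f"{path}: missing POINTS or POLYGONS section")
    return _assemble(vertices, triangles, scalars, meta, str(path))


# ---------------------------------------------------------------------
# Tabular bundle
# ---------------------------------------------------------------------

def write_bundle(surface: SurfaceMap, path) -> None:
    """Write a map as a directory of CSV files plus meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(surface.vertices, columns=["x", "y", "z"]).to_csv(
        path / "vertices.csv", index=False, float_format="%.17g"
    )
    pd.DataFrame(surface.triangles, columns=["v0", "v1", "v2"]).to_csv(
        path / "triangles.csv", index=False
    )
    pd.DataFrame(
        {
            "activation_ms": surface.activation,
            "voltage_mV": surface.voltage,
            "cutout": surface.cutout.astype(int),
            "wall_label": surface.wall_label,
        }
    ).to_csv(path / "scalars.csv", index=False, float_format="%.17g")
    units = {"coordinates": "mm", "activation_ms": "ms", "voltage_mV": "mV"}
    (path / "meta.json").write_text(
        json.dumps({**surface.meta.to_dict(), "units": units}, indent=1)
    )


def read_bundle(path) -> SurfaceMap:
    """Read a map from a tabular-bundle directory."""
    path = Path(path)
    for fname in ("vertices.csv", "triangles.csv", "scalars.csv"):
        if not (path / fname).exists():
            raise FormatError(f"{path}: bundle is missing {fname}")
    vertices = pd.read_csv(path / "vertices.csv", float_precision="round_trip")[
        ["x", "y", "z"]
    ].to_numpy(float)
    triangles = pd.read_csv(path / "triangles.csv")[["v0", "v1", "v2"]].to_numpy(np.int64)
    sc = pd.read_csv(path / "scalars.csv", float_precision="round_trip")
    scalars: dict[str, np.ndarray] = {}
    for col in sc.columns:
        scalars[col] = sc[col].to_numpy()
    meta = MapMeta()
    if (path / "meta.json").exists():
        meta = MapMeta.from_dict(json.loads((path / "meta.json").read_text()))
    return _assemble(vertices, triangles, scalars, meta, str(path))


# ---------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------

def read_map(path, format: str = None) -> SurfaceMap:
    """Read a map, auto-detecting the dialect unless ``format`` is given.

    ``format`` may be ``"vtk-polydata"`` or ``"tabular-bundle"``.
    """
    path = Path(path)
    if format is None:
        format = "tabular-bundle" if path.is_dir() else "vtk-polydata"
    if format == "vtk-polydata":
        return read_vtk(path)
    if format == "tabular-bundle":
        return read_bundle(path)
    raise ValueError(f"unknown format {format!r}")


def write_map(surface: SurfaceMap, path, format: str = None) -> None:
    path = Path(path)
    if format is None:
        format = "vtk-polydata" if path.suffix == ".vtk" else "tabular-bundle"
    if format == "vtk-polydata":
        write_vtk(surface, path)
    elif format == "tabular-bundle":
        write_bundle(surface, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _assemble(vertices, triangles, scalars, meta, origin) -> SurfaceMap:
    for name in _REQUIRED:
        if name not in scalars:
            raise SchemaError(f"{origin}: required scalar field {name!r} is missing")
    n = len(vertices)
    cutout = scalars.get("cutout")
    cutout = np.zeros(n, bool) if cutout is None else np.asarray(cutout).astype(bool)
    wall = scalars.get("wall_label")
    if wall is None:
        wall_label = np.full(n, "unlabeled", dtype=object)
    elif np.asarray(wall).dtype.kind in "ifu":
        codes = np.asarray(wall).astype(int)
        if codes.min() < 0 or codes.max() >= len(WALL_LABELS):
            raise SchemaError(f"{origin}: wall_label codes out of range")
        wall_label = np.array([WALL_LABELS[c] for c in codes], dtype=object)
    else:
        wall_label = np.asarray(wall, dtype=object)
    return SurfaceMap(
        vertices=vertices,
        triangles=triangles,
        activation=np.asarray(scalars["activation_ms"], float),
        voltage=np.asarray(scalars["voltage_mV"], float),
        cutout=cutout,
        wall_label=wall_label,
        meta=meta,
    )
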