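"""STL input/output and plain-text deviation export.

STL is read and written through :mod:`trimesh` (binary and ASCII dialects
autodetected on read).  Facet normals stored in a file are never trusted:
they are recomputed from vertex winding on write, and discarded on read.
Because STL is a triangle soup, every mesh read from disk is welded
(:func:`castmetric.mesh.weld_vertices`) so that shared edges become
topologically connected.

Deviation fields are exported as a delimited text table, one measurement
point per line: ``x  y  z  signed_distance_mm``.
"""

from __future__ import annotations

import io
import os
import struct
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import trimesh as _trimesh

from .errors import EmptyResultError, MeshFormatError
from .mesh import WELD_TOLERANCE, MeshValidationReport, TriangleMesh, validate

if TYPE_CHECKING:  # pragma: no cover
    from .comparison import DeviationField


def _sniff_dialect(path: Path) -> str:
    """Classify an STL file as 'ascii' or 'binary'.

    A file is ASCII when it starts with the token ``solid`` *and* its size is
    inconsistent with the binary layout (some binary exporters also begin
    their 80-byte header with "solid").
    """
    size = path.stat().st_size
    if size < 15:
        raise MeshFormatError(f"{path}: too short ({size} bytes) to be an STL file")
    with open(path, "rb") as fh:
        head = fh.read(84)
    if head[:5].lower() == b"solid":
        if size >= 84:
            (n,) = struct.unpack("<I", head[80:84])
            if size == 84 + 50 * n:
                return "binary"
        return "ascii"
    if size < 84:
        raise MeshFormatError(f"{path}: binary STL truncated before byte 84")
    return "binary"


def read_stl(
    path: str | os.PathLike,
    weld_tolerance: float = WELD_TOLERANCE,
    with_report: bool = False,
) -> TriangleMesh | tuple[TriangleMesh, MeshValidationReport]:
    """Read an STL file (binary or ASCII, autodetected) into a welded mesh.

    Parameters
    ----------
    path : path to an STL file
    weld_tolerance : vertex merge tolerance in mm
    with_report : also return a :class:`MeshValidationReport` of what
        welding found (duplicate vertices/faces, degenerate faces,
        watertightness).
    """
    p = Path(path)
    if not p.is_file():
        raise IOError(f"no such file: {p}")
    dialect = _sniff_dialect(p)
    if dialect == "binary":
        size = p.stat().st_size
        (n,) = struct.unpack("<I", p.read_bytes()[80:84])
        if size != 84 + 50 * n:
            raise MeshFormatError(
                f"{p}: binary STL declares {n} facets ({84 + 50 * n} bytes) "
                f"but file is {size} bytes; truncation at byte {size}"
            )
    try:
        tm = _trimesh.load(str(p), file_type="stl", process=False)
    except Exception as exc:  # malformed ASCII records surface here
        raise MeshFormatError(f"{p}: unparseable STL ({exc})") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{p}: STL contains no facets")
    raw = TriangleMesh.from_trimesh(tm)
    welded, report = validate(raw, tolerance=weld_tolerance)
    if with_report:
        return welded, report
    return welded


def write_stl(
    mesh: TriangleMesh, path: str | os.PathLike, dialect: str = "binary"
) -> None:
    """Write ``mesh`` as STL; facet normals are recomputed from winding.

    Binary is the default dialect (a binary file is 50 bytes per facet plus
    an 84-byte header).
    """
    if mesh.n_faces == 0:
        raise EmptyResultError("refusing to write an STL file with zero facets")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tm = mesh.to_trimesh()
    if dialect == "binary":
        data = _trimesh.exchange.stl.export_stl(tm)
    else:
        data = _trimesh.exchange.stl.export_stl_ascii(tm).encode()
    Path(path).write_bytes(data if isinstance(data, bytes) else data.encode())


DISTANCE_HEADER = ("x", "y", "z", "signed_distance_mm")


def export_distances(
    field: "DeviationField",
    path: str | os.PathLike,
    delimiter: str = "\t",
    decimals: int = 6,
) -> None:
    """Write one line per retained measurement point: x y z signed distance (mm)."""
    if len(field.distances) == 0:
        raise EmptyResultError("deviation field is empty")
    buf = io.StringIO()
    buf.write(delimiter.join(DISTANCE_HEADER) + "\n")
    table = np.column_stack([field.points, field.distances])
    np.savetxt(buf, table, fmt=f"%.{decimals}f", delimiter=delimiter)
    Path(path).write_text(buf.getvalue())


def read_distances(path: str | os.PathLike, delimiter: str = "\t") -> np.ndarray:
    """Re-parse a distance table; returns the (n, 4) array of x, y, z, distance."""
    arr = np.loadtxt(path, delimiter=delimiter, skiprows=1, ndmin=2)
    if arr.shape[1] != 4:
        raise MeshFormatError(f"{path}: expected 4 columns, found {arr.shape[1]}")
    return arr
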