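"""Corresponded triangle meshes: topology, vertex normals, PLY/OBJ I/O.

Dense-correspondence morphometrics represents every subject as the same
template topology deformed onto that subject's surface, so the *vertex
order* carries the anatomical correspondence: vertex ``i`` of one mesh is
homologous to vertex ``i`` of every other mesh.  Nothing in this module
ever re-orders vertices or matches by proximity.

Coordinates are millimetres throughout.  The anatomical meaning of the
three coordinate axes (medial-lateral, superior-inferior,
anterior-posterior) is data-dependent and is carried explicitly by
:class:`AxisConvention`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    CorrespondenceError,
    DegenerateGeometryError,
    MeshFormatError,
    ValidationError,
)

__all__ = [
    "AxisConvention",
    "TriangleTopology",
    "CorrespondedShape",
    "compute_vertex_normals",
    "read_mesh",
    "write_mesh",
    "read_ply",
    "write_ply",
    "read_obj",
    "write_obj",
    "read_corresponded_mesh",
    "write_corresponded_mesh",
]

ANATOMICAL_DIRECTIONS = ("medial-lateral", "superior-inferior", "anterior-posterior")


@dataclass(frozen=True)
class AxisConvention:
    """Mapping of coordinate axes (0=x, 1=y, 2=z) to anatomical directions.

    Default: x = medial-lateral, y = superior-inferior,
    z = anterior-posterior (positive z towards the viewer for an upright
    face).  Stored in model manifests so that directional statistics are
    unambiguous.
    """

    medial_lateral: int = 0
    superior_inferior: int = 1
    anterior_posterior: int = 2

    def __post_init__(self) -> None:
        axes = (self.medial_lateral, self.superior_inferior, self.anterior_posterior)
        if sorted(axes) != [0, 1, 2]:
            raise ValidationError(
                f"axis convention must be a permutation of (0, 1, 2), got {axes}"
            )

    def to_dict(self) -> dict:
        return {
            "medial-lateral": self.medial_lateral,
            "superior-inferior": self.superior_inferior,
            "anterior-posterior": self.anterior_posterior,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxisConvention":
        return cls(
            medial_lateral=int(d["medial-lateral"]),
            superior_inferior=int(d["superior-inferior"]),
            anterior_posterior=int(d["anterior-posterior"]),
        )


@dataclass(frozen=True)
class TriangleTopology:
    """Shared template topology: vertex count plus triangle connectivity.

    Invariants (checked on construction): all triangle indices lie in
    ``[0, n_vertices)`` and every vertex is referenced by at least one
    triangle, so vertex normals are defined everywhere.
    """

    n_vertices: int
    triangles: np.ndarray
    axis_convention: AxisConvention = field(default_factory=AxisConvention)

    def __post_init__(self) -> None:
        tri = np.asarray(self.triangles, dtype=np.int64)
        if tri.ndim != 2 or tri.shape[1] != 3:
            raise ValidationError(f"triangles must be (m, 3), got {tri.shape}")
        if self.n_vertices <= 0:
            raise ValidationError("n_vertices must be positive")
        if tri.size == 0:
            raise ValidationError("topology has no triangles")
        if tri.min() < 0 or tri.max() >= self.n_vertices:
            raise ValidationError("triangle indices out of range")
        referenced = np.zeros(self.n_vertices, dtype=bool)
        referenced[tri.ravel()] = True
        if not referenced.all():
            missing = np.flatnonzero(~referenced)
            raise ValidationError(
                f"{missing.size} vertices referenced by no triangle "
                f"(first: {missing[:5].tolist()})"
            )
        object.__setattr__(self, "triangles", tri)

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])

    @classmethod
    def from_mesh(
        cls, path: str | Path, axis_convention: AxisConvention | None = None
    ) -> "TriangleTopology":
        """Load the template mesh defining the shared topology."""
        vertices, triangles, _ = read_mesh(path)
        return cls(
            n_vertices=vertices.shape[0],
            triangles=triangles,
            axis_convention=axis_convention or AxisConvention(),
        )


@dataclass
class CorrespondedShape:
    """One subject's face on the shared topology, with metadata.

    ``vertices`` is a ``(k, 3)`` float64 array in mm, in template vertex
    order.  ``age`` is in decimal years; ``sex`` is ``"male"`` or
    ``"female"`` (``None`` when unknown, e.g. a bare mesh file).
    """

    vertices: np.ndarray
    subject_id: str = ""
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError(f"vertices must be (k, 3), got {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("vertex coordinates must be finite")
        if self.age is not None:
            age = float(self.age)
            if not np.isfinite(age) or age < 0:
                raise ValidationError(f"age must be finite and >= 0, got {self.age}")
            self.age = age
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def centroid_size(self) -> float:
        """Root summed squared distances of vertices from their centroid (mm)."""
        centred = self.vertices - self.vertices.mean(axis=0)
        return float(np.sqrt(np.sum(centred**2)))

    def with_vertices(self, vertices: np.ndarray) -> "CorrespondedShape":
        return dataclasses.replace(self, vertices=vertices)


# ---------------------------------------------------------------------------
# vertex normals
# ---------------------------------------------------------------------------


def compute_vertex_normals(
    vertices: np.ndarray, topology: TriangleTopology
) -> np.ndarray:
    """Unit, outward-oriented vertex normals.

    Each vertex normal is the area-weighted average of the normals of its
    incident triangles, normalised to unit length.  Orientation follows the
    triangle winding; if the winding points inward on average (mean dot
    product with the centroid-to-vertex direction negative), all normals
    are flipped so that closed convex surfaces always get outward normals.

    Raises
    ------
    DegenerateGeometryError
        If some vertex's incident triangles all have (numerically) zero
        area, so its normal is undefined.
    """
    v = np.asarray(vertices, dtype=np.float64)
    if v.shape != (topology.n_vertices, 3):
        raise ValidationError(
            f"vertices shape {v.shape} does not match topology "
            f"({topology.n_vertices}, 3)"
        )
    tri = topology.triangles
    e1 = v[tri[:, 1]] - v[tri[:, 0]]
    e2 = v[tri[:, 2]] - v[tri[:, 0]]
    face_normal = np.cross(e1, e2)  # magnitude = 2 * triangle area

    vn = np.zeros_like(v)
    for c in range(3):
        np.add.at(vn, tri[:, c], face_normal)
    norms = np.linalg.norm(vn, axis=1)
    scale = float(np.abs(v - v.mean(axis=0)).max()) or 1.0
    bad = norms <= 1e-14 * scale**2
    if bad.any():
        idx = np.flatnonzero(bad)
        raise DegenerateGeometryError(
            f"zero-area triangle umbrella at {idx.size} vertices "
            f"(first: {idx[:5].tolist()}); normals undefined there"
        )
    vn /= norms[:, None]
    outwardness = np.einsum("kc,kc->", vn, v - v.mean(axis=0))
    if outwardness < 0:
        vn = -vn
    return vn


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_SCALAR = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "<i2", "int16": "<i2",
    "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
    "float": "<f4", "float32": "<f4",
    "double": "<f8", "float64": "<f8",
}


def write_ply(
    path: str | Path,
    vertices: np.ndarray,
    triangles: np.ndarray,
    binary: bool = True,
    vertex_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a triangle mesh as PLY (binary little-endian by default).

    ``vertex_scalars`` adds extra per-vertex double properties (used for
    z-score colour maps).
    """
    path = Path(path)
    v = np.asarray(vertices, dtype=np.float64)
    tri = np.asarray(triangles, dtype=np.int32)
    scalars = vertex_scalars or {}
    for name, arr in scalars.items():
        if np.asarray(arr).shape != (v.shape[0],):
            raise ValidationError(f"scalar {name!r} must have one value per vertex")

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", "comment written by facegrowth"]
    header.append(f"element vertex {v.shape[0]}")
    for axis in "xyz":
        header.append(f"property double {axis}")
    for name in scalars:
        header.append(f"property double {name}")
    header.append(f"element face {tri.shape[0]}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    columns = [v] + [np.asarray(scalars[n], dtype=np.float64)[:, None] for n in scalars]
    vdata = np.hstack(columns)

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(vdata, dtype="<f8").tobytes())
            face_dtype = np.dtype([("n", "u1"), ("v", "<i4", (3,))])
            faces = np.empty(tri.shape[0], dtype=face_dtype)
            faces["n"] = 3
            faces["v"] = tri
            fh.write(faces.tobytes())
        else:
            lines = ["\t".join(f"{x:.17g}" for x in row) for row in vdata]
            lines += [f"3\t{a}\t{b}\t{c}" for a, b, c in tri]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def read_ply(path: str | Path):
    """Read a PLY triangle mesh.

    Returns ``(vertices, triangles, scalars)`` where ``scalars`` maps any
    extra per-vertex property names to float64 arrays.  Supports ascii and
    binary little-endian files with a single ``vertex_indices`` list
    property on faces (triangles only).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = fh.read()
    if not data.startswith(b"ply"):
        raise MeshFormatError(f"{path}: not a PLY file")
    end = data.find(b"end_header")
    if end < 0:
        raise MeshFormatError(f"{path}: missing end_header")
    header_block = data[:end].decode("ascii", errors="replace")
    body = data[end:]
    body = body[body.find(b"\n") + 1 :]

    fmt = None
    elements: list[dict] = []
    for raw in header_block.splitlines():
        parts = raw.strip().split()
        if not parts or parts[0] == "comment":
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append({"name": parts[1], "count": int(parts[2]), "props": []})
        elif parts[0] == "property":
            if not elements:
                raise MeshFormatError(f"{path}: property before element")
            if parts[1] == "list":
                elements[-1]["props"].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1]["props"].append(("scalar", parts[1], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"{path}: unsupported format {fmt!r}")

    vertices = triangles = None
    scalars: dict[str, np.ndarray] = {}
    offset = 0
    ascii_lines = body.decode("ascii").splitlines() if fmt == "ascii" else None
    line_pos = 0

    for elem in elements:
        n = elem["count"]
        if elem["name"] == "vertex":
            names = []
            dtypes = []
            for p in elem["props"]:
                if p[0] != "scalar":
                    raise MeshFormatError(f"{path}: list property on vertices")
                names.append(p[2])
                dtypes.append(_PLY_SCALAR[p[1]])
            if fmt == "ascii":
                rows = [ascii_lines[line_pos + i].split() for i in range(n)]
                line_pos += n
                table = np.array(rows, dtype=np.float64)
            else:
                dt = np.dtype([(nm, d) for nm, d in zip(names, dtypes)])
                rec = np.frombuffer(body, dtype=dt, count=n, offset=offset)
                offset += dt.itemsize * n
                table = np.column_stack([rec[nm].astype(np.float64) for nm in names])
            cols = {nm: table[:, i] for i, nm in enumerate(names)}
            for axis in "xyz":
                if axis not in cols:
                    raise MeshFormatError(f"{path}: vertex missing {axis}")
            vertices = np.column_stack([cols["x"], cols["y"], cols["z"]])
            scalars = {nm: cols[nm] for nm in names if nm not in ("x", "y", "z")}
        elif elem["name"] == "face":
            if len(elem["props"]) != 1 or elem["props"][0][0] != "list":
                raise MeshFormatError(f"{path}: unsupported face properties")
            _, count_t, item_t, _name = elem["props"][0]
            if fmt == "ascii":
                rows = []
                for i in range(n):
                    toks = ascii_lines[line_pos + i].split()
                    if int(toks[0]) != 3:
                        raise MeshFormatError(f"{path}: non-triangular face")
                    rows.append([int(t) for t in toks[1:4]])
                line_pos += n
                triangles = np.array(rows, dtype=np.int64)
            else:
                dt = np.dtype(
                    [("n", _PLY_SCALAR[count_t]), ("v", _PLY_SCALAR[item_t], (3,))]
                )
                rec = np.frombuffer(body, dtype=dt, count=n, offset=offset)
                offset += dt.itemsize * n
                if n and not (rec["n"] == 3).all():
                    raise MeshFormatError(f"{path}: non-triangular face")
                triangles = rec["v"].astype(np.int64)
        else:
            # skip unknown elements only when nothing follows that we need
            raise MeshFormatError(f"{path}: unsupported element {elem['name']!r}")

    if vertices is None:
        raise MeshFormatError(f"{path}: no vertex element")
    if triangles is None:
        triangles = np.empty((0, 3), dtype=np.int64)
    return vertices, triangles, scalars


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------


def write_obj(path: str | Path, vertices: np.ndarray, triangles: np.ndarray) -> None:
    v = np.asarray(vertices, dtype=np.float64)
    tri = np.asarray(triangles, dtype=np.int64)
    with open(path, "w") as fh:
        for row in v:
            fh.write(f"v {row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
        for a, b, c in tri + 1:  # OBJ is 1-based
            fh.write(f"f {a} {b} {c}\n")


def read_obj(path: str | Path):
    vertices, faces = [], []
    with open(path) as fh:
        for raw in fh:
            parts = raw.split()
            if not parts:
                continue
            if parts[0] == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}: malformed vertex line {raw!r}")
                vertices.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                if len(idx) != 3:
                    raise MeshFormatError(f"{path}: only triangular faces supported")
                faces.append(idx)
    if not vertices:
        raise MeshFormatError(f"{path}: no vertices")
    v = np.asarray(vertices, dtype=np.float64)
    tri = np.asarray(faces, dtype=np.int64) - 1 if faces else np.empty((0, 3), np.int64)
    return v, tri, {}


# ---------------------------------------------------------------------------
# dispatch + correspondence-checked I/O
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path):
    """Read a PLY or OBJ mesh; returns ``(vertices, triangles, scalars)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return read_ply(path)
    if suffix == ".obj":
        return read_obj(path)
    raise MeshFormatError(f"unsupported mesh format {suffix!r} ({path})")


def write_mesh(
    path: str | Path,
    vertices: np.ndarray,
    triangles: np.ndarray,
    binary: bool = True,
    vertex_scalars: dict[str, np.ndarray] | None = None,
) -> None:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply":
        write_ply(path, vertices, triangles, binary=binary, vertex_scalars=vertex_scalars)
    elif suffix == ".obj":
        if vertex_scalars:
            raise MeshFormatError("OBJ cannot carry per-vertex scalars; use PLY")
        write_obj(path, vertices, triangles)
    else:
        raise MeshFormatError(f"unsupported mesh format {suffix!r} ({path})")


def read_corresponded_mesh(
    path: str | Path,
    topology: TriangleTopology,
    subject_id: str | None = None,
    age: float | None = None,
    sex: str | None = None,
) -> CorrespondedShape:
    """Read a mesh that must lie on the shared template topology.

    Correspondence is positional: the file's vertex order is preserved
    exactly.  A vertex-count mismatch is a :class:`CorrespondenceError`.
    """
    path = Path(path)
    vertices, _triangles, _ = read_mesh(path)
    if vertices.shape[0] != topology.n_vertices:
        raise CorrespondenceError(
            f"{path}: {vertices.shape[0]} vertices but topology has "
            f"{topology.n_vertices}; not in correspondence"
        )
    return CorrespondedShape(
        vertices=vertices,
        subject_id=subject_id if subject_id is not None else path.stem,
        age=age,
        sex=sex,
    )


def write_corresponded_mesh(
    path: str | Path,
    shape: CorrespondedShape,
    topology: TriangleTopology,
    binary: bool = True,
) -> None:
    if shape.n_vertices != topology.n_vertices:
        raise CorrespondenceError(
            f"shape has {shape.n_vertices} vertices, topology "
            f"{topology.n_vertices}"
        )
    write_mesh(path, shape.vertices, topology.triangles, binary=binary)
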