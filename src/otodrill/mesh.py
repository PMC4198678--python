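"""Triangle meshes: container, PLY/STL/OBJ I/O, and geometric utilities."""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TriangleMesh:
    """Indexed triangle mesh in world millimetres.

    ``vertex_labels`` carries the material label of the occupied voxel each
    vertex was extracted from (0 when unknown); ``vertex_normals`` are unit
    vectors when present.
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    vertex_labels: np.ndarray | None = None  # (n,) int32
    vertex_normals: np.ndarray | None = None  # (n, 3) float64

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_labels is not None:
            self.vertex_labels = np.ascontiguousarray(self.vertex_labels, dtype=np.int32)
        if self.vertex_normals is not None:
            self.vertex_normals = np.ascontiguousarray(
                self.vertex_normals, dtype=np.float64
            ).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_labels is None else self.vertex_labels.copy(),
            None if self.vertex_normals is None else self.vertex_normals.copy(),
        )


def empty_mesh() -> TriangleMesh:
    return TriangleMesh(
        np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), np.zeros(0, dtype=np.int32),
        np.zeros((0, 3))
    )


# ---------------------------------------------------------------------------
# topology / geometry
# ---------------------------------------------------------------------------


def undirected_edges(mesh: TriangleMesh) -> np.ndarray:
    """Unique undirected edges as an (e, 2) sorted-index array."""
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def edge_face_counts(mesh: TriangleMesh) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for tri in mesh.faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(a, b)), int(max(a, b)))
            counts[key] = counts.get(key, 0) + 1
    return counts


def boundary_edge_count(mesh: TriangleMesh) -> int:
    """Directed edges without an opposite partner (0 for a closed, consistently
    oriented mesh)."""
    directed: dict[tuple[int, int], int] = {}
    for tri in mesh.faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
    unmatched = 0
    for (a, b), n in directed.items():
        unmatched += abs(n - directed.get((b, a), 0))
    return unmatched // 2 + sum(n - 1 for n in directed.values() if n > 1)


def is_closed(mesh: TriangleMesh) -> bool:
    """Every undirected edge shared by exactly two triangles."""
    if mesh.is_empty():
        return False
    return all(n == 2 for n in edge_face_counts(mesh).values())


def euler_characteristic(mesh: TriangleMesh) -> int:
    v = len(np.unique(mesh.faces)) if len(mesh.faces) else mesh.n_vertices
    e = len(undirected_edges(mesh))
    f = mesh.n_faces
    return v - e + f


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume by the divergence theorem (absolute value, mm^3)."""
    if mesh.is_empty():
        return 0.0
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0
    return float(abs(signed))


def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def drop_degenerate(mesh: TriangleMesh, tol: float = 0.0) -> TriangleMesh:
    """Remove zero-area triangles (and triangles with repeated indices)."""
    if mesh.is_empty():
        return mesh
    f = mesh.faces
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 2] != f[:, 0])
    keep = distinct & (triangle_areas(mesh) > tol)
    return TriangleMesh(mesh.vertices, f[keep], mesh.vertex_labels, mesh.vertex_normals)


def mean_dihedral_roughness(mesh: TriangleMesh) -> float:
    """Mean |dihedral angle - pi| over interior edges; 0 for a plane."""
    v0 = mesh.vertices[mesh.faces[:, 0]]
    v1 = mesh.vertices[mesh.faces[:, 1]]
    v2 = mesh.vertices[mesh.faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)
    norms = np.linalg.norm(fn, axis=1)
    norms[norms == 0] = 1.0
    fn = fn / norms[:, None]

    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi, tri in enumerate(mesh.faces):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(a, b)), int(max(a, b)))
            edge_to_faces.setdefault(key, []).append(fi)
    devs = []
    for fis in edge_to_faces.values():
        if len(fis) == 2:
            c = float(np.clip(np.dot(fn[fis[0]], fn[fis[1]]), -1.0, 1.0))
            # dihedral = pi - angle between normals for consistent orientation
            devs.append(np.arccos(c))
    return float(np.mean(devs)) if devs else 0.0


def compute_vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex normals, unit length (zeros for isolated)."""
    normals = np.zeros_like(mesh.vertices)
    if len(mesh.faces):
        v0 = mesh.vertices[mesh.faces[:, 0]]
        v1 = mesh.vertices[mesh.faces[:, 1]]
        v2 = mesh.vertices[mesh.faces[:, 2]]
        fn = np.cross(v1 - v0, v2 - v0)  # magnitude = 2*area
        for i in range(3):
            np.add.at(normals, mesh.faces[:, i], fn)
    lens = np.linalg.norm(normals, axis=1)
    nz = lens > 0
    normals[nz] /= lens[nz, None]
    return normals


def weld_vertices(mesh: TriangleMesh, decimals: int = 9) -> TriangleMesh:
    """Merge exactly coincident vertices (rounded to ``decimals``).

    Chunked extraction duplicates seam vertices; welding restores shared
    connectivity before smoothing or topology checks.
    """
    if mesh.n_vertices == 0:
        return mesh
    key = np.round(mesh.vertices, decimals)
    uniq, index, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    vertices = mesh.vertices[index]
    faces = inverse[mesh.faces]
    labels = mesh.vertex_labels[index] if mesh.vertex_labels is not None else None
    out = TriangleMesh(vertices, faces, labels, None)
    out = drop_degenerate(out)
    out.vertex_normals = compute_vertex_normals(out)
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _infer_mesh_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in (".ply", ".stl", ".obj"):
        return ext[1:]
    raise ValueError(f"cannot infer mesh format from {path.name!r}")


def save_mesh(
    mesh: TriangleMesh,
    path,
    format: str | None = None,
    binary: bool = False,
    vertex_colors: np.ndarray | None = None,
) -> None:
    """Write PLY (ascii or binary little-endian), STL (ascii) or OBJ.

    ``vertex_colors`` is an optional (n, 4) RGBA float array in [0, 1]; only
    PLY carries it (as uchar, alpha honoured).
    """
    path = Path(path)
    fmt = format or _infer_mesh_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _save_ply(mesh, path, binary=binary, vertex_colors=vertex_colors)
    elif fmt == "stl":
        _save_stl_ascii(mesh, path)
    elif fmt == "obj":
        _save_obj(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def load_mesh(path, format: str | None = None) -> TriangleMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_mesh_format(path)
    if fmt == "ply":
        return _load_ply(path)
    if fmt == "stl":
        return _load_stl(path)
    if fmt == "obj":
        return _load_obj(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _save_ply(mesh, path, binary=False, vertex_colors=None):
    n, m = mesh.n_vertices, mesh.n_faces
    has_normals = mesh.vertex_normals is not None and len(mesh.vertex_normals) == n
    has_colors = vertex_colors is not None
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header += ["property double x", "property double y", "property double z"]
    if has_normals:
        header += ["property double nx", "property double ny", "property double nz"]
    if has_colors:
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
            "property uchar alpha",
        ]
    header.append(f"element face {m}")
    header.append("property list uchar int vertex_indices")
    header.append("end_header")

    cols = None
    if has_colors:
        cols = np.clip(np.round(np.asarray(vertex_colors, float) * 255.0), 0, 255).astype(np.uint8)

    with open(path, "wb") as f:
        f.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            for i in range(n):
                f.write(struct.pack("<3d", *mesh.vertices[i]))
                if has_normals:
                    f.write(struct.pack("<3d", *mesh.vertex_normals[i]))
                if has_colors:
                    f.write(struct.pack("<4B", *cols[i]))
            for tri in mesh.faces:
                f.write(struct.pack("<B3i", 3, *[int(v) for v in tri]))
        else:
            lines = []
            for i in range(n):
                parts = [repr(float(v)) for v in mesh.vertices[i]]
                if has_normals:
                    parts += [repr(float(v)) for v in mesh.vertex_normals[i]]
                if has_colors:
                    parts += [str(int(v)) for v in cols[i]]
                lines.append(" ".join(parts))
            for tri in mesh.faces:
                lines.append("3 " + " ".join(str(int(v)) for v in tri))
            f.write(("\n".join(lines) + "\n").encode("ascii"))


def _load_ply(path) -> TriangleMesh:
    with open(path, "rb") as f:
        data = f.read()
    head_end = data.find(b"end_header\n")
    if head_end < 0:
        raise ValueError(f"{path}: malformed PLY (no end_header)")
    header_lines = data[:head_end].decode("ascii").splitlines()
    body = data[head_end + len(b"end_header\n"):]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    cur_props: list[tuple[str, str]] = []
    for line in header_lines:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            cur_props = []
            elements.append((tok[1], int(tok[2]), cur_props))
        elif tok[0] == "property":
            if tok[1] == "list":
                cur_props.append(("list", tok[-1]))
            else:
                cur_props.append((tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise ValueError(f"{path}: unsupported PLY format {fmt!r}")

    type_map = {
        "char": "b", "uchar": "B", "int8": "b", "uint8": "B",
        "short": "h", "ushort": "H", "int16": "h", "uint16": "H",
        "int": "i", "uint": "I", "int32": "i", "uint32": "I",
        "float": "f", "float32": "f", "double": "d", "float64": "d",
    }

    verts, norms, faces = [], [], []
    if fmt == "ascii":
        lines = body.decode("ascii").splitlines()
        pos = 0
        for name, count, props in elements:
            for _ in range(count):
                tok = lines[pos].split()
                pos += 1
                if name == "vertex":
                    vals = {}
                    ti = 0
                    for ptype, pname in props:
                        vals[pname] = float(tok[ti])
                        ti += 1
                    verts.append([vals["x"], vals["y"], vals["z"]])
                    if "nx" in vals:
                        norms.append([vals["nx"], vals["ny"], vals["nz"]])
                elif name == "face":
                    k = int(tok[0])
                    idx = [int(v) for v in tok[1 : 1 + k]]
                    for i in range(1, k - 1):
                        faces.append([idx[0], idx[i], idx[i + 1]])
    else:
        off = 0
        for name, count, props in elements:
            if name == "vertex":
                fmt_str = "<" + "".join(type_map[pt] for pt, _ in props)
                size = struct.calcsize(fmt_str)
                names = [pn for _, pn in props]
                for _ in range(count):
                    vals = dict(zip(names, struct.unpack_from(fmt_str, body, off)))
                    off += size
                    verts.append([vals["x"], vals["y"], vals["z"]])
                    if "nx" in vals:
                        norms.append([vals["nx"], vals["ny"], vals["nz"]])
            elif name == "face":
                for _ in range(count):
                    (k,) = struct.unpack_from("<B", body, off)
                    off += 1
                    idx = struct.unpack_from(f"<{k}i", body, off)
                    off += 4 * k
                    for i in range(1, k - 1):
                        faces.append([idx[0], idx[i], idx[i + 1]])

    return TriangleMesh(
        np.asarray(verts, dtype=np.float64).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        None,
        np.asarray(norms, dtype=np.float64).reshape(-1, 3) if norms else None,
    )


def _save_stl_ascii(mesh, path):
    v = mesh.vertices
    with open(path, "w") as f:
        f.write("solid otodrill\n")
        for tri in mesh.faces:
            a, b, c = v[tri[0]], v[tri[1]], v[tri[2]]
            n = np.cross(b - a, c - a)
            ln = np.linalg.norm(n)
            n = n / ln if ln > 0 else n
            f.write(f"  facet normal {float(n[0])!r} {float(n[1])!r} {float(n[2])!r}\n")
            f.write("    outer loop\n")
            for p in (a, b, c):
                f.write(f"      vertex {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
            f.write("    endloop\n  endfacet\n")
        f.write("endsolid otodrill\n")


def _load_stl(path) -> TriangleMesh:
    raw = Path(path).read_bytes()
    if raw[:5].lower() == b"solid" and b"facet" in raw[:200]:
        tris = []
        cur = []
        for line in raw.decode("ascii", "replace").splitlines():
            tok = line.split()
            if tok[:1] == ["vertex"]:
                cur.append([float(tok[1]), float(tok[2]), float(tok[3])])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
        pts = np.asarray(tris, dtype=np.float64).reshape(-1, 3)
    else:  # binary STL
        (m,) = struct.unpack_from("<I", raw, 80)
        pts = np.zeros((m * 3, 3))
        off = 84
        for t in range(m):
            vals = struct.unpack_from("<12f", raw, off)
            off += 50
            pts[3 * t : 3 * t + 3] = np.asarray(vals[3:], dtype=np.float64).reshape(3, 3)
    faces = np.arange(len(pts), dtype=np.int64).reshape(-1, 3)
    return weld_vertices(TriangleMesh(pts, faces))


def _save_obj(mesh, path):
    with open(path, "w") as f:
        for v in mesh.vertices:
            f.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        if mesh.vertex_normals is not None:
            for n in mesh.vertex_normals:
                f.write(f"vn {float(n[0])!r} {float(n[1])!r} {float(n[2])!r}\n")
            for tri in mesh.faces:
                a, b, c = (int(i) + 1 for i in tri)
                f.write(f"f {a}//{a} {b}//{b} {c}//{c}\n")
        else:
            for tri in mesh.faces:
                f.write(f"f {tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")


def _load_obj(path) -> TriangleMesh:
    verts, norms, faces = [], [], []
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "v":
            verts.append([float(v) for v in tok[1:4]])
        elif tok[0] == "vn":
            norms.append([float(v) for v in tok[1:4]])
        elif tok[0] == "f":
            idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
            for i in range(1, len(idx) - 1):
                faces.append([idx[0], idx[i], idx[i + 1]])
    return TriangleMesh(
        np.asarray(verts, dtype=np.float64).reshape(-1, 3),
        np.asarray(faces, dtype=np.int64).reshape(-1, 3),
        None,
        np.asarray(norms, dtype=np.float64).reshape(-1, 3) if len(norms) == len(verts) else None,
    )


# ---------------------------------------------------------------------------
# primitive constructors (fixtures and voxelization inputs)
# ---------------------------------------------------------------------------


def box_mesh(lo, hi) -> TriangleMesh:
    """Axis-aligned closed box [lo, hi] with outward-facing triangles."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    v = np.array(
        [
            [x0, y0, z0], [x1, y0, z0], [x1, y1, z0], [x0, y1, z0],
            [x0, y0, z1], [x1, y0, z1], [x1, y1, z1], [x0, y1, z1],
        ]
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z0), outward -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # y0 side
            [2, 3, 7], [2, 7, 6],  # y1 side
            [1, 2, 6], [1, 6, 5],  # x1 side
            [3, 0, 4], [3, 4, 7],  # x0 side
        ],
        dtype=np.int64,
    )
    return TriangleMesh(v, f)


def icosphere_mesh(center, radius: float, subdivisions: int = 3) -> TriangleMesh:
    """Subdivided icosahedron projected to a sphere; watertight by construction."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}
        vlist = [tuple(v) for v in verts]
        new_faces = []

        def mid(a: int, b: int) -> int:
            key = (min(a, b), max(a, b))
            if key not in midpoint:
                m = (np.asarray(vlist[a]) + np.asarray(vlist[b])) / 2.0
                vlist.append(tuple(m))
                midpoint[key] = len(vlist) - 1
            return midpoint[key]

        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(vlist, dtype=np.float64)
        faces = np.asarray(new_faces, dtype=np.int64)
    verts = verts / np.linalg.norm(verts, axis=1)[:, None]
    verts = np.asarray(center, float) + radius * verts
    return TriangleMesh(verts, faces)
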