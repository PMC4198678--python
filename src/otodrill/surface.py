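"""Surface extraction and smoothing.

Marching Cubes runs per chunk of the cell grid (cells = unit cubes between
voxel centers).  Chunks tile the cell grid disjointly, so every cell is
emitted by exactly one chunk and the concatenation of chunk fragments is
triangle-set-identical to a single full-volume extraction.  Voxel edits mark
the chunks owning any adjacent cell dirty; :func:`update_dirty` recomputes
only those.

Smoothing (HC-corrected Laplacian) is a global post-pass on the assembled,
welded mesh — never per chunk — so its result cannot depend on the chunk
partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .mesh import (
    TriangleMesh,
    compute_vertex_normals,
    drop_degenerate,
    empty_mesh,
)
from .volume_model import LabeledVolume

DEFAULT_CHUNK_SIZE = 16
DEFAULT_ISO = 0.5


def scalar_field(volume: LabeledVolume, field: str = "occupancy") -> np.ndarray:
    """The scalar grid to iso-surface: binary occupancy (cached) or raw density."""
    if field == "occupancy":
        key = ("occupancy", volume.version)
        if key not in volume._cache:
            volume._cache[key] = volume.occupancy()
        return volume._cache[key]
    if field == "density":
        return volume.density
    raise ValueError(f"unknown scalar field {field!r}")


def _vertex_labels(
    volume: LabeledVolume, field: np.ndarray, iso: float, verts_idx: np.ndarray
) -> np.ndarray:
    """Label each vertex with the occupied voxel adjacent to its crossing edge."""
    n = len(verts_idx)
    if n == 0:
        return np.zeros(0, dtype=np.int32)
    dims = np.asarray(volume.dims)
    lo = np.floor(verts_idx).astype(np.int64)
    frac = verts_idx - lo
    axis = np.argmax(frac, axis=1)
    p0 = np.clip(lo, 0, dims - 1)
    p1 = p0.copy()
    p1[np.arange(n), axis] = np.clip(p1[np.arange(n), axis] + 1, 0, dims[axis] - 1)
    inside0 = field[tuple(p0.T)] >= iso
    occ = np.where(inside0[:, None], p0, p1)
    other = np.where(inside0[:, None], p1, p0)
    lab = volume.label[tuple(occ.T)]
    lab_other = volume.label[tuple(other.T)]
    return np.where(lab != 0, lab, lab_other).astype(np.int32)


def marching_cubes(
    volume: LabeledVolume,
    iso: float = DEFAULT_ISO,
    region: tuple | None = None,
    field: str = "occupancy",
    method: str = "lewiner",
) -> TriangleMesh:
    """Iso-surface of a voxel box via the per-cell case-table algorithm.

    ``region`` is ``((i0, j0, k0), (i1, j1, k1))`` in voxel indices with
    exclusive upper bound; ``None`` means the whole volume.  Vertices are in
    world millimetres; an iso value outside the field range yields an empty
    mesh (not an error).

    The kernel resolves the classic face/interior ambiguities (topologically
    consistent variant), so closed occupancy fields yield closed 2-manifolds.
    """
    grid = scalar_field(volume, field)
    if region is None:
        lo = np.zeros(3, dtype=np.int64)
        hi = np.asarray(volume.dims, dtype=np.int64)
    else:
        lo = np.asarray(region[0], dtype=np.int64)
        hi = np.asarray(region[1], dtype=np.int64)
        if np.any(lo < 0) or np.any(hi > np.asarray(volume.dims)) or np.any(lo >= hi):
            raise ValueError(f"region {region} outside volume dims {volume.dims}")
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if min(sub.shape) < 2:
        return empty_mesh()
    smin, smax = sub.min(), sub.max()
    if not (smin < iso <= smax) or smin == smax:
        return empty_mesh()
    verts, faces, normals, _ = measure.marching_cubes(
        sub, level=iso, method=method, allow_degenerate=False
    )
    verts_idx = verts + lo.astype(np.float64)
    labels = _vertex_labels(volume, grid, iso, verts_idx)
    world = verts_idx * volume.spacing + volume.origin
    mesh = TriangleMesh(
        world,
        faces.astype(np.int64),
        labels,
        np.ascontiguousarray(normals, dtype=np.float64),
    )
    return drop_degenerate(mesh)


def canonical_triangles(mesh: TriangleMesh) -> np.ndarray:
    """Order-independent triangle representation: (m, 9) lexsorted array.

    Each row is a triangle's three vertex coordinates, vertices sorted
    lexicographically within the triangle, rows sorted lexicographically.
    Two meshes are triangle-set-identical iff these arrays match elementwise.
    """
    if mesh.is_empty():
        return np.zeros((0, 9))
    tris = mesh.vertices[mesh.faces]  # (m, 3, 3)
    # sort the 3 vertices of each triangle lexicographically
    key = np.round(tris, 6)
    order = np.lexsort((key[:, :, 2], key[:, :, 1], key[:, :, 0]), axis=1)
    tris = np.take_along_axis(tris, order[:, :, None], axis=1).reshape(-1, 9)
    rkey = np.round(tris, 6)
    row_order = np.lexsort([rkey[:, c] for c in range(8, -1, -1)])
    return tris[row_order]


# ---------------------------------------------------------------------------
# chunked incremental extraction
# ---------------------------------------------------------------------------


class ChunkGrid:
    """Dirty-region bookkeeping over a disjoint tiling of the cell grid.

    Each chunk owns ``chunk_size`` cells per axis and caches its extracted
    mesh fragment.  Chunk recomputation is order-independent and side-effect
    free (each fragment depends only on the volume), so it may be parallelized;
    this implementation runs serially and correctness tests compare against a
    one-shot full extraction.
    """

    def __init__(
        self,
        volume: LabeledVolume,
        chunk_size: int = DEFAULT_CHUNK_SIZE,
        iso: float = DEFAULT_ISO,
        field: str = "occupancy",
        method: str = "lewiner",
    ) -> None:
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        self.chunk_size = int(chunk_size)
        self.iso = float(iso)
        self.field = field
        self.method = method
        dims = volume.dims
        self.n_cells = tuple(max(d - 1, 0) for d in dims)
        self.n_chunks = tuple(
            max(1, math.ceil(c / self.chunk_size)) if c else 1 for c in self.n_cells
        )
        self.fragments: dict[tuple[int, int, int], TriangleMesh] = {}
        self.revision: dict[tuple[int, int, int], int] = {}
        self.dirty: set[tuple[int, int, int]] = set(self._all_keys())

    def _all_keys(self):
        ni, nj, nk = self.n_chunks
        return (
            (i, j, k) for i in range(ni) for j in range(nj) for k in range(nk)
        )

    def chunk_voxel_box(self, key) -> tuple[np.ndarray, np.ndarray]:
        """Inclusive-lo / exclusive-hi voxel box covering this chunk's cells."""
        lo = np.array([key[a] * self.chunk_size for a in range(3)], dtype=np.int64)
        hi_cell = np.array(
            [min(lo[a] + self.chunk_size, self.n_cells[a]) for a in range(3)], dtype=np.int64
        )
        return lo, hi_cell + 1

    def mark_dirty_voxel(self, idx) -> None:
        """A voxel edit dirties every chunk owning a cell incident to it."""
        i, j, k = (int(v) for v in idx)
        cs = self.chunk_size
        ranges = []
        for a, v in enumerate((i, j, k)):
            c_lo = max(v - 1, 0)
            c_hi = min(v, self.n_cells[a] - 1)
            if c_hi < c_lo:
                c_hi = c_lo = max(min(c_lo, self.n_cells[a] - 1), 0)
            ranges.append((c_lo // cs, c_hi // cs))
        for ci in range(ranges[0][0], ranges[0][1] + 1):
            for cj in range(ranges[1][0], ranges[1][1] + 1):
                for ck in range(ranges[2][0], ranges[2][1] + 1):
                    self.dirty.add((ci, cj, ck))

    def update(self, volume: LabeledVolume, edits=()) -> TriangleMesh:
        """Recompute dirty chunk fragments (after ``edits``) and reassemble."""
        for idx in edits:
            self.mark_dirty_voxel(idx)
        for key in sorted(self.dirty):
            lo, hi = self.chunk_voxel_box(key)
            self.fragments[key] = marching_cubes(
                volume, iso=self.iso, region=(lo, hi), field=self.field, method=self.method
            )
            self.revision[key] = self.revision.get(key, 0) + 1
        self.dirty.clear()
        return self.assemble()

    def assemble(self) -> TriangleMesh:
        """Concatenate cached fragments (seam vertices duplicated, not welded)."""
        frags = [f for f in self.fragments.values() if not f.is_empty()]
        if not frags:
            return empty_mesh()
        verts = np.concatenate([f.vertices for f in frags])
        offsets = np.cumsum([0] + [f.n_vertices for f in frags[:-1]])
        faces = np.concatenate([f.faces + off for f, off in zip(frags, offsets)])
        labels = np.concatenate(
            [
                f.vertex_labels
                if f.vertex_labels is not None
                else np.zeros(f.n_vertices, np.int32)
                for f in frags
            ]
        )
        normals = np.concatenate(
            [
                f.vertex_normals
                if f.vertex_normals is not None
                else np.zeros((f.n_vertices, 3))
                for f in frags
            ]
        )
        return TriangleMesh(verts, faces, labels, normals)


def update_dirty(chunks: ChunkGrid, volume: LabeledVolume, edits=()) -> TriangleMesh:
    """Incrementally refresh the chunked surface after voxel ``edits``.

    The returned mesh equals a full-volume :func:`marching_cubes` call as a
    sorted triangle set; an empty edit set with no dirty chunks is a no-op.
    """
    return chunks.update(volume, edits)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothingParams:
    alpha: float = 0.0
    beta: float = 0.5
    iterations: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


def _neighbor_operator(mesh: TriangleMesh):
    """Sparse vertex adjacency and degree vector."""
    from scipy import sparse

    from .mesh import undirected_edges

    n = mesh.n_vertices
    e = undirected_edges(mesh)
    if len(e) == 0:
        return sparse.csr_matrix((n, n)), np.zeros(n)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    a = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(a.sum(axis=1)).ravel()
    return a, deg


def _neighbor_average(a, deg, p: np.ndarray) -> np.ndarray:
    """Mean of neighbor positions; isolated vertices keep their own position."""
    avg = a @ p
    has = deg > 0
    avg[has] /= deg[has, None]
    avg[~has] = p[~has]
    return avg


def laplacian_smooth(mesh: TriangleMesh, iterations: int = 10) -> TriangleMesh:
    """Plain iterative neighbor-average smoothing (shrinks enclosed volume)."""
    out = mesh.copy()
    if iterations <= 0 or out.n_vertices == 0:
        return out
    a, deg = _neighbor_operator(out)
    p = out.vertices
    for _ in range(iterations):
        p = _neighbor_average(a, deg, p)
    out.vertices = p
    out.vertex_normals = compute_vertex_normals(out)
    return out


def hc_smooth(mesh: TriangleMesh, params: SmoothingParams = SmoothingParams()) -> TriangleMesh:
    """HC-corrected Laplacian smoothing (Vollmer-style back-projection).

    Each iteration takes a neighbor-average step, then subtracts the
    blended drift ``b = p_new - (alpha*original + (1-alpha)*previous)``
    together with its neighborhood average, weighted by ``beta``.  This
    suppresses the volume shrinkage of plain Laplacian smoothing while
    preserving vertex count and connectivity exactly.
    """
    out = mesh.copy()
    if params.iterations <= 0 or out.n_vertices == 0:
        return out
    a, deg = _neighbor_operator(out)
    o = out.vertices.copy()
    p = out.vertices.copy()
    alpha, beta = params.alpha, params.beta
    for _ in range(params.iterations):
        q = p
        p = _neighbor_average(a, deg, q)
        b = p - (alpha * o + (1.0 - alpha) * q)
        p = p - (beta * b + (1.0 - beta) * _neighbor_average(a, deg, b))
    out.vertices = p
    out.vertex_normals = compute_vertex_normals(out)
    return out
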