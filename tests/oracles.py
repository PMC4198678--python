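"""Independent brute-force oracles used by the test-suite.

These deliberately avoid the code paths they check: point-in-mesh is a
z-ray parity cast (the library uses winding numbers), sphere membership is
recomputed from raw coordinates, and the 'full recompute' surface oracle is
a single whole-volume extraction compared against incremental updates.
"""

import numpy as np

# ray origin jitter: large vs float rounding, far below geometric clearances,
# so edge-on ray hits cannot flip parity on the meshes tests use
_JITTER = (1.043e-9, 0.731e-9)


def ray_parity_inside(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Point-in-mesh by counting +z ray crossings (odd = inside)."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    px = points[:, 0] + _JITTER[0]
    py = points[:, 1] + _JITTER[1]
    pz = points[:, 2]
    crossings = np.zeros(len(points), dtype=np.int64)
    for tri in faces:
        a, b, c = vertices[tri[0]], vertices[tri[1]], vertices[tri[2]]
        det = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(det) < 1e-15:
            continue  # projected-degenerate (vertical) triangle
        dx = px - a[0]
        dy = py - a[1]
        u = (dx * (c[1] - a[1]) - dy * (c[0] - a[0])) / det
        v = (dy * (b[0] - a[0]) - dx * (b[1] - a[1])) / det
        inside2d = (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0)
        z = a[2] + u * (b[2] - a[2]) + v * (c[2] - a[2])
        crossings += (inside2d & (z > pz)).astype(np.int64)
    return (crossings % 2) == 1


def voxel_centers(volume) -> tuple[np.ndarray, np.ndarray]:
    """All voxel indices and their world-mm centers as flat arrays."""
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in volume.dims], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    return idx, volume.origin + idx * volume.spacing


def sphere_voxel_indices(volume, center, radius) -> set:
    """Voxel indices whose centers lie within ``radius`` of ``center``."""
    idx, centers = voxel_centers(volume)
    d2 = ((centers - np.asarray(center, float)) ** 2).sum(axis=1)
    return {tuple(i) for i in idx[d2 <= radius * radius]}


def sphere_union_removable(volume, materials, centers, radius) -> set:
    """Brute-force union of per-step spheres over initially drillable voxels."""
    out = set()
    drillable = {
        lab for lab in materials.labels() if materials[lab].drillable
    }
    idx, world = voxel_centers(volume)
    labels = volume.label[tuple(idx.T)]
    keep = np.isin(labels, list(drillable))
    idx, world = idx[keep], world[keep]
    for c in centers:
        d2 = ((world - np.asarray(c, float)) ** 2).sum(axis=1)
        out.update(tuple(i) for i in idx[d2 <= radius * radius])
    return out


def assert_triangle_sets_equal(tris_a: np.ndarray, tris_b: np.ndarray, atol: float = 1e-12):
    """Compare canonical (m, 9) triangle arrays elementwise within atol."""
    assert tris_a.shape == tris_b.shape, (
        f"triangle counts differ: {tris_a.shape[0]} vs {tris_b.shape[0]}"
    )
    if tris_a.size:
        worst = float(np.abs(tris_a - tris_b).max())
        assert worst <= atol, f"max coordinate deviation {worst} > {atol}"
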