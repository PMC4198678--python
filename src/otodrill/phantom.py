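"""Synthetic temporal-bone-like phantoms with analytic ground truth.

No deposited imaging exists for the original specimens, so tests and demos
run on generated volumes that mimic the relevant structure classes: a
cortical shell, trabecular interior, an air-cell (void) system, tubular
vessel/nerve analogues, a thin dural-plate analogue and small ossicle-like
ellipsoids.  Every primitive is placed analytically and the emitted ground
truth records exact per-label voxel counts plus analytic volumes, so tests
can re-derive everything by exhaustive per-voxel recomputation.

Air cells are placed by seeded dart-throwing with overlap rejection (against
each other and against embedded structures), keeping per-sphere voxel counts
exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume_model import LabeledVolume, Material, MaterialTable

# canonical label assignment for generated phantoms
LABEL_CORTICAL = 1
LABEL_TRABECULAR = 2
LABEL_VESSEL = 3
LABEL_NERVE = 4
LABEL_PLATE = 5
LABEL_OSSICLE = 6

DEFAULT_DENSITIES = {
    LABEL_CORTICAL: 1800.0,
    LABEL_TRABECULAR: 700.0,
    LABEL_VESSEL: 60.0,
    LABEL_NERVE: 40.0,
    LABEL_PLATE: 1200.0,
    LABEL_OSSICLE: 2000.0,
}


class PhantomError(RuntimeError):
    """Infeasible primitive placement (named in the message)."""


def default_materials() -> MaterialTable:
    """Material table covering every label a phantom can emit."""
    return MaterialTable(
        {
            LABEL_CORTICAL: Material(
                name="cortical_bone", color=(0.93, 0.90, 0.80, 1.0), stiffness=0.8,
                drillable=True, ease=1.0, density=DEFAULT_DENSITIES[LABEL_CORTICAL],
            ),
            LABEL_TRABECULAR: Material(
                name="trabecular_bone", color=(0.85, 0.78, 0.62, 1.0), stiffness=0.5,
                drillable=True, ease=1.5, density=DEFAULT_DENSITIES[LABEL_TRABECULAR],
            ),
            LABEL_VESSEL: Material(
                name="vessel", color=(0.80, 0.10, 0.10, 1.0), stiffness=0.3,
                drillable=False, density=DEFAULT_DENSITIES[LABEL_VESSEL],
            ),
            LABEL_NERVE: Material(
                name="nerve", color=(0.95, 0.92, 0.30, 1.0), stiffness=0.3,
                drillable=False, density=DEFAULT_DENSITIES[LABEL_NERVE],
            ),
            LABEL_PLATE: Material(
                name="dural_plate", color=(0.60, 0.70, 0.90, 0.8), transparency=0.2,
                stiffness=0.6, drillable=True, density=DEFAULT_DENSITIES[LABEL_PLATE],
            ),
            LABEL_OSSICLE: Material(
                name="ossicle", color=(0.98, 0.80, 0.85, 1.0), stiffness=0.9,
                drillable=True, ease=0.7, density=DEFAULT_DENSITIES[LABEL_OSSICLE],
            ),
        }
    )


@dataclass(frozen=True)
class TubeSpec:
    """Tubular structure along a polyline (vessel / nerve analogue)."""

    path: tuple  # sequence of world-mm points
    radius: float  # mm
    label: int = LABEL_VESSEL


@dataclass(frozen=True)
class PlateSpec:
    """Thin axis-aligned plate (dural-plate analogue)."""

    axis: int  # normal axis (0/1/2)
    lo_mm: float  # world-mm slab bounds along the axis
    hi_mm: float
    label: int = LABEL_PLATE


@dataclass(frozen=True)
class BlobSpec:
    """Small solid ellipsoid (ossicle analogue)."""

    center: tuple  # world mm
    semi_axes: tuple  # mm
    label: int = LABEL_OSSICLE


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shell_kind: str = "ellipsoid"  # or "box"
    shell_thickness_mm: float = 2.0
    cortical_density: float = DEFAULT_DENSITIES[LABEL_CORTICAL]
    trabecular_density: float = DEFAULT_DENSITIES[LABEL_TRABECULAR]
    n_air_cells: int = 0
    air_cell_radius_mm: tuple[float, float] = (0.6, 1.2)
    tubes: tuple[TubeSpec, ...] = ()
    plates: tuple[PlateSpec, ...] = ()
    blobs: tuple[BlobSpec, ...] = ()
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "dims": list(self.dims),
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "shell_kind": self.shell_kind,
            "shell_thickness_mm": self.shell_thickness_mm,
            "cortical_density": self.cortical_density,
            "trabecular_density": self.trabecular_density,
            "n_air_cells": self.n_air_cells,
            "air_cell_radius_mm": list(self.air_cell_radius_mm),
            "tubes": [
                {"path": [list(p) for p in t.path], "radius": t.radius, "label": t.label}
                for t in self.tubes
            ],
            "plates": [
                {"axis": p.axis, "lo_mm": p.lo_mm, "hi_mm": p.hi_mm, "label": p.label}
                for p in self.plates
            ],
            "blobs": [
                {"center": list(b.center), "semi_axes": list(b.semi_axes), "label": b.label}
                for b in self.blobs
            ],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            dims=tuple(d.get("dims", (64, 64, 64))),
            spacing=tuple(d.get("spacing", (0.5, 0.5, 0.5))),
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
            shell_kind=d.get("shell_kind", "ellipsoid"),
            shell_thickness_mm=float(d.get("shell_thickness_mm", 2.0)),
            cortical_density=float(d.get("cortical_density", DEFAULT_DENSITIES[LABEL_CORTICAL])),
            trabecular_density=float(
                d.get("trabecular_density", DEFAULT_DENSITIES[LABEL_TRABECULAR])
            ),
            n_air_cells=int(d.get("n_air_cells", 0)),
            air_cell_radius_mm=tuple(d.get("air_cell_radius_mm", (0.6, 1.2))),
            tubes=tuple(
                TubeSpec(
                    path=tuple(tuple(p) for p in t["path"]),
                    radius=float(t["radius"]),
                    label=int(t.get("label", LABEL_VESSEL)),
                )
                for t in d.get("tubes", ())
            ),
            plates=tuple(
                PlateSpec(
                    axis=int(p["axis"]), lo_mm=float(p["lo_mm"]), hi_mm=float(p["hi_mm"]),
                    label=int(p.get("label", LABEL_PLATE)),
                )
                for p in d.get("plates", ())
            ),
            blobs=tuple(
                BlobSpec(
                    center=tuple(b["center"]), semi_axes=tuple(b["semi_axes"]),
                    label=int(b.get("label", LABEL_OSSICLE)),
                )
                for b in d.get("blobs", ())
            ),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def _voxel_centers(dims, spacing, origin):
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    return (
        origin[0] + ii * spacing[0],
        origin[1] + jj * spacing[1],
        origin[2] + kk * spacing[2],
    )


def _segment_distance_sq(px, py, pz, a, b):
    """Squared distance from grid points to the segment a-b."""
    ab = b - a
    ab2 = float(np.dot(ab, ab))
    dx, dy, dz = px - a[0], py - a[1], pz - a[2]
    if ab2 < 1e-24:
        return dx * dx + dy * dy + dz * dz
    t = np.clip((dx * ab[0] + dy * ab[1] + dz * ab[2]) / ab2, 0.0, 1.0)
    cx, cy, cz = dx - t * ab[0], dy - t * ab[1], dz - t * ab[2]
    return cx * cx + cy * cy + cz * cz


def _point_to_polyline_distance(point, path) -> float:
    p = np.asarray(point, float)
    best = np.inf
    for a, b in zip(path[:-1], path[1:]):
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        ab = b - a
        ab2 = float(np.dot(ab, ab))
        t = 0.0 if ab2 < 1e-24 else float(np.clip(np.dot(p - a, ab) / ab2, 0.0, 1.0))
        best = min(best, float(np.linalg.norm(p - (a + t * ab))))
    if len(path) == 1:
        best = float(np.linalg.norm(p - np.asarray(path[0], float)))
    return best


def make_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, MaterialTable, dict]:
    """Deterministic labeled phantom + material table + analytic ground truth."""
    dims = tuple(int(v) for v in spec.dims)
    spacing = np.asarray(spec.spacing, float)
    origin = np.asarray(spec.origin, float)
    if spec.shell_kind not in ("ellipsoid", "box"):
        raise ValueError(f"unknown shell kind {spec.shell_kind!r}")
    rng = np.random.default_rng(spec.seed)
    px, py, pz = _voxel_centers(dims, spacing, origin)
    extent = (np.asarray(dims) - 1) * spacing
    center = origin + extent / 2.0

    # --- shell and interior -------------------------------------------------
    margin = np.max(spacing)  # keep the occupied set off the volume boundary
    if spec.shell_kind == "ellipsoid":
        semi = extent / 2.0 - margin
        if np.any(semi <= spec.shell_thickness_mm):
            raise PhantomError("shell: thickness exceeds ellipsoid semi-axes")
        q_out = (
            ((px - center[0]) / semi[0]) ** 2
            + ((py - center[1]) / semi[1]) ** 2
            + ((pz - center[2]) / semi[2]) ** 2
        )
        semi_in = semi - spec.shell_thickness_mm
        q_in = (
            ((px - center[0]) / semi_in[0]) ** 2
            + ((py - center[1]) / semi_in[1]) ** 2
            + ((pz - center[2]) / semi_in[2]) ** 2
        )
        outer = q_out <= 1.0
        inner = q_in <= 1.0
        gt_shell = {
            "kind": "ellipsoid",
            "outer_semi_axes_mm": [float(v) for v in semi],
            "inner_semi_axes_mm": [float(v) for v in semi_in],
            "center_mm": [float(v) for v in center],
            "analytic_outer_volume_mm3": float(4.0 / 3.0 * np.pi * np.prod(semi)),
            "analytic_inner_volume_mm3": float(4.0 / 3.0 * np.pi * np.prod(semi_in)),
        }
    else:  # box shell
        lo = origin + margin
        hi = origin + extent - margin
        t = spec.shell_thickness_mm
        outer = (
            (px >= lo[0]) & (px <= hi[0]) & (py >= lo[1]) & (py <= hi[1])
            & (pz >= lo[2]) & (pz <= hi[2])
        )
        inner = (
            (px >= lo[0] + t) & (px <= hi[0] - t) & (py >= lo[1] + t) & (py <= hi[1] - t)
            & (pz >= lo[2] + t) & (pz <= hi[2] - t)
        )
        gt_shell = {
            "kind": "box",
            "lo_mm": [float(v) for v in lo],
            "hi_mm": [float(v) for v in hi],
            "thickness_mm": t,
        }

    label = np.zeros(dims, dtype=np.int32)
    density = np.zeros(dims, dtype=np.float64)
    shell_mask = outer & ~inner
    label[shell_mask] = LABEL_CORTICAL
    density[shell_mask] = spec.cortical_density
    label[inner] = LABEL_TRABECULAR
    density[inner] = spec.trabecular_density

    # --- embedded structures (they overwrite trabecular space) --------------
    structure_keepout: list[tuple] = []  # (kind, payload, clearance radius)
    for t_i, tube in enumerate(spec.tubes):
        d2 = np.full(dims, np.inf)
        path = [np.asarray(p, float) for p in tube.path]
        if len(path) < 2:
            raise PhantomError(f"tube {t_i}: path needs at least 2 points")
        for a, b in zip(path[:-1], path[1:]):
            d2 = np.minimum(d2, _segment_distance_sq(px, py, pz, a, b))
        mask = (d2 <= tube.radius**2) & inner
        if not mask.any():
            raise PhantomError(f"tube {t_i} (label {tube.label}) lies outside the interior")
        label[mask] = tube.label
        density[mask] = DEFAULT_DENSITIES.get(tube.label, 50.0)
        structure_keepout.append(("tube", tube, tube.radius))
    for p_i, plate in enumerate(spec.plates):
        coord = (px, py, pz)[plate.axis]
        mask = (coord >= plate.lo_mm) & (coord <= plate.hi_mm) & inner
        if not mask.any():
            raise PhantomError(f"plate {p_i} (label {plate.label}) lies outside the interior")
        label[mask] = plate.label
        density[mask] = DEFAULT_DENSITIES.get(plate.label, 1200.0)
        structure_keepout.append(("plate", plate, 0.0))
    for b_i, blob in enumerate(spec.blobs):
        c = np.asarray(blob.center, float)
        s = np.asarray(blob.semi_axes, float)
        q = (
            ((px - c[0]) / s[0]) ** 2 + ((py - c[1]) / s[1]) ** 2 + ((pz - c[2]) / s[2]) ** 2
        )
        mask = (q <= 1.0) & inner
        if not mask.any():
            raise PhantomError(f"blob {b_i} (label {blob.label}) lies outside the interior")
        label[mask] = blob.label
        density[mask] = DEFAULT_DENSITIES.get(blob.label, 2000.0)
        structure_keepout.append(("blob", blob, float(np.max(s))))

    # --- air cells: seeded dart throwing, overlap-rejected -------------------
    air_cells: list[dict] = []
    if spec.n_air_cells > 0:
        r_lo, r_hi = spec.air_cell_radius_mm
        if spec.shell_kind == "ellipsoid":
            placement_semi = semi_in
        max_tries = 200
        for c_i in range(spec.n_air_cells):
            placed = False
            for _ in range(max_tries):
                r = float(rng.uniform(r_lo, r_hi))
                u = rng.uniform(-1.0, 1.0, size=3)
                if spec.shell_kind == "ellipsoid":
                    if np.any(placement_semi - r <= 0):
                        continue
                    cand = center + u * (placement_semi - r) * 0.95
                    q = np.sum(((cand - center) / (placement_semi - r)) ** 2)
                    if q > 1.0:
                        continue
                else:
                    lo_in = origin + margin + spec.shell_thickness_mm + r
                    hi_in = origin + extent - margin - spec.shell_thickness_mm - r
                    cand = lo_in + (u + 1.0) / 2.0 * (hi_in - lo_in)
                ok = True
                for prev in air_cells:
                    if np.linalg.norm(cand - np.asarray(prev["center_mm"])) <= r + prev["radius_mm"]:
                        ok = False
                        break
                if ok:
                    for kind, payload, clearance in structure_keepout:
                        if kind == "tube":
                            d = _point_to_polyline_distance(cand, [np.asarray(p) for p in payload.path])
                            if d <= r + clearance:
                                ok = False
                                break
                        elif kind == "plate":
                            c_ax = cand[payload.axis]
                            if payload.lo_mm - r <= c_ax <= payload.hi_mm + r:
                                ok = False
                                break
                        elif kind == "blob":
                            if np.linalg.norm(cand - np.asarray(payload.center)) <= r + clearance:
                                ok = False
                                break
                if not ok:
                    continue
                d2 = (px - cand[0]) ** 2 + (py - cand[1]) ** 2 + (pz - cand[2]) ** 2
                sphere = d2 <= r * r
                mask = sphere & inner & (label == LABEL_TRABECULAR)
                if not np.array_equal(mask, sphere):
                    continue  # clipped by shell or a structure label; retry elsewhere
                label[mask] = 0
                density[mask] = 0.0
                air_cells.append(
                    {
                        "center_mm": [float(v) for v in cand],
                        "radius_mm": r,
                        "voxel_count": int(mask.sum()),
                        "analytic_volume_mm3": float(4.0 / 3.0 * np.pi * r**3),
                    }
                )
                placed = True
                break
            if not placed:
                raise PhantomError(
                    f"air cell {c_i}: no non-colliding placement found in {max_tries} tries"
                )

    volume = LabeledVolume(density=density, label=label, spacing=spacing, origin=origin)
    materials = default_materials()
    counts = {int(l): int((label == l).sum()) for l in np.unique(label) if l != 0}
    ground_truth = {
        "spec": spec.to_dict(),
        "shell": gt_shell,
        "label_voxel_counts": {str(k): v for k, v in sorted(counts.items())},
        "void_voxel_count": int((label == 0).sum()),
        "air_cells": air_cells,
        "air_cell_void_voxels": int(sum(c["voxel_count"] for c in air_cells)),
        "voxel_volume_mm3": float(np.prod(spacing)),
    }
    return volume, materials, ground_truth


# ---------------------------------------------------------------------------
# simple analytic fixtures
# ---------------------------------------------------------------------------


def make_sphere_phantom(
    radius_mm: float = 20.0,
    spacing: float = 0.5,
    margin_voxels: int = 3,
    density: float = 1500.0,
    label: int = LABEL_CORTICAL,
) -> tuple[LabeledVolume, dict]:
    """Solid ball centered in the grid; ground truth = analytic sphere volume."""
    n = int(2 * np.ceil(radius_mm / spacing)) + 2 * margin_voxels + 1
    dims = (n, n, n)
    sp = np.array([spacing] * 3)
    origin = np.zeros(3)
    c = (np.asarray(dims) - 1) / 2.0 * sp
    px, py, pz = _voxel_centers(dims, sp, origin)
    d2 = (px - c[0]) ** 2 + (py - c[1]) ** 2 + (pz - c[2]) ** 2
    inside = d2 <= radius_mm**2
    vol = LabeledVolume(
        density=np.where(inside, density, 0.0),
        label=np.where(inside, np.int32(label), np.int32(0)),
        spacing=sp,
        origin=origin,
    )
    gt = {
        "center_mm": [float(v) for v in c],
        "radius_mm": radius_mm,
        "analytic_volume_mm3": float(4.0 / 3.0 * np.pi * radius_mm**3),
        "voxel_count": int(inside.sum()),
    }
    return vol, gt


def make_torus_phantom(
    major_mm: float = 6.0,
    minor_mm: float = 2.5,
    spacing: float = 0.5,
    margin_voxels: int = 3,
    density: float = 1500.0,
    label: int = LABEL_CORTICAL,
) -> tuple[LabeledVolume, dict]:
    """Solid torus (genus 1) about the z axis through the grid center."""
    half = major_mm + minor_mm
    n = int(2 * np.ceil(half / spacing)) + 2 * margin_voxels + 1
    nz = int(2 * np.ceil(minor_mm / spacing)) + 2 * margin_voxels + 1
    dims = (n, n, nz)
    sp = np.array([spacing] * 3)
    origin = np.zeros(3)
    c = (np.asarray(dims) - 1) / 2.0 * sp
    px, py, pz = _voxel_centers(dims, sp, origin)
    rho = np.sqrt((px - c[0]) ** 2 + (py - c[1]) ** 2)
    inside = (rho - major_mm) ** 2 + (pz - c[2]) ** 2 <= minor_mm**2
    vol = LabeledVolume(
        density=np.where(inside, density, 0.0),
        label=np.where(inside, np.int32(label), np.int32(0)),
        spacing=sp,
        origin=origin,
    )
    gt = {
        "center_mm": [float(v) for v in c],
        "major_mm": major_mm,
        "minor_mm": minor_mm,
        "analytic_volume_mm3": float(2.0 * np.pi**2 * major_mm * minor_mm**2),
        "voxel_count": int(inside.sum()),
        "genus": 1,
    }
    return vol, gt


def make_wall_phantom(
    thickness_voxels: int,
    nx: int = 32,
    ny: int = 32,
    nz: int = 32,
    spacing: float = 0.5,
    channel_width: int | None = None,
    density: float = 1500.0,
    label: int = LABEL_CORTICAL,
) -> LabeledVolume:
    """Flat slab of ``thickness_voxels`` z-layers centered in z.

    With ``channel_width`` set, a straight channel of that voxel width in x
    is carved through the full slab thickness along the whole y extent — the
    constrained-space fixture (channel voxel count = width * thickness * ny).
    """
    if thickness_voxels < 1:
        raise ValueError("wall thickness must be >= 1 voxel")
    density_grid = np.zeros((nx, ny, nz), dtype=np.float64)
    label_grid = np.zeros((nx, ny, nz), dtype=np.int32)
    z0 = (nz - thickness_voxels) // 2
    label_grid[:, :, z0 : z0 + thickness_voxels] = label
    density_grid[:, :, z0 : z0 + thickness_voxels] = density
    if channel_width is not None:
        if channel_width < 1:
            raise ValueError("channel width must be >= 1 voxel")
        x0 = (nx - channel_width) // 2
        label_grid[x0 : x0 + channel_width, :, z0 : z0 + thickness_voxels] = 0
        density_grid[x0 : x0 + channel_width, :, z0 : z0 + thickness_voxels] = 0.0
    return LabeledVolume(
        density=density_grid,
        label=label_grid,
        spacing=np.array([spacing] * 3),
        origin=np.zeros(3),
    )


def save_ground_truth(ground_truth: dict, path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=2, sort_keys=True))
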