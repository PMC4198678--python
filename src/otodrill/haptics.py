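"""Position-locking proxy force rendering, with a virtual-spring baseline.

The device position may penetrate occupied voxels freely; the *proxy* never
does.  Each tick the proxy marches from its previous position toward the
device in sub-voxel steps, stops at the last free sample when it would enter
an occupied voxel, and slides the residual motion along the local tangent
plane (up to 3 slide iterations).  The rendered force is a spring between
proxy and device using the contacted material's stiffness, clamped to the
device's maximum force.

The penalty-method baseline (:func:`spring_force_baseline`) pushes the device
out toward the *nearest* free space — which, past the midplane of a thin
wall, is the far side: the classic pop-through failure the proxy avoids.

The exact mathematics of the original position-locking scheme are not public;
this march-and-slide proxy is an interpretation chosen to satisfy the
properties attributed to it (per-iteration bit location, fine-feature
navigation, stability in tightly constrained spaces).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .drilling import DrillBit, ExposureField, UndoRecord, drill_segment
from .volume_model import LabeledVolume, MaterialTable

log = logging.getLogger(__name__)

DEFAULT_MAX_FORCE = 3.3  # N; typical entry-level device clamp (configurable)
MAX_SLIDE_ITERATIONS = 3


@dataclass
class HapticState:
    """Device/proxy pose and rendered force at one simulated tick."""

    device_pos: np.ndarray
    proxy_pos: np.ndarray
    pedal: bool = False
    t: float = 0.0
    force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contact_label: int | None = None
    max_force: float = DEFAULT_MAX_FORCE

    def __post_init__(self) -> None:
        self.device_pos = np.asarray(self.device_pos, dtype=np.float64).reshape(3)
        self.proxy_pos = np.asarray(self.proxy_pos, dtype=np.float64).reshape(3)
        self.force = np.asarray(self.force, dtype=np.float64).reshape(3)


# ---------------------------------------------------------------------------
# cached derived fields
# ---------------------------------------------------------------------------


def _smoothed_occupancy(volume: LabeledVolume) -> np.ndarray:
    """Occupancy box-filtered over a 1-voxel neighborhood (normal estimation)."""
    key = ("occ_smooth", volume.version)
    if key not in volume._cache:
        volume._cache[key] = ndimage.uniform_filter(volume.occupancy(), size=3, mode="nearest")
    return volume._cache[key]


def _free_space_edt(volume: LabeledVolume):
    """Distance (mm) from each occupied voxel to the nearest free voxel, with
    the index of that free voxel (for the penalty baseline)."""
    key = ("edt", volume.version)
    if key not in volume._cache:
        occ = volume.label != 0
        dist, indices = ndimage.distance_transform_edt(
            occ, sampling=volume.spacing, return_indices=True
        )
        volume._cache[key] = (dist, indices)
    return volume._cache[key]


def surface_normal(volume: LabeledVolume, voxel_idx, fallback_point=None) -> np.ndarray:
    """Outward unit normal at a voxel, from the smoothed-occupancy gradient.

    Falls back to the direction from the voxel center toward
    ``fallback_point`` when the gradient vanishes (e.g. deep inside bulk).
    """
    occ = _smoothed_occupancy(volume)
    i, j, k = (int(v) for v in voxel_idx)
    dims = volume.dims
    g = np.zeros(3)
    for a, (n, v) in enumerate(zip(dims, (i, j, k))):
        lo = [i, j, k]
        hi = [i, j, k]
        lo[a] = max(v - 1, 0)
        hi[a] = min(v + 1, n - 1)
        denom = (hi[a] - lo[a]) * volume.spacing[a]
        if denom > 0:
            g[a] = (occ[tuple(hi)] - occ[tuple(lo)]) / denom
    norm = np.linalg.norm(g)
    if norm > 1e-9:
        return -g / norm  # occupancy decreases outward
    if fallback_point is not None:
        d = np.asarray(fallback_point, float) - volume.index_to_world((i, j, k))
        n = np.linalg.norm(d)
        if n > 1e-12:
            return d / n
    return np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# proxy update
# ---------------------------------------------------------------------------


def _snap_to_free(volume: LabeledVolume, pos: np.ndarray) -> np.ndarray:
    dist, indices = _free_space_edt(volume)
    idx = volume.world_to_index(pos)
    idx = np.clip(idx, 0, np.asarray(volume.dims) - 1)
    free_idx = indices[:, idx[0], idx[1], idx[2]]
    return volume.index_to_world(free_idx)


def update_proxy(
    volume: LabeledVolume,
    prev_proxy,
    device_pos,
    max_slides: int = MAX_SLIDE_ITERATIONS,
) -> tuple[np.ndarray, int | None]:
    """March the proxy toward the device, sliding along contacted surfaces.

    Returns ``(new_proxy, contact_label)``; the contact label is that of the
    first occupied voxel blocking the march (``None`` in free space).  The
    result is always in free space; in fully free space it equals
    ``device_pos`` exactly.
    """
    proxy = np.asarray(prev_proxy, dtype=np.float64).copy()
    target = np.asarray(device_pos, dtype=np.float64).copy()
    if volume.occupied_at(proxy):
        log.warning("proxy started inside occupied space; snapping to nearest free voxel")
        proxy = _snap_to_free(volume, proxy)
    step = 0.25 * float(np.min(volume.spacing))
    contact: int | None = None

    for _ in range(max_slides + 1):
        d = target - proxy
        length = float(np.linalg.norm(d))
        if length < 1e-12:
            break
        n_steps = max(1, int(np.ceil(length / step)))
        base = proxy
        hit_idx = None
        for s in range(1, n_steps + 1):
            p = target if s == n_steps else base + d * (s / n_steps)
            idx = volume.world_to_index(p)
            if volume.in_bounds(idx) and volume.label[tuple(idx)] != 0:
                hit_idx = idx
                break
            proxy = p
        if hit_idx is None:
            break  # reached the target
        contact = int(volume.label[tuple(hit_idx)])
        normal = surface_normal(volume, hit_idx, fallback_point=proxy)
        residual = target - proxy
        inward = float(np.dot(residual, normal))
        if inward < 0:
            residual = residual - inward * normal  # keep only tangential motion
        else:
            break  # pushing away from the surface yet blocked; give up this tick
        target = proxy + residual
    return proxy, contact


def compute_force(
    state: HapticState, materials: MaterialTable, contact_label: int | None
) -> np.ndarray:
    """Proxy-device spring force, clamped in magnitude, direction preserved."""
    diff = state.proxy_pos - state.device_pos
    sep = float(np.linalg.norm(diff))
    if sep < 1e-12 or contact_label is None:
        return np.zeros(3)
    k = materials[contact_label].stiffness  # KeyError for unknown labels
    f = k * diff
    mag = float(np.linalg.norm(f))
    if mag > state.max_force:
        f = f * (state.max_force / mag)
    return f


def spring_force_baseline(
    volume: LabeledVolume,
    device_pos,
    materials: MaterialTable,
    default_stiffness: float = 0.5,
) -> np.ndarray:
    """Classic penalty force: stiffness * penetration depth toward nearest free
    space.  Comparison baseline only — exhibits pop-through on thin walls."""
    device_pos = np.asarray(device_pos, dtype=np.float64)
    idx = volume.world_to_index(device_pos)
    if not volume.in_bounds(idx) or volume.label[tuple(idx)] == 0:
        return np.zeros(3)
    lab = int(volume.label[tuple(idx)])
    k = materials[lab].stiffness if lab in materials else default_stiffness
    dist, indices = _free_space_edt(volume)
    free_idx = indices[:, idx[0], idx[1], idx[2]]
    free_center = volume.index_to_world(free_idx)
    depth = float(dist[tuple(idx)])
    direction = free_center - device_pos
    n = np.linalg.norm(direction)
    if n < 1e-12:
        return np.zeros(3)
    return k * depth * (direction / n)


def haptic_step(
    state: HapticState,
    volume: LabeledVolume,
    materials: MaterialTable,
    bit: DrillBit,
    new_device_pos,
    pedal: bool,
    dt: float,
    exposure: ExposureField,
    undo: UndoRecord | None = None,
    chunks=None,
) -> tuple[HapticState, np.ndarray, list[tuple[int, int, int]]]:
    """Advance one simulated tick: proxy update, force, optional carving.

    With the pedal on, the burr carves along the proxy's path this tick
    (sub-sampled against tunnelling).  Fully deterministic given its inputs.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new_device_pos = np.asarray(new_device_pos, dtype=np.float64)
    prev_proxy = state.proxy_pos
    proxy, contact = update_proxy(volume, prev_proxy, new_device_pos)
    removals: list[tuple[int, int, int]] = []
    if pedal:
        removals = drill_segment(
            volume, materials, bit, prev_proxy, proxy, dt, exposure, undo=undo, chunks=chunks
        )
    new_state = HapticState(
        device_pos=new_device_pos,
        proxy_pos=proxy,
        pedal=pedal,
        t=state.t + dt,
        contact_label=contact,
        max_force=state.max_force,
    )
    force = compute_force(new_state, materials, contact)
    new_state.force = force
    return new_state, force, removals
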