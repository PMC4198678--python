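"""Spherical-burr carving with exposure/resistance dynamics and stroke undo.

Removal model: every drillable voxel whose center lies within the bit radius
accrues ``exposure += removal_rate * dt * ease(label)`` per application; the
voxel is removed (density and label zeroed) once its exposure reaches the
material's ``resistance``.  The default resistance of 0 reproduces simple
binary carving; a positive resistance makes bone feel "harder" and ease
modulation meaningful (time-to-removal ``R / (rate * ease)`` under constant
exposure).

Undrillable labels never accrue exposure and never change.  A *stroke* is a
maximal contiguous pedal-on interval; it is the unit of undo, and undo is
strictly LIFO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volume_model import LabeledVolume, Material, MaterialTable


class MaterialError(KeyError):
    """A voxel carries a label with no entry in the material table."""


class UndoOrderError(RuntimeError):
    """Attempted out-of-order (non-LIFO) or repeated undo."""


@dataclass(frozen=True)
class DrillBit:
    """Spherical burr; the radius is modifiable between strokes."""

    radius: float  # mm
    removal_rate: float = 1.0  # exposure units per second

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("bit radius must be positive")
        if self.removal_rate <= 0:
            raise ValueError("removal rate must be positive")


class ExposureField:
    """Sparse accumulated drill exposure, voxel index -> seconds*rate*ease."""

    def __init__(self) -> None:
        self._data: dict[tuple[int, int, int], float] = {}

    def get(self, idx) -> float:
        return self._data.get(tuple(int(v) for v in idx), 0.0)

    def add(self, idx, amount: float) -> float:
        key = tuple(int(v) for v in idx)
        val = self._data.get(key, 0.0) + amount
        self._data[key] = val
        return val

    def clear(self, idx) -> None:
        self._data.pop(tuple(int(v) for v in idx), None)

    def __len__(self) -> int:
        return len(self._data)


@dataclass
class UndoRecord:
    """Per-stroke reversal data: prior density/label of every removed voxel."""

    stroke_id: int
    entries: list[tuple[tuple[int, int, int], float, int]] = field(default_factory=list)
    t_start: float = 0.0
    t_end: float = 0.0

    def record_removal(self, idx, prior_density: float, prior_label: int) -> None:
        self.entries.append((tuple(int(v) for v in idx), float(prior_density), int(prior_label)))

    @property
    def voxel_indices(self) -> list[tuple[int, int, int]]:
        return [e[0] for e in self.entries]


class UndoStack:
    """LIFO stack of stroke records."""

    def __init__(self) -> None:
        self._stack: list[UndoRecord] = []
        self._next_id = 0

    def new_stroke(self, t_start: float = 0.0) -> UndoRecord:
        rec = UndoRecord(stroke_id=self._next_id, t_start=t_start, t_end=t_start)
        self._next_id += 1
        return rec

    def push(self, record: UndoRecord) -> None:
        self._stack.append(record)

    def __len__(self) -> int:
        return len(self._stack)

    @property
    def top(self) -> UndoRecord | None:
        return self._stack[-1] if self._stack else None

    def pop_for_undo(self, record: UndoRecord | None = None) -> UndoRecord:
        if not self._stack:
            raise UndoOrderError("undo stack is empty")
        if record is not None and record is not self._stack[-1]:
            raise UndoOrderError(
                f"stroke {record.stroke_id} is not the most recent; undo is LIFO-only"
            )
        return self._stack.pop()


def _material_for(materials: MaterialTable, label: int) -> Material:
    try:
        return materials[label]
    except KeyError as e:
        raise MaterialError(str(e)) from None


def apply_drill(
    volume: LabeledVolume,
    materials: MaterialTable,
    bit: DrillBit,
    center,
    dt: float,
    exposure: ExposureField,
    undo: UndoRecord | None = None,
    chunks=None,
) -> tuple[list[tuple[int, int, int]], list[tuple[tuple[int, int, int], float, int]]]:
    """One drill application at ``center`` (world mm) for ``dt`` seconds.

    Returns ``(removed_voxel_indices, undo_delta)`` where the delta lists the
    prior ``(index, density, label)`` of each removed voxel.  The caller is
    responsible for pedal gating.  A center outside the volume is a no-op
    for out-of-range voxels (the in-range part of the sphere still carves).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    center = np.asarray(center, dtype=np.float64)
    dims = np.asarray(volume.dims)
    lo = np.ceil((center - bit.radius - volume.origin) / volume.spacing - 1e-12).astype(np.int64)
    hi = np.floor((center + bit.radius - volume.origin) / volume.spacing + 1e-12).astype(np.int64)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, dims - 1)
    removed: list[tuple[int, int, int]] = []
    delta: list[tuple[tuple[int, int, int], float, int]] = []
    if np.any(lo > hi):
        return removed, delta

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = volume.origin + idx * volume.spacing
    d2 = np.einsum("ij,ij->i", centers - center, centers - center)
    within = d2 <= bit.radius * bit.radius
    idx = idx[within]

    labels = volume.label[tuple(idx.T)]
    touched = idx[labels != 0]
    any_removed = False
    for i, j, k in touched:
        lab = int(volume.label[i, j, k])
        mat = _material_for(materials, lab)
        if not mat.drillable:
            continue
        exp = exposure.add((i, j, k), bit.removal_rate * dt * mat.ease)
        if exp >= mat.resistance:
            prior_d = float(volume.density[i, j, k])
            entry = ((int(i), int(j), int(k)), prior_d, lab)
            delta.append(entry)
            if undo is not None:
                undo.entries.append(entry)
            volume.density[i, j, k] = 0.0
            volume.label[i, j, k] = 0
            exposure.clear((i, j, k))
            removed.append((int(i), int(j), int(k)))
            any_removed = True
            if chunks is not None:
                chunks.mark_dirty_voxel((i, j, k))
    if any_removed:
        volume.touch()
    return removed, delta


def sample_segment(p0, p1, max_step: float) -> list[np.ndarray]:
    """Evenly spaced samples along ``p0 -> p1`` at spacing <= ``max_step``.

    Excludes ``p0`` (assumed already applied), includes ``p1`` exactly.
    A zero-length segment yields a single sample at ``p1`` so a stationary
    bit still drills.
    """
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    length = float(np.linalg.norm(p1 - p0))
    n = max(1, int(math.ceil(length / max_step)))
    return [p0 + (p1 - p0) * ((s + 1) / n) for s in range(n)]


def drill_segment(
    volume: LabeledVolume,
    materials: MaterialTable,
    bit: DrillBit,
    p0,
    p1,
    dt: float,
    exposure: ExposureField,
    undo: UndoRecord | None = None,
    chunks=None,
) -> list[tuple[int, int, int]]:
    """Carve along a straight segment, sub-sampled at <= 1/4 voxel spacing.

    Sub-sampling prevents a fast sweep from tunnelling through structures
    thinner than one timestep of travel; ``dt`` is split evenly across the
    samples so total exposure matches a single application of duration ``dt``.
    """
    max_step = 0.25 * float(np.min(volume.spacing))
    samples = sample_segment(p0, p1, max_step)
    removed: list[tuple[int, int, int]] = []
    sub_dt = dt / len(samples)
    for p in samples:
        r, _ = apply_drill(volume, materials, bit, p, sub_dt, exposure, undo=undo, chunks=chunks)
        removed.extend(r)
    return removed


def undo_stroke(
    volume: LabeledVolume,
    record: UndoRecord,
    exposure: ExposureField,
    stack: UndoStack | None = None,
    chunks=None,
) -> LabeledVolume:
    """Revert a stroke bitwise (density + label), clearing its exposure.

    When ``stack`` is given, LIFO order is enforced and the record is popped.
    """
    if stack is not None:
        stack.pop_for_undo(record)
    for (i, j, k), prior_d, prior_l in record.entries:
        volume.density[i, j, k] = prior_d
        volume.label[i, j, k] = prior_l
        exposure.clear((i, j, k))
        if chunks is not None:
            chunks.mark_dirty_voxel((i, j, k))
    if record.entries:
        volume.touch()
    return volume


def set_ease(materials: MaterialTable, label: int, ease: float) -> MaterialTable:
    """Return a table with the label's removal-ease multiplier replaced."""
    if ease <= 0:
        raise ValueError(f"ease must be > 0, got {ease}")
    mat = materials[label]  # raises KeyError for unknown labels
    return materials.with_material(int(label), replace(mat, ease=float(ease)))
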