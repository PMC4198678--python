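"""Session recording, JSONL persistence, exact replay, and guidance cues.

A session log is one header object plus one object per haptic tick (JSON
Lines: streamable, diffable, append-safe).  The header pins the model and
material-table content hashes so an expert recording can only be replayed on
the matching isomorphic model.  Replay re-executes every tick through the
same `haptic_step` code path, so the final volume and force trace are
bit-identical to the original run.

Passive training = exact replay of an expert log.  Active training =
guidance cues: a monotonic nearest-point match onto the expert trajectory
plus a unit direction toward the pose ``lookahead`` records ahead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .drilling import DrillBit, ExposureField, UndoStack
from .haptics import DEFAULT_MAX_FORCE, HapticState, haptic_step
from .volume_model import LabeledVolume, MaterialTable

DEFAULT_DT = 0.001  # 1 ms simulated haptic tick
DEFAULT_LOOKAHEAD = 50  # records


class SessionError(ValueError):
    """Malformed session log or model/log mismatch."""


@dataclass
class SessionRecord:
    t: float
    pose: tuple[float, float, float]
    pedal: bool
    radius: float

    def to_json(self) -> dict:
        return {"t": self.t, "pose": list(self.pose), "pedal": self.pedal, "radius": self.radius}

    @classmethod
    def from_json(cls, d: dict) -> "SessionRecord":
        return cls(
            t=float(d["t"]),
            pose=tuple(float(v) for v in d["pose"]),
            pedal=bool(d["pedal"]),
            radius=float(d["radius"]),
        )


@dataclass
class SessionLog:
    header: dict
    records: list[SessionRecord] = dc_field(default_factory=list)

    @property
    def dt(self) -> float:
        return float(self.header.get("dt", DEFAULT_DT))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SessionLog):
            return NotImplemented
        return self.header == other.header and self.records == other.records

    def strokes(self) -> list[tuple[int, int]]:
        """Half-open record-index ranges of contiguous pedal-on intervals."""
        out = []
        start = None
        for i, rec in enumerate(self.records):
            if rec.pedal and start is None:
                start = i
            elif not rec.pedal and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.records)))
        return out


def new_session_log(
    volume: LabeledVolume,
    materials: MaterialTable,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    bit_radius: float = 1.0,
) -> SessionLog:
    return SessionLog(
        header={
            "format": "otodrill-session-v1",
            "model_hash": volume.content_hash(),
            "material_hash": materials.content_hash(),
            "dt": dt,
            "seed": seed,
            "bit_radius": bit_radius,
        }
    )


def record_step(log: SessionLog, t: float, pose, pedal: bool, radius: float) -> SessionLog:
    """Append one tick; timestamps must advance by exactly the header dt."""
    if radius <= 0:
        raise SessionError("bit radius must be positive")
    if log.records:
        expected = log.records[-1].t + log.dt
        if abs(t - expected) > 1e-9:
            raise SessionError(
                f"non-monotone or gapped timestamp: got {t}, expected {expected}"
            )
    log.records.append(
        SessionRecord(t=float(t), pose=tuple(float(v) for v in pose), pedal=bool(pedal), radius=float(radius))
    )
    return log


def save_session(log: SessionLog, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(json.dumps({"type": "header", **log.header}, sort_keys=True) + "\n")
        for rec in log.records:
            f.write(json.dumps(rec.to_json(), sort_keys=True) + "\n")


def load_session(path) -> SessionLog:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise SessionError(f"{path}: empty session file")
    head = json.loads(lines[0])
    if head.pop("type", None) != "header":
        raise SessionError(f"{path}: first line must be the session header")
    log = SessionLog(header=head)
    for ln in lines[1:]:
        log.records.append(SessionRecord.from_json(json.loads(ln)))
    return log


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------


@dataclass
class SessionResult:
    volume: LabeledVolume
    log: SessionLog
    trace: list[dict]
    undo_stack: UndoStack
    removed_by_label: dict[int, int]

    def summary(self) -> dict:
        return {
            "ticks": len(self.log),
            "duration_s": len(self.log) * self.log.dt,
            "strokes": len(self.log.strokes()),
            "removed_by_label": {str(k): v for k, v in sorted(self.removed_by_label.items())},
            "removed_total": sum(self.removed_by_label.values()),
        }


def run_session(
    volume: LabeledVolume,
    materials: MaterialTable,
    commands: list[tuple],
    dt: float = DEFAULT_DT,
    seed: int = 0,
    max_force: float = DEFAULT_MAX_FORCE,
    start_pose=None,
) -> SessionResult:
    """Drive the haptic loop over ``(pose, pedal, radius)`` commands.

    The same routine executes fresh simulations and replays; determinism of
    `haptic_step` makes record -> replay bit-exact.  The volume is mutated in
    place (pass a copy to keep the original).
    """
    log = new_session_log(volume, materials, dt=dt, seed=seed,
                          bit_radius=commands[0][2] if commands else 1.0)
    if start_pose is None:
        start_pose = commands[0][0] if commands else (0.0, 0.0, 0.0)
    state = HapticState(device_pos=np.asarray(start_pose, float),
                        proxy_pos=np.asarray(start_pose, float), max_force=max_force)
    exposure = ExposureField()
    stack = UndoStack()
    stroke = None
    trace: list[dict] = []
    removed_by_label: dict[int, int] = {}
    t = 0.0

    for pose, pedal, radius in commands:
        bit = DrillBit(radius=float(radius))
        if pedal and stroke is None:
            stroke = stack.new_stroke(t_start=t)
        if not pedal and stroke is not None:
            stack.push(stroke)
            stroke = None
        undo_rec = stroke if pedal else None
        n_before = len(stroke.entries) if stroke is not None else 0
        state, force, removals = haptic_step(
            state, volume, materials, bit, pose, pedal, dt, exposure, undo=undo_rec
        )
        if stroke is not None:
            stroke.t_end = state.t
            for _, _, lab in stroke.entries[n_before:]:
                removed_by_label[lab] = removed_by_label.get(lab, 0) + 1
        record_step(log, t, pose, pedal, radius)
        trace.append(
            {
                "t": t,
                "device": tuple(float(v) for v in state.device_pos),
                "proxy": tuple(float(v) for v in state.proxy_pos),
                "force": tuple(float(v) for v in force),
                "pedal": bool(pedal),
                "contact": int(state.contact_label) if state.contact_label else 0,
            }
        )
        t = state.t
    if stroke is not None:
        stack.push(stroke)
    return SessionResult(volume=volume, log=log, trace=trace, undo_stack=stack,
                         removed_by_label=removed_by_label)


def replay_passive(
    log: SessionLog, volume: LabeledVolume, materials: MaterialTable
) -> SessionResult:
    """Re-execute an expert log on (a copy of the state of) its model.

    The log header's content hashes must match ``volume`` and ``materials``;
    this machine-checks the isomorphic pairing before any drilling happens.
    """
    if log.header.get("model_hash") != volume.content_hash():
        raise SessionError("session/model mismatch: model content hash differs")
    if log.header.get("material_hash") != materials.content_hash():
        raise SessionError("session/material mismatch: material table hash differs")
    commands = [(np.asarray(r.pose), r.pedal, r.radius) for r in log.records]
    return run_session(
        volume,
        materials,
        commands,
        dt=log.dt,
        seed=int(log.header.get("seed", 0)),
    )


def write_trace_csv(trace: list[dict], path) -> None:
    """Force/pose trace as CSV (floats via repr, so replays diff bit-exactly)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = "t,dx,dy,dz,px,py,pz,fx,fy,fz,pedal,contact"
    lines = [cols]
    for row in trace:
        vals = [row["t"], *row["device"], *row["proxy"], *row["force"]]
        lines.append(
            ",".join(repr(float(v)) for v in vals)
            + f",{int(row['pedal'])},{int(row['contact'])}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# active-mode guidance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuidanceCue:
    direction: tuple[float, float, float]  # unit vector (zeros when at target)
    distance: float  # mm to the lookahead target
    matched_index: int  # expert record matched (non-decreasing)


class GuidanceTracker:
    """Monotonic nearest-point matching onto an expert trajectory.

    The matched index may only advance, so a trainee looping back is pulled
    forward along the expert's path rather than re-matched to an earlier
    segment.  The cue points at the expert pose ``lookahead`` records ahead
    of the match (clamped to the end of the recording).
    """

    def __init__(self, expert_log: SessionLog, lookahead: int = DEFAULT_LOOKAHEAD) -> None:
        if len(expert_log) == 0:
            raise SessionError("expert log is empty")
        if lookahead < 1:
            raise ValueError("lookahead must be >= 1")
        self.poses = np.asarray([r.pose for r in expert_log.records], dtype=np.float64)
        self.lookahead = int(lookahead)
        self.matched = 0

    def update(self, current_pose) -> GuidanceCue:
        p = np.asarray(current_pose, dtype=np.float64)
        tail = self.poses[self.matched:]
        d = np.linalg.norm(tail - p, axis=1)
        self.matched = self.matched + int(np.argmin(d))
        target_idx = min(self.matched + self.lookahead, len(self.poses) - 1)
        vec = self.poses[target_idx] - p
        dist = float(np.linalg.norm(vec))
        direction = tuple(vec / dist) if dist > 1e-12 else (0.0, 0.0, 0.0)
        return GuidanceCue(direction=direction, distance=dist, matched_index=self.matched)


def guidance(current_pose, expert_log: SessionLog, lookahead: int = DEFAULT_LOOKAHEAD,
             tracker: GuidanceTracker | None = None) -> GuidanceCue:
    """One guidance cue; pass a :class:`GuidanceTracker` to keep the matched
    index monotonic across calls."""
    if tracker is None:
        tracker = GuidanceTracker(expert_log, lookahead)
    return tracker.update(current_pose)
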