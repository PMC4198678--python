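# otodrill

A headless, fully testable engine for voxel-based temporal-bone drilling
simulation: it builds labeled voxel models from segmented imaging, extracts
smooth surfaces incrementally while the bone is carved, renders
position-locking haptic contact forces, and records/replays whole drilling
sessions bit-exactly.

## What is in the box

| module | purpose |
| --- | --- |
| `otodrill.volume_model` | `LabeledVolume` / `MaterialTable`, NRRD / NIfTI-1 / raw+JSON I/O, x-y block downsampling, HU-window bone segmentation, watertight-mesh voxelization, structure recombination |
| `otodrill.mesh` | `TriangleMesh`, PLY/STL/OBJ I/O, topology and volume metrics, vertex welding |
| `otodrill.surface` | chunked Marching Cubes with dirty-region incremental updates (`ChunkGrid`, `update_dirty`), HC-corrected Laplacian smoothing |
| `otodrill.drilling` | spherical-burr carving with exposure/resistance dynamics, removal-ease modulation, undrillable protection, stroke-level LIFO undo |
| `otodrill.haptics` | march-and-slide proxy (`update_proxy`), clamped spring force law, virtual-spring penalty baseline for comparison, per-tick `haptic_step` |
| `otodrill.session` | JSONL session logs, exact passive replay (content-hash paired to its model), active-mode guidance cues |
| `otodrill.phantom` | synthetic temporal-bone-like phantoms (cortical shell, trabecular fill, air-cell voids, vessel/nerve tubes, plates, ossicle blobs) with exact analytic ground truth |
| `otodrill.cli` | `otodrill` command-line pipeline |

Key guarantees, all enforced by tests:

- incremental surface updates are triangle-set-identical to a full recompute;
- carving with zero resistance equals a brute-force union of per-step spheres
  over drillable voxel centers; undrillable labels never change;
- undoing strokes in LIFO order restores the volume bitwise;
- record → replay reproduces the final volume and force trace bit-exactly;
- the proxy never penetrates occupied voxels and holds the entry side of a
  2-voxel wall while the classic penalty method pops through.

## CLI

```sh
# generate a 64^3 phantom with analytic ground truth
otodrill --deterministic phantom --out-dir ph --seed 3

# segment a scalar volume into a labeled model (HU window, optional x/y downsample)
otodrill build-model --volume scan.nrrd --out model.nrrd --hu-low 500 --hu-high 3000 --downsample 4

# run a scripted drilling trajectory (JSONL of {pose, pedal, radius})
otodrill --deterministic simulate --model ph/phantom.nrrd --trajectory traj.jsonl --out-dir sim

# replay the recorded session on the matching model (content-hash checked)
otodrill --deterministic replay --model ph/phantom.nrrd --session sim/session.jsonl --out-dir rep

# extract a smoothed, per-material-colored surface
otodrill extract-surface --model ph/phantom.nrrd --out surf.ply \
    --smooth-iterations 10 --materials ph/phantom.materials.json

# summarize a session
otodrill report --session sim/session.jsonl --out report.json
```

Exit codes: `0` success, `2` usage error, `3` data error.  `--deterministic`
suppresses embedded timestamps so identical inputs give bit-identical outputs.

## Conventions

- 0-based voxel indices; world position of voxel `(i, j, k)` center is
  `origin + (i, j, k) * spacing`; all distances in mm, forces in N,
  stiffness in N/mm.
- Label 0 is void/air; collision occupancy is `label != 0`.
- The haptic tick is 1 ms simulated time; determinism is favored over
  wall-clock fidelity, and chunk recomputation is order-independent so it may
  be parallelized without changing results.
- The exact mathematics of the original position-locking force algorithm are
  not public; `otodrill.haptics` implements a march-and-slide proxy chosen to
  satisfy the properties attributed to it (per-iteration bit location,
  fine-feature navigation, thin-wall and constrained-space stability).
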