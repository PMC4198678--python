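import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otodrill import (
    DrillBit,
    ExposureField,
    UndoStack,
    apply_drill,
    drill_segment,
    set_ease,
    undo_stroke,
)
from otodrill.drilling import MaterialError, UndoOrderError, sample_segment
from otodrill.phantom import PhantomSpec, TubeSpec, make_phantom, make_sphere_phantom
from otodrill.volume_model import LabeledVolume, Material, MaterialTable

from oracles import sphere_union_removable, sphere_voxel_indices


def test_bit_validation():
    with pytest.raises(ValueError):
        DrillBit(radius=0.0)
    with pytest.raises(ValueError):
        DrillBit(radius=1.0, removal_rate=-1)


def test_drill_in_void_removes_nothing(materials):
    vol, gt = make_sphere_phantom(radius_mm=4.0, spacing=0.5)
    exp = ExposureField()
    far = np.asarray(gt["center_mm"]) + 50.0
    removed, delta = apply_drill(vol, materials, DrillBit(1.6), far, 0.01, exp)
    assert removed == [] and delta == []


def test_instant_carving_matches_brute_force_sphere(materials):
    vol, gt = make_sphere_phantom(radius_mm=6.0, spacing=0.5)
    center = np.asarray(gt["center_mm"])
    pristine = vol.copy()
    exp = ExposureField()
    removed, _ = apply_drill(vol, materials, DrillBit(1.6), center, 0.01, exp)
    # oracle: exhaustive distance test over all voxel centers of the pre-drill
    # volume, restricted to voxels that were bone
    in_sphere = sphere_voxel_indices(pristine, center, 1.6)
    oracle = {i for i in in_sphere if pristine.label[i] != 0}
    assert set(removed) == oracle
    assert all(vol.label[i] == 0 for i in oracle)


def test_undrillable_labels_protected(materials):
    spec = PhantomSpec(
        dims=(48, 48, 48),
        seed=3,
        tubes=(TubeSpec(path=((11.75, 4.0, 11.75), (11.75, 20.0, 11.75)), radius=1.0),),
    )
    vol, mats, gt = make_phantom(spec)
    vessel_before = int((vol.label == 3).sum())
    exp = ExposureField()
    # sweep the bit straight across the vessel
    drill_segment(
        vol, mats, DrillBit(2.0), (6.0, 11.75, 11.75), (18.0, 11.75, 11.75), 1.0, exp
    )
    assert int((vol.label == 3).sum()) == vessel_before
    assert int((vol.label == 2).sum()) < int(gt["label_voxel_counts"]["2"])  # bone carved


def test_mass_conservation(materials):
    vol, _ = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    before = int((vol.label != 0).sum())
    exp = ExposureField()
    removed, _ = apply_drill(
        vol, materials, DrillBit(2.0), vol.index_to_world((10, 10, 10)), 0.01, exp
    )
    after = int((vol.label != 0).sum())
    assert len(removed) + after == before


def test_unknown_label_raises():
    vol = LabeledVolume(
        density=np.ones((4, 4, 4)) * 1000,
        label=np.full((4, 4, 4), 9, dtype=np.int32),
        spacing=[0.5] * 3,
        origin=[0, 0, 0],
    )
    mats = MaterialTable({1: Material(name="bone")})
    with pytest.raises(MaterialError):
        apply_drill(vol, mats, DrillBit(1.0), (1.0, 1.0, 1.0), 0.01, ExposureField())


def test_center_outside_volume_is_noop(materials):
    vol, _ = make_sphere_phantom(radius_mm=4.0, spacing=0.5)
    removed, _ = apply_drill(
        vol, materials, DrillBit(1.0), (-100.0, -100.0, -100.0), 0.01, ExposureField()
    )
    assert removed == []


# ---------------------------------------------------------------------------
# resistance / ease
# ---------------------------------------------------------------------------


def _resistive_volume(resistance=2.0, ease=1.0):
    vol = LabeledVolume(
        density=np.ones((3, 3, 3)) * 1000,
        label=np.ones((3, 3, 3), dtype=np.int32),
        spacing=[0.5] * 3,
        origin=[0, 0, 0],
    )
    mats = MaterialTable(
        {1: Material(name="bone", resistance=resistance, ease=ease, stiffness=0.5)}
    )
    return vol, mats


def test_time_to_removal_closed_form():
    # R = 2 exposure units, rate 1/s, ease 2 -> removal at t = R/(rate*ease) = 1 s
    vol, mats = _resistive_volume(resistance=2.0)
    mats = set_ease(mats, 1, 2.0)
    exp = ExposureField()
    bit = DrillBit(radius=0.3, removal_rate=1.0)
    center = vol.index_to_world((1, 1, 1))
    t, dt = 0.0, 0.125  # binary-exact step so exposure hits R with no rounding
    removed_at = None
    while t < 2.0 and removed_at is None:
        removed, _ = apply_drill(vol, mats, bit, center, dt, exp)
        t += dt
        if removed:
            removed_at = t
    assert removed_at == pytest.approx(1.0, abs=dt / 2)


def test_doubling_ease_halves_removal_time():
    times = {}
    for ease in (1.0, 2.0):
        vol, mats = _resistive_volume(resistance=2.0, ease=ease)
        exp = ExposureField()
        bit = DrillBit(radius=0.3, removal_rate=1.0)
        center = vol.index_to_world((1, 1, 1))
        t, dt = 0.0, 0.0625  # binary-exact step
        while t < 5.0:
            removed, _ = apply_drill(vol, mats, bit, center, dt, exp)
            t += dt
            if removed:
                break
        times[ease] = t
    assert times[1.0] == pytest.approx(2 * times[2.0], abs=0.0625)


def test_set_ease_validation(materials):
    with pytest.raises(ValueError):
        set_ease(materials, 1, 0.0)
    with pytest.raises(KeyError):
        set_ease(materials, 99, 1.0)


def test_set_ease_on_undrillable_keeps_protection(materials):
    mats = set_ease(materials, 3, 5.0)  # vessel stays undrillable
    assert mats[3].ease == 5.0
    assert not mats[3].drillable
    vol, _ = make_sphere_phantom(radius_mm=3.0, spacing=0.5, label=3)
    before = int((vol.label == 3).sum())
    apply_drill(vol, mats, DrillBit(2.0), vol.index_to_world((6, 6, 6)), 1.0, ExposureField())
    assert int((vol.label == 3).sum()) == before


def test_ease_one_is_neutral(materials):
    assert set_ease(materials, 1, 1.0)[1].ease == 1.0


# ---------------------------------------------------------------------------
# segments and tunnelling
# ---------------------------------------------------------------------------


def test_sample_segment_step_bound():
    pts = sample_segment((0, 0, 0), (1, 0, 0), 0.125)
    assert len(pts) == 8
    assert np.allclose(pts[-1], [1, 0, 0])


def test_fast_sweep_cannot_tunnel(materials):
    # 2-voxel wall; a single segment jumping across it must still carve a hole
    from otodrill.phantom import make_wall_phantom

    vol = make_wall_phantom(2, nx=16, ny=16, nz=16, spacing=0.5)
    before = int((vol.label != 0).sum())
    exp = ExposureField()
    removed = drill_segment(
        vol, materials, DrillBit(0.8), (3.75, 3.75, 1.0), (3.75, 3.75, 7.0), 0.01, exp
    )
    assert removed  # the sweep crossed the wall and removed voxels in it
    assert int((vol.label != 0).sum()) == before - len(removed)


def test_trajectory_carving_matches_sphere_union_oracle(materials):
    vol, gt = make_sphere_phantom(radius_mm=6.0, spacing=0.5)
    pristine = vol.copy()
    rng = np.random.default_rng(7)
    center = np.asarray(gt["center_mm"])
    poses = [center + rng.uniform(-4, 4, 3) for _ in range(6)]
    exp = ExposureField()
    bit = DrillBit(1.2)
    all_removed: set = set()
    sample_points = []
    prev = poses[0]
    r0, _ = apply_drill(vol, materials, bit, prev, 0.01, exp)
    all_removed.update(r0)
    sample_points.append(prev)
    for p in poses[1:]:
        pts = sample_segment(prev, p, 0.25 * float(np.min(vol.spacing)))
        sample_points.extend(pts)
        all_removed.update(drill_segment(vol, materials, bit, prev, p, 0.01, exp))
        prev = p
    oracle = sphere_union_removable(pristine, materials, sample_points, bit.radius)
    assert all_removed == oracle


# ---------------------------------------------------------------------------
# undo
# ---------------------------------------------------------------------------


def test_stroke_undo_restores_bitwise(materials):
    vol, gt = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    snap = vol.copy()
    exp = ExposureField()
    stack = UndoStack()
    rec = stack.new_stroke()
    apply_drill(vol, materials, DrillBit(2.0), gt["center_mm"], 0.01, exp, undo=rec)
    stack.push(rec)
    assert vol != snap
    undo_stroke(vol, rec, exp, stack=stack)
    assert vol == snap


def test_two_strokes_undo_lifo(materials):
    vol, gt = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    snap = vol.copy()
    c = np.asarray(gt["center_mm"])
    exp = ExposureField()
    stack = UndoStack()
    for offset in ([0, 0, 0], [2.0, 0, 0]):
        rec = stack.new_stroke()
        apply_drill(vol, materials, DrillBit(1.5), c + offset, 0.01, exp, undo=rec)
        stack.push(rec)
    undo_stroke(vol, stack.top, exp, stack=stack)
    undo_stroke(vol, stack.top, exp, stack=stack)
    assert vol == snap


def test_out_of_order_undo_rejected(materials):
    vol, gt = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    c = np.asarray(gt["center_mm"])
    exp = ExposureField()
    stack = UndoStack()
    recs = []
    for offset in ([0, 0, 0], [2.0, 0, 0]):
        rec = stack.new_stroke()
        apply_drill(vol, materials, DrillBit(1.5), c + offset, 0.01, exp, undo=rec)
        stack.push(rec)
        recs.append(rec)
    with pytest.raises(UndoOrderError):
        undo_stroke(vol, recs[0], exp, stack=stack)


def test_undo_then_replay_reproduces_post_stroke_state(materials):
    vol, gt = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    exp = ExposureField()
    stack = UndoStack()
    rec = stack.new_stroke()
    apply_drill(vol, materials, DrillBit(1.5), gt["center_mm"], 0.01, exp, undo=rec)
    stack.push(rec)
    post = vol.copy()
    undo_stroke(vol, rec, exp, stack=stack)
    # replay the identical stroke deterministically
    rec2 = stack.new_stroke()
    apply_drill(vol, materials, DrillBit(1.5), gt["center_mm"], 0.01, exp, undo=rec2)
    assert vol == post


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 10_000), n_strokes=st.integers(1, 6))
def test_random_stroke_sequences_undo_to_original(seed, n_strokes):
    mats = __import__("otodrill").default_materials()
    vol, gt = make_sphere_phantom(radius_mm=5.0, spacing=0.5)
    snap = vol.copy()
    rng = np.random.default_rng(seed)
    c = np.asarray(gt["center_mm"])
    exp = ExposureField()
    stack = UndoStack()
    for _ in range(n_strokes):
        rec = stack.new_stroke()
        p0 = c + rng.uniform(-5, 5, 3)
        p1 = c + rng.uniform(-5, 5, 3)
        drill_segment(vol, mats, DrillBit(rng.uniform(0.5, 2.0)), p0, p1, 0.05, exp, undo=rec)
        stack.push(rec)
    while len(stack):
        undo_stroke(vol, stack.top, exp, stack=stack)
    assert vol == snap
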