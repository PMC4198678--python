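import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otodrill import (
    LabeledVolume,
    combine_structures,
    downsample_xy,
    read_volume,
    threshold_segment,
    voxelize_mesh,
    write_volume,
)
from otodrill.mesh import TriangleMesh, box_mesh, icosphere_mesh
from otodrill.phantom import PhantomSpec, make_phantom
from otodrill.volume_model import FormatError, GridMismatchError

from oracles import ray_parity_inside, voxel_centers


def _volume(density, label=None, spacing=(1, 1, 1), origin=(0, 0, 0)):
    density = np.asarray(density, dtype=np.float64)
    if label is None:
        label = np.zeros(density.shape, dtype=np.int32)
    return LabeledVolume(density=density, label=label, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_trivial_zero_volume_roundtrip(tmp_path):
    v = _volume(np.zeros((2, 2, 2)))
    p = tmp_path / "v.raw"
    write_volume(v, p)
    r = read_volume(p)
    assert r.dims == (2, 2, 2)
    assert np.all(r.density == 0.0)


@pytest.mark.parametrize("name", ["v.nrrd", "v.nii", "v.nii.gz", "v.raw", "v.nrrd.gz", "v.raw.gz"])
def test_roundtrip_bit_identical_all_formats(tmp_path, name):
    rng = np.random.default_rng(0)
    v = _volume(
        rng.normal(size=(5, 4, 3)) * 1000,
        label=rng.integers(0, 4, size=(5, 4, 3)).astype(np.int32),
        spacing=(0.14, 0.14, 0.035),
        origin=(-1.0, 2.5, 0.0),
    )
    p = tmp_path / name
    write_volume(v, p)
    r = read_volume(p)
    assert np.array_equal(r.density, v.density)
    assert np.array_equal(r.label, v.label)
    if ".nii" in name:
        # NIfTI-1 stores the affine as float32 by format; geometry round-trips
        # at single precision only
        assert np.array_equal(r.spacing, v.spacing.astype(np.float32).astype(np.float64))
        assert np.allclose(r.origin, v.origin, rtol=1e-6)
    else:
        assert np.array_equal(r.spacing, v.spacing)
        assert np.array_equal(r.origin, v.origin)


def test_label_histogram_survives_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    lab = rng.integers(0, 3, size=(6, 6, 6)).astype(np.int32)
    v = _volume(np.ones((6, 6, 6)), label=lab)
    write_volume(v, tmp_path / "v.nrrd")
    r = read_volume(tmp_path / "v.nrrd")
    assert np.array_equal(np.bincount(r.label.ravel()), np.bincount(lab.ravel()))


def test_empty_label_volume_omits_label_file(tmp_path):
    v = _volume(np.ones((3, 3, 3)))
    write_volume(v, tmp_path / "v.nrrd")
    assert not (tmp_path / "v.labels.nrrd").exists()
    r = read_volume(tmp_path / "v.nrrd")
    assert np.all(r.label == 0)


def test_handwritten_nrrd_header_spacing_echo(tmp_path):
    # independent fixture: header written by hand, not by write_volume
    payload = np.arange(8, dtype="<f8").tobytes()
    header = (
        "NRRD0004\n"
        "type: double\n"
        "dimension: 3\n"
        "sizes: 2 2 2\n"
        "spacings: 0.14 0.14 0.035\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    p = tmp_path / "hand.nrrd"
    p.write_bytes(header.encode() + payload)
    v = read_volume(p)
    assert v.spacing.tolist() == [0.14, 0.14, 0.035]
    assert v.dims == (2, 2, 2)


def test_gzip_encoded_nrrd_is_read(tmp_path):
    data = np.arange(8, dtype="<f8")
    header = (
        "NRRD0004\ntype: double\ndimension: 3\nsizes: 2 2 2\n"
        "spacings: 1 1 1\nendian: little\nencoding: gzip\n\n"
    )
    p = tmp_path / "gz.nrrd"
    p.write_bytes(header.encode() + gzip.compress(data.tobytes()))
    v = read_volume(p)
    assert np.array_equal(np.sort(v.density.ravel()), data)


def test_negative_spacing_rejected(tmp_path):
    header = (
        "NRRD0004\ntype: double\ndimension: 3\nsizes: 1 1 1\n"
        "spacings: -1 1 1\nendian: little\nencoding: raw\n\n"
    )
    p = tmp_path / "bad.nrrd"
    p.write_bytes(header.encode() + np.zeros(1).tobytes())
    with pytest.raises(FormatError):
        read_volume(p)


def test_missing_spacing_rejected(tmp_path):
    header = (
        "NRRD0004\ntype: double\ndimension: 3\nsizes: 1 1 1\n"
        "endian: little\nencoding: raw\n\n"
    )
    p = tmp_path / "bad.nrrd"
    p.write_bytes(header.encode() + np.zeros(1).tobytes())
    with pytest.raises(FormatError):
        read_volume(p)


def test_payload_size_mismatch_rejected(tmp_path):
    header = (
        "NRRD0004\ntype: double\ndimension: 3\nsizes: 2 2 2\n"
        "spacings: 1 1 1\nendian: little\nencoding: raw\n\n"
    )
    p = tmp_path / "bad.nrrd"
    p.write_bytes(header.encode() + np.zeros(3).tobytes())  # 3 != 8 values
    with pytest.raises(FormatError):
        read_volume(p)


def test_missing_file_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_volume(tmp_path / "nope.nrrd")


# ---------------------------------------------------------------------------
# downsample_xy
# ---------------------------------------------------------------------------


def test_downsample_factor_one_is_identity():
    rng = np.random.default_rng(2)
    v = _volume(rng.normal(size=(4, 4, 2)))
    out = downsample_xy(v, 1)
    assert out == v


def test_downsample_uniform_block_mean():
    v = _volume(np.ones((8, 8, 8)))
    out = downsample_xy(v, 4)
    assert out.dims == (2, 2, 8)
    assert np.all(out.density == 1.0)
    assert np.array_equal(out.spacing, [4.0, 4.0, 1.0])


def test_downsample_hand_computed_block_mean():
    d = np.zeros((4, 4, 1))
    d[0, 0, 0] = 4.0  # block {0,0,0,4, 0...} over 16 voxels -> mean 0.25
    v = _volume(d)
    out = downsample_xy(v, 4)
    assert out.dims == (1, 1, 1)
    assert out.density[0, 0, 0] == pytest.approx(4.0 / 16.0)


def test_downsample_majority_label_ties_lowest_id():
    lab = np.zeros((2, 2, 1), dtype=np.int32)
    lab[0, 0, 0] = 3
    lab[0, 1, 0] = 3
    lab[1, 0, 0] = 2
    lab[1, 1, 0] = 2  # tie 2 vs 2 between labels 2 and 3 -> lowest (2) wins
    v = _volume(np.ones((2, 2, 1)), label=lab)
    out = downsample_xy(v, 2)
    assert out.label[0, 0, 0] == 2


def test_downsample_crops_trailing_with_warning():
    v = _volume(np.ones((5, 5, 2)))
    with pytest.warns(UserWarning, match="cropping"):
        out = downsample_xy(v, 2)
    assert out.dims == (2, 2, 2)


def test_downsample_bad_factor():
    v = _volume(np.ones((4, 4, 1)))
    with pytest.raises(ValueError):
        downsample_xy(v, 0)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    factor=st.sampled_from([2, 3, 4]),
    nz=st.integers(1, 4),
)
def test_downsample_conserves_density_mass(seed, factor, nz):
    rng = np.random.default_rng(seed)
    n = factor * rng.integers(1, 4)
    v = _volume(rng.uniform(0, 2000, size=(n, n, nz)), spacing=(0.25, 0.25, 0.5))
    out = downsample_xy(v, factor)
    before = v.density.sum() * v.voxel_volume
    after = out.density.sum() * out.voxel_volume
    assert after == pytest.approx(before, rel=1e-9)


# ---------------------------------------------------------------------------
# threshold_segment
# ---------------------------------------------------------------------------


def test_threshold_all_zero_volume_labels_nothing():
    v = _volume(np.zeros((4, 4, 4)))
    out = threshold_segment(v, 500, 3000, 1)
    assert np.all(out.label == 0)


def test_threshold_infinite_window_labels_everything():
    rng = np.random.default_rng(3)
    v = _volume(rng.normal(size=(4, 4, 4)) * 5000)
    out = threshold_segment(v, -np.inf, np.inf, 2)
    assert np.all(out.label == 2)


def test_threshold_shell_phantom_retains_air_cells():
    spec = PhantomSpec(dims=(48, 48, 48), n_air_cells=15, seed=4)
    vol, _, gt = make_phantom(spec)
    # bone-only window: cortical 1800 and trabecular 700 are in, air (0) is out
    seg = threshold_segment(vol, 500.0, 3000.0, 1)
    expected = int(gt["label_voxel_counts"]["1"]) + int(gt["label_voxel_counts"]["2"])
    assert int((seg.label == 1).sum()) == expected
    # every air-cell voxel stays void
    for cell in gt["air_cells"]:
        idx = vol.world_to_index(cell["center_mm"])
        assert seg.label[tuple(idx)] == 0


def test_threshold_never_labels_outside_window():
    rng = np.random.default_rng(5)
    v = _volume(rng.uniform(-1000, 4000, size=(6, 6, 6)))
    out = threshold_segment(v, 500, 3000, 1)
    labeled = out.label == 1
    assert np.all(v.density[labeled] >= 500)
    assert np.all(v.density[labeled] <= 3000)
    assert np.all(out.label[~labeled] == 0)


def test_threshold_bad_window_rejected():
    v = _volume(np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        threshold_segment(v, 3000, 500, 1)


# ---------------------------------------------------------------------------
# voxelize_mesh
# ---------------------------------------------------------------------------


def test_voxelize_cube_spanning_27_centers():
    # cube [0.75, 2.25] mm on a 0.5 mm grid -> centers 1.0, 1.5, 2.0 inside
    mesh = box_mesh([0.75] * 3, [2.25] * 3)
    mask = voxelize_mesh(mesh, (7, 7, 7), (0.5, 0.5, 0.5), (0, 0, 0))
    assert int(mask.sum()) == 27


def test_voxelize_sphere_volume_and_exact_oracle_agreement():
    # center chosen off-grid so no voxel center lands exactly on the surface
    center = (12.07, 11.93, 12.11)
    mesh = icosphere_mesh(center, 10.0, subdivisions=3)
    dims = (49, 49, 49)
    spacing = (0.5, 0.5, 0.5)
    mask = voxelize_mesh(mesh, dims, spacing, (0, 0, 0))
    analytic = 4.0 / 3.0 * np.pi * 10.0**3
    assert mask.sum() * 0.125 == pytest.approx(analytic, rel=0.02)

    v = _volume(np.zeros(dims), spacing=spacing)
    idx, centers = voxel_centers(v)
    oracle = ray_parity_inside(centers, mesh.vertices, mesh.faces).reshape(dims)
    assert np.array_equal(mask, oracle)


def test_voxelize_mesh_outside_grid_is_empty():
    mesh = box_mesh([100, 100, 100], [110, 110, 110])
    mask = voxelize_mesh(mesh, (8, 8, 8), (0.5, 0.5, 0.5), (0, 0, 0))
    assert not mask.any()


def test_voxelize_rejects_open_mesh():
    mesh = box_mesh([0, 0, 0], [1, 1, 1])
    open_mesh = TriangleMesh(mesh.vertices, mesh.faces[:-2])  # drop two triangles
    with pytest.raises(ValueError, match="boundary"):
        voxelize_mesh(open_mesh, (4, 4, 4), (1, 1, 1), (0, 0, 0))


# ---------------------------------------------------------------------------
# combine_structures
# ---------------------------------------------------------------------------


def test_combine_empty_list_identity(sphere8):
    vol, _ = sphere8
    out = combine_structures([], vol)
    assert out == vol


def test_combine_priority_later_wins():
    v = _volume(np.ones((4, 4, 4)) * 1000)
    bone = np.zeros((4, 4, 4), dtype=bool)
    bone[:2] = True
    vessel = np.zeros((4, 4, 4), dtype=bool)
    vessel[1] = True  # overlaps bone on plane 1
    out = combine_structures([(bone, 1), (vessel, 3)], v)
    assert np.all(out.label[1] == 3)
    assert np.all(out.label[0] == 1)


def test_combine_disjoint_masks_add():
    v = _volume(np.ones((4, 4, 4)))
    a = np.zeros((4, 4, 4), dtype=bool)
    a[0] = True
    b = np.zeros((4, 4, 4), dtype=bool)
    b[2] = True
    out = combine_structures([(a, 1), (b, 3)], v)
    assert int((out.label == 1).sum()) + int((out.label == 3).sum()) == int(a.sum() + b.sum())


def test_combine_assigns_representative_density_to_void(materials):
    v = _volume(np.zeros((3, 3, 3)))
    m = np.ones((3, 3, 3), dtype=bool)
    out = combine_structures([(m, 3)], v, materials=materials)
    assert np.all(out.density == materials[3].density)


def test_combine_idempotent(materials):
    v = _volume(np.zeros((4, 4, 4)))
    m1 = np.zeros((4, 4, 4), dtype=bool)
    m1[:2] = True
    m2 = np.zeros((4, 4, 4), dtype=bool)
    m2[1:3] = True
    masks = [(m1, 1), (m2, 3)]
    once = combine_structures(masks, v, materials=materials)
    twice = combine_structures(masks, once, materials=materials)
    assert once == twice


def test_combine_grid_mismatch_rejected():
    v = _volume(np.zeros((4, 4, 4)))
    with pytest.raises(GridMismatchError):
        combine_structures([(np.zeros((3, 3, 3), dtype=bool), 1)], v)
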