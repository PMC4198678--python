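"""Labeled voxel volumes, material tables, and isomorphic model building.

A :class:`LabeledVolume` carries two co-registered grids: a scalar density
field (HU-like, or occupancy in ``[0, 1]``) and an integer label field in
which label 0 means void/air.  World coordinates are millimetres; the world
position of voxel ``(i, j, k)`` center is ``origin + (i, j, k) * spacing``
(0-based indices).

Supported on-disk dialects: NRRD (raw or gzip encoded), NIfTI-1 via nibabel,
and raw little-endian payload with a JSON sidecar.  Labels travel in a
companion file next to the density file (``<stem>.labels.<ext>``), omitted
when the label grid is all zero.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: Default Hounsfield window used to segment bone.  The window is a
#: configuration default, not a measured constant; override per dataset.
DEFAULT_HU_WINDOW = (500.0, 3000.0)


class FormatError(ValueError):
    """A volume or material file is malformed (bad header, size mismatch...)."""


class GridMismatchError(ValueError):
    """Two grids expected to share dims/spacing/origin do not."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass
class LabeledVolume:
    """Density + label grids with shared geometry.

    ``density`` and ``label`` are ``(nx, ny, nz)`` arrays (float64 / int32).
    ``version`` is bumped on every in-place mutation so downstream caches
    (smoothed occupancy, distance transforms, chunked surfaces) can detect
    staleness.
    """

    density: np.ndarray
    label: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    version: int = 0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        self.label = np.ascontiguousarray(self.label, dtype=np.int32)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.density.ndim != 3:
            raise FormatError("density must be a 3-D array")
        if self.density.shape != self.label.shape:
            raise GridMismatchError(
                f"density shape {self.density.shape} != label shape {self.label.shape}"
            )
        if min(self.density.shape) < 1:
            raise FormatError("all dims must be >= 1")
        if not np.all(self.spacing > 0):
            raise FormatError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.density)):
            raise FormatError("density contains non-finite values")
        if np.any(self.label < 0):
            raise FormatError("labels must be non-negative")

    # -- geometry ----------------------------------------------------------

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.density.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=np.float64) * self.spacing

    def world_to_index(self, pos) -> np.ndarray:
        """Nearest voxel index of a world point (may be out of bounds)."""
        return np.rint((np.asarray(pos, dtype=np.float64) - self.origin) / self.spacing).astype(
            np.int64
        )

    def in_bounds(self, idx) -> bool:
        idx = np.asarray(idx)
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.dims)))

    def occupied_at(self, pos) -> bool:
        """Collision test: a world point is occupied iff its voxel has label != 0."""
        idx = self.world_to_index(pos)
        if not self.in_bounds(idx):
            return False
        return self.label[tuple(idx)] != 0

    def occupancy(self) -> np.ndarray:
        """Float occupancy field: 1 where label != 0, else 0."""
        return (self.label != 0).astype(np.float64)

    # -- bookkeeping -------------------------------------------------------

    def touch(self) -> None:
        """Mark the volume mutated; invalidates derived caches."""
        self.version += 1
        self._cache.clear()

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            density=self.density.copy(),
            label=self.label.copy(),
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            version=self.version,
        )

    def same_grid(self, other: "LabeledVolume") -> bool:
        return (
            self.dims == other.dims
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.origin, other.origin)
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.dims, dtype=np.int64).tobytes())
        h.update(self.spacing.tobytes())
        h.update(self.origin.tobytes())
        h.update(self.density.tobytes())
        h.update(self.label.tobytes())
        return h.hexdigest()

    def __eq__(self, other) -> bool:  # bitwise equality
        if not isinstance(other, LabeledVolume):
            return NotImplemented
        return (
            self.same_grid(other)
            and np.array_equal(self.density, other.density)
            and np.array_equal(self.label, other.label)
        )


@dataclass(frozen=True)
class Material:
    """Per-label rendering and interaction properties."""

    name: str
    color: tuple[float, float, float, float] = (0.8, 0.8, 0.7, 1.0)
    transparency: float = 0.0
    stiffness: float = 0.5  # N/mm
    drillable: bool = True
    ease: float = 1.0  # removal-ease multiplier
    resistance: float = 0.0  # exposure units needed before removal; 0 = instant
    density: float | None = None  # representative density for re-labeled void voxels
    render: bool = True

    def validate(self) -> None:
        if len(self.color) != 4 or any(not (0.0 <= c <= 1.0) for c in self.color):
            raise FormatError(f"material {self.name!r}: color must be RGBA in [0,1]")
        if not (0.0 <= self.transparency <= 1.0):
            raise FormatError(f"material {self.name!r}: transparency outside [0,1]")
        if self.stiffness <= 0:
            raise FormatError(f"material {self.name!r}: stiffness must be > 0")
        if self.ease <= 0:
            raise FormatError(f"material {self.name!r}: ease must be > 0")
        if self.resistance < 0:
            raise FormatError(f"material {self.name!r}: resistance must be >= 0")


@dataclass
class MaterialTable:
    """Mapping label id -> :class:`Material`.  Label 0 is reserved for void."""

    materials: dict[int, Material] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for lab, mat in self.materials.items():
            if int(lab) <= 0:
                raise FormatError("label ids must be positive; 0 is reserved for void")
            mat.validate()

    def __getitem__(self, label: int) -> Material:
        try:
            return self.materials[int(label)]
        except KeyError:
            raise KeyError(f"label {label} not present in material table") from None

    def __contains__(self, label: int) -> bool:
        return int(label) in self.materials

    def labels(self) -> list[int]:
        return sorted(self.materials)

    def with_material(self, label: int, mat: Material) -> "MaterialTable":
        out = dict(self.materials)
        out[int(label)] = mat
        return MaterialTable(out)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            str(lab): {
                "name": m.name,
                "color": list(m.color),
                "transparency": m.transparency,
                "stiffness": m.stiffness,
                "drillable": m.drillable,
                "ease": m.ease,
                "resistance": m.resistance,
                "density": m.density,
                "render": m.render,
            }
            for lab, m in sorted(self.materials.items())
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialTable":
        mats = {}
        for lab, spec in d.items():
            mats[int(lab)] = Material(
                name=spec["name"],
                color=tuple(spec.get("color", (0.8, 0.8, 0.7, 1.0))),
                transparency=float(spec.get("transparency", 0.0)),
                stiffness=float(spec.get("stiffness", 0.5)),
                drillable=bool(spec.get("drillable", True)),
                ease=float(spec.get("ease", 1.0)),
                resistance=float(spec.get("resistance", 0.0)),
                density=spec.get("density"),
                render=bool(spec.get("render", True)),
            )
        return cls(mats)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "MaterialTable":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: material table must be a mapping of label -> spec")
        return cls.from_dict(data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

_NRRD_TYPES = {
    "double": "<f8",
    "float": "<f4",
    "int": "<i4",
    "signed int": "<i4",
    "uint": "<u4",
    "unsigned int": "<u4",
    "short": "<i2",
    "unsigned short": "<u2",
    "uchar": "|u1",
    "unsigned char": "|u1",
}
_NRRD_TYPE_NAMES = {np.dtype(v): k for k, v in reversed(_NRRD_TYPES.items())}


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nrrd") or name.endswith(".nrrd.gz"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".raw") or name.endswith(".raw.gz"):
        return "raw+json"
    raise FormatError(f"cannot infer volume format from {path.name!r}")


def _label_companion(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nrrd.gz", ".raw.gz", ".nii", ".nrrd", ".raw"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".labels" + ext)
    raise FormatError(f"unsupported volume extension: {name!r}")


def _open_maybe_gz(path: Path, mode: str):
    if path.name.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _write_nrrd_field(path: Path, arr: np.ndarray, spacing, origin) -> None:
    dtype = np.dtype(arr.dtype).newbyteorder("<")
    tname = _NRRD_TYPE_NAMES[np.dtype(arr.dtype)]
    nx, ny, nz = arr.shape
    sx, sy, sz = (float(v) for v in spacing)
    ox, oy, oz = (float(v) for v in origin)
    header = (
        "NRRD0004\n"
        "# headless otodrill volume\n"
        f"type: {tname}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        "encoding: raw\n"
        "endian: little\n"
        "space dimension: 3\n"
        f"space directions: ({sx!r},0,0) (0,{sy!r},0) (0,0,{sz!r})\n"
        f"space origin: ({ox!r},{oy!r},{oz!r})\n"
        "\n"
    )
    with _open_maybe_gz(path, "wb") as f:
        f.write(header.encode("ascii"))
        # NRRD convention: first listed axis is fastest on disk
        f.write(np.asarray(arr, dtype=dtype).flatten(order="F").tobytes())


def _parse_nrrd_triples(text: str) -> list[list[float]]:
    out = []
    for chunk in text.replace(") (", ")|(").split("|"):
        chunk = chunk.strip().strip("()")
        if chunk.lower() == "none":
            out.append([])
        else:
            out.append([float(v) for v in chunk.split(",")])
    return out


def _read_nrrd_field(path: Path):
    with _open_maybe_gz(path, "rb") as f:
        magic = f.readline()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = f.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if not text or text.startswith("#"):
                continue
            if ":=" in text:
                key, _, val = text.partition(":=")
            elif ":" in text:
                key, _, val = text.partition(":")
            else:
                continue
            fields[key.strip().lower()] = val.strip()

        try:
            tname = fields["type"]
            sizes = [int(v) for v in fields["sizes"].split()]
        except KeyError as e:
            raise FormatError(f"{path}: missing NRRD header field {e}") from None
        if int(fields.get("dimension", len(sizes))) != 3 or len(sizes) != 3:
            raise FormatError(f"{path}: only 3-D NRRD supported")
        if tname not in _NRRD_TYPES:
            raise FormatError(f"{path}: unsupported NRRD type {tname!r}")
        dtype = np.dtype(_NRRD_TYPES[tname])
        if fields.get("endian", "little") != "little":
            raise FormatError(f"{path}: only little-endian NRRD supported")

        spacing = None
        if "space directions" in fields:
            dirs = [d for d in _parse_nrrd_triples(fields["space directions"]) if d]
            if len(dirs) == 3:
                spacing = np.asarray([dirs[i][i] for i in range(3)], dtype=np.float64)
        if spacing is None and "spacings" in fields:
            spacing = np.asarray([float(v) for v in fields["spacings"].split()], dtype=np.float64)
        if spacing is None:
            raise FormatError(f"{path}: NRRD header carries no spacing information")
        if not np.all(np.isfinite(spacing)) or not np.all(spacing > 0):
            raise FormatError(f"{path}: non-positive spacing {spacing}")

        origin = np.zeros(3)
        if "space origin" in fields:
            origin = np.asarray(_parse_nrrd_triples(fields["space origin"])[0], dtype=np.float64)

        encoding = fields.get("encoding", "raw").lower()
        payload = f.read()
    if encoding in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    expected = int(np.prod(sizes)) * dtype.itemsize
    if len(payload) != expected:
        raise FormatError(
            f"{path}: payload is {len(payload)} bytes, header promises {expected}"
        )
    arr = np.frombuffer(payload, dtype=dtype).reshape(sizes, order="F")
    return arr, spacing, origin


def _nifti_io():
    import nibabel as nib

    return nib


def write_volume(volume: LabeledVolume, path, format: str | None = None) -> None:
    """Write a volume; labels go to a ``.labels`` companion file if nonzero."""
    path = Path(path)
    fmt = format or _infer_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_labels = bool(np.any(volume.label != 0))
    lpath = _label_companion(path)

    if fmt == "nrrd":
        _write_nrrd_field(path, volume.density, volume.spacing, volume.origin)
        if has_labels:
            _write_nrrd_field(lpath, volume.label, volume.spacing, volume.origin)
    elif fmt == "nifti":
        nib = _nifti_io()
        affine = np.diag([*volume.spacing, 1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.density, affine), str(path))
        if has_labels:
            nib.save(nib.Nifti1Image(volume.label, affine), str(lpath))
    elif fmt == "raw+json":
        with _open_maybe_gz(path, "wb") as f:
            f.write(volume.density.astype("<f8").tobytes(order="F"))
        if has_labels:
            with _open_maybe_gz(lpath, "wb") as f:
                f.write(volume.label.astype("<i4").tobytes(order="F"))
        sidecar = {
            "dims": list(volume.dims),
            "spacing": [float(v) for v in volume.spacing],
            "origin": [float(v) for v in volume.origin],
            "dtype": "<f8",
            "order": "F",
            "label_file": lpath.name if has_labels else None,
            "label_dtype": "<i4",
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")

    if not has_labels and lpath.exists():
        lpath.unlink()


def read_volume(path, format: str | None = None) -> LabeledVolume:
    """Read a volume (density + optional label companion)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    lpath = _label_companion(path)

    if fmt == "nrrd":
        density, spacing, origin = _read_nrrd_field(path)
        label = None
        if lpath.exists():
            label, lsp, _ = _read_nrrd_field(lpath)
            if not np.allclose(lsp, spacing):
                raise GridMismatchError(f"{lpath}: label spacing differs from density spacing")
    elif fmt == "nifti":
        nib = _nifti_io()
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.diag(affine)[:3].astype(np.float64)
        if not np.all(spacing > 0):
            raise FormatError(f"{path}: non-positive spacing in affine")
        origin = affine[:3, 3].astype(np.float64)
        density = np.asarray(img.dataobj)
        label = np.asarray(nib.load(str(lpath)).dataobj) if lpath.exists() else None
    elif fmt == "raw+json":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        dims = meta["dims"]
        spacing = np.asarray(meta["spacing"], dtype=np.float64)
        if len(spacing) != 3 or not np.all(spacing > 0):
            raise FormatError(f"{sidecar_path}: spacing must be 3 positive values")
        origin = np.asarray(meta["origin"], dtype=np.float64)
        with _open_maybe_gz(path, "rb") as f:
            payload = f.read()
        dtype = np.dtype(meta.get("dtype", "<f8"))
        expected = int(np.prod(dims)) * dtype.itemsize
        if len(payload) != expected:
            raise FormatError(f"{path}: payload {len(payload)} bytes != expected {expected}")
        density = np.frombuffer(payload, dtype=dtype).reshape(dims, order=meta.get("order", "F"))
        label = None
        if meta.get("label_file"):
            with _open_maybe_gz(path.with_name(meta["label_file"]), "rb") as f:
                label = np.frombuffer(f.read(), dtype=np.dtype(meta.get("label_dtype", "<i4")))
            label = label.reshape(dims, order=meta.get("order", "F"))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")

    if label is None:
        label = np.zeros(density.shape, dtype=np.int32)
    if label.shape != density.shape:
        raise FormatError(f"{path}: label dims {label.shape} != density dims {density.shape}")
    return LabeledVolume(density=density, label=label, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# model-building operations
# ---------------------------------------------------------------------------


def downsample_xy(volume: LabeledVolume, factor: int) -> LabeledVolume:
    """Block-downsample in x and y only (z untouched).

    Density is the block mean; label is the block-majority label with ties
    resolved toward the lowest id.  Trailing voxels that do not fill a block
    are cropped (with a warning).  Spacing in x/y scales by ``factor`` and the
    origin moves to the new voxel-0 center.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return volume.copy()
    nx, ny, nz = volume.dims
    nbx, nby = nx // factor, ny // factor
    if nbx < 1 or nby < 1:
        raise ValueError(f"factor {factor} larger than volume dims {volume.dims[:2]}")
    if nx % factor or ny % factor:
        warnings.warn(
            f"downsample_xy: cropping trailing voxels {nx % factor} in x, {ny % factor} in y",
            stacklevel=2,
        )
    d = volume.density[: nbx * factor, : nby * factor, :]
    l = volume.label[: nbx * factor, : nby * factor, :]
    blocks_d = d.reshape(nbx, factor, nby, factor, nz)
    density = blocks_d.mean(axis=(1, 3))

    blocks_l = l.reshape(nbx, factor, nby, factor, nz)
    uniq = np.unique(blocks_l)
    counts = np.stack([(blocks_l == u).sum(axis=(1, 3)) for u in uniq])
    label = uniq[np.argmax(counts, axis=0)]  # argmax keeps first max -> lowest id

    spacing = volume.spacing * np.array([factor, factor, 1.0])
    # new voxel-0 center sits at the centroid of the first block's centers
    origin = volume.origin + np.array(
        [(factor - 1) / 2.0 * volume.spacing[0], (factor - 1) / 2.0 * volume.spacing[1], 0.0]
    )
    return LabeledVolume(density=density, label=label.astype(np.int32), spacing=spacing, origin=origin)


def threshold_segment(
    volume: LabeledVolume, hu_low: float, hu_high: float, label: int
) -> LabeledVolume:
    """Label voxels whose density lies in ``[hu_low, hu_high]``; others get 0.

    Interior voxels below the window stay void, so air-cell systems are
    retained as drill-through free space.
    """
    if hu_low > hu_high:
        raise ValueError(f"hu_low ({hu_low}) must be <= hu_high ({hu_high})")
    if int(label) <= 0:
        raise ValueError("segment label must be positive")
    mask = (volume.density >= hu_low) & (volume.density <= hu_high)
    out = volume.copy()
    out.label = np.where(mask, np.int32(label), np.int32(0)).astype(np.int32)
    return out


def combine_structures(
    masks: list[tuple[np.ndarray, int]],
    base: LabeledVolume,
    materials: MaterialTable | None = None,
    representative_density: float | None = None,
) -> LabeledVolume:
    """Overlay structure masks onto a base volume; later entries win overlaps.

    Voxels newly labeled out of density-0 space receive the material's
    representative density (``Material.density`` when set, else
    ``representative_density``, else the midpoint of the default HU window).
    """
    out = base.copy()
    default_rep = (
        representative_density
        if representative_density is not None
        else 0.5 * (DEFAULT_HU_WINDOW[0] + DEFAULT_HU_WINDOW[1])
    )
    for mask, lab in masks:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != out.density.shape:
            raise GridMismatchError(
                f"mask shape {mask.shape} does not match base grid {out.density.shape}"
            )
        lab = int(lab)
        if lab <= 0:
            raise ValueError("structure label must be positive")
        rep = default_rep
        if materials is not None and lab in materials and materials[lab].density is not None:
            rep = float(materials[lab].density)  # type: ignore[arg-type]
        out.density[mask & (out.density == 0.0)] = rep
        out.label[mask] = lab
    return out


# ---------------------------------------------------------------------------
# mesh voxelization
# ---------------------------------------------------------------------------


def _winding_number(points: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Generalized winding number of each point w.r.t. a triangle soup.

    Sums signed solid angles (van Oosterom & Strackee) per triangle; for a
    watertight, consistently oriented mesh the result is ~1 inside, ~0 outside.
    """
    w = np.zeros(len(points), dtype=np.float64)
    for tri in faces:
        a = vertices[tri[0]] - points
        b = vertices[tri[1]] - points
        c = vertices[tri[2]] - points
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", c, a) * lb
        )
        w += 2.0 * np.arctan2(num, den)
    return w / (4.0 * np.pi)


def voxelize_mesh(
    mesh,
    dims: tuple[int, int, int],
    spacing,
    origin,
) -> np.ndarray:
    """Occupancy mask of a watertight mesh on a voxel grid.

    A voxel is occupied iff its center lies inside the mesh (winding-number
    test).  Raises on non-watertight input, naming the boundary-edge count.
    """
    from .mesh import boundary_edge_count  # local import to avoid cycle

    n_boundary = boundary_edge_count(mesh)
    if n_boundary:
        raise ValueError(
            f"mesh is not watertight: {n_boundary} boundary/non-manifold directed edges"
        )
    spacing = np.asarray(spacing, dtype=np.float64)
    origin = np.asarray(origin, dtype=np.float64)
    nx, ny, nz = dims

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    ilo = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    ihi = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, dims)
    mask = np.zeros(dims, dtype=bool)
    if np.any(ilo >= ihi):
        return mask  # mesh entirely outside the grid

    ii, jj, kk = np.meshgrid(
        np.arange(ilo[0], ihi[0]),
        np.arange(ilo[1], ihi[1]),
        np.arange(ilo[2], ihi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = origin + idx * spacing
    w = _winding_number(centers, mesh.vertices, mesh.faces)
    inside = np.abs(w) > 0.5
    mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    return mask
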