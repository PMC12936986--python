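"""Domain types and I/O: bone meshes, label volumes, templates, landmarks.

Units are millimetres everywhere. Label volumes map voxel indices to world
mm through a NIfTI-style affine (RAS+, affine maps voxel *centres*); mesh
files are STL/PLY/OBJ via trimesh; landmark sets are a small JSON dialect::

    {"subject": "s01", "bone": "femur", "side": "R",
     "landmarks": {"FHC": [x, y, z], ...}}

Unknown acronyms in a landmark file are kept under an ``extra`` namespace
and never reach the measurement engine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    EmptyRegionError,
    LandmarkParseError,
    MeshFormatError,
    MeshValidationError,
)

MERGE_TOL_MM = 1e-6

_MESH_FORMATS = {"stl", "ply", "obj"}


class BoneLabel(str, Enum):
    femur = "femur"
    patella = "patella"
    tibia = "tibia"
    fibula = "fibula"
    talus = "talus"
    calcaneus = "calcaneus"
    metatarsal2 = "metatarsal2"


class Side(str, Enum):
    left = "L"
    right = "R"


class Provenance(str, Enum):
    direct = "direct"
    indirect = "indirect"
    ground_truth = "ground_truth"
    manual = "manual"


@dataclass
class TriangleMesh:
    """A single bone surface: vertices (mm, world) + triangle faces.

    Watertightness is not required — the fitting pipeline works on open
    surfaces — but degenerate faces are removed on cleaning.
    """

    vertices: np.ndarray
    faces: np.ndarray
    bone_label: BoneLabel | None = None
    side: Side | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    def validate(self) -> "TriangleMesh":
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise MeshValidationError("empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of range")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinates")
        return self

    # -- derived quantities ------------------------------------------------
    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def mean_edge_length(self) -> float:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        return float(d.mean())

    def edges(self) -> np.ndarray:
        """Unique undirected vertex edges, (E, 2)."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.bone_label, self.side
        )

    def cleaned(self) -> "TriangleMesh":
        """Merge duplicate vertices (1e-6 mm) and drop degenerate faces."""
        v, f = _merge_vertices(self.vertices, self.faces, MERGE_TOL_MM)
        keep = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
        f = f[keep]
        t = v[f]
        area = 0.5 * np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        f = f[area > 1e-14]
        return TriangleMesh(v, f, self.bone_label, self.side)

    def mirrored(self) -> "TriangleMesh":
        """Mirror across the sagittal (x = 0) plane.

        Flips handedness, so face orientation is repaired by reversing the
        vertex order of every face. Used to map left-side bones onto the
        single right-handed template and back.
        """
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        f = self.faces[:, ::-1].copy()
        side = None
        if self.side is not None:
            side = Side.left if self.side == Side.right else Side.right
        return TriangleMesh(v, f, self.bone_label, side)


def _merge_vertices(vertices, faces, tol):
    key = np.round(np.asarray(vertices, dtype=float) / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    v = vertices[first[order]]
    f = rank[inverse][faces]
    return np.asarray(v, dtype=float), np.asarray(f, dtype=np.int64)


@dataclass
class LabelVolume:
    """Integer label voxel grid with a voxel-centre -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    label_table: dict[int, BoneLabel] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if (self.spacing <= 0).any():
            raise MeshValidationError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def same_grid(self, other: "LabelVolume") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine
        )


@dataclass
class TemplateDefinition:
    """A per-bone template: corresponded mesh + landmark/region annotations.

    ``direct_landmarks`` maps each of this bone's direct acronyms to a
    template vertex index; ``regions`` maps region names (femoral head,
    neck, shaft slices, local-fit regions...) to vertex-index arrays;
    ``reference_points`` stores non-vertex anchor points (ground-truth
    positions of indirect landmarks on the undeformed template).
    """

    mesh: TriangleMesh
    bone_label: BoneLabel
    direct_landmarks: dict[str, int] = field(default_factory=dict)
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    reference_points: dict[str, np.ndarray] = field(default_factory=dict)
    proximal_marker: int | None = None  # vertex known to be proximal; orients axes

    def validate(self) -> "TemplateDefinition":
        self.mesh.validate()
        nv = len(self.mesh.vertices)
        for name, idx in self.direct_landmarks.items():
            if not (0 <= int(idx) < nv):
                raise MeshValidationError(f"landmark {name}: vertex index out of range")
        for name, idxs in self.regions.items():
            idxs = np.asarray(idxs)
            if idxs.size == 0:
                raise MeshValidationError(f"region {name} is empty")
            if idxs.min() < 0 or idxs.max() >= nv:
                raise MeshValidationError(f"region {name}: index out of range")
        return self


@dataclass
class LandmarkSet:
    """Named 3D landmarks (mm) for one subject/bone complex."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    provenance: dict[str, Provenance] = field(default_factory=dict)
    extra: dict[str, np.ndarray] = field(default_factory=dict)
    subject: str = ""
    side: Side | None = None

    def __setitem__(self, acronym: str, point):
        self.points[acronym] = np.asarray(point, dtype=float).reshape(3)

    def __getitem__(self, acronym: str) -> np.ndarray:
        from .errors import IncompleteLandmarkError

        if acronym not in self.points:
            raise IncompleteLandmarkError(f"missing landmark {acronym}")
        return self.points[acronym]

    def __contains__(self, acronym: str) -> bool:
        return acronym in self.points

    def __len__(self) -> int:
        return len(self.points)

    def set(self, acronym, point, provenance: Provenance):
        self[acronym] = point
        self.provenance[acronym] = provenance

    def update(self, other: "LandmarkSet"):
        for k, p in other.points.items():
            self.points[k] = p.copy()
            if k in other.provenance:
                self.provenance[k] = other.provenance[k]

    def transformed(self, R, t, s: float = 1.0) -> "LandmarkSet":
        out = LandmarkSet(subject=self.subject, side=self.side)
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        for k, p in self.points.items():
            out.points[k] = s * R @ p + t
            out.provenance[k] = self.provenance.get(k, Provenance.manual)
        return out


# ---------------------------------------------------------------------------
# I/O operations
# ---------------------------------------------------------------------------


def read_mesh(path, fmt: str | None = None, bone_label=None, side=None) -> TriangleMesh:
    """Load an STL/PLY/OBJ surface, merging duplicate vertices within 1e-6 mm."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # trimesh raises a zoo of exceptions
        raise MeshFormatError(f"unreadable {fmt} file {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshValidationError(f"no geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), bone_label, side)
    mesh = mesh.cleaned()
    return mesh.validate()


def write_mesh(mesh: TriangleMesh, path) -> None:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _MESH_FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    mesh.validate()
    mesh.as_trimesh().export(str(path))


def mask_to_mesh(
    volume: LabelVolume,
    label: int,
    iso_level: float = 0.5,
    smoothing_iterations: int = 0,
) -> TriangleMesh:
    """Extract the surface of one label as a world-mm triangle mesh.

    Marching cubes at ``iso_level`` on the binarized {0,1} field (volume
    padded by one voxel so boundary-touching regions close), mapped to
    world coordinates through the affine, optionally Taubin-smoothed
    (volume-preserving).
    """
    from skimage import measure

    binary = (volume.data == label).astype(np.float32)
    if binary.sum() == 0:
        raise EmptyRegionError(f"label {label} absent from volume")
    padded = np.pad(binary, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level)
    verts = verts - 1.0  # undo padding; still voxel-index coordinates
    world = volume.world_coords(verts)
    mesh = TriangleMesh(world, faces, volume.label_table.get(label))
    mesh = mesh.cleaned().validate()
    if smoothing_iterations > 0:
        tm = mesh.as_trimesh()
        trimesh.smoothing.filter_taubin(tm, iterations=smoothing_iterations)
        mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                            mesh.bone_label, mesh.side)
    return mesh


def read_label_volume(path, label_table=None) -> LabelVolume:
    """Read a NIfTI segmentation (.nii/.nii.gz) as a LabelVolume."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    return LabelVolume(data, img.affine, label_table or {})


def write_label_volume(volume: LabelVolume, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.affine)
    nib.save(img, str(path))


_KNOWN_ACRONYMS: frozenset | None = None


def _known_acronyms():
    global _KNOWN_ACRONYMS
    if _KNOWN_ACRONYMS is None:
        from .landmarks import LANDMARK_REGISTRY

        _KNOWN_ACRONYMS = frozenset(LANDMARK_REGISTRY)
    return _KNOWN_ACRONYMS


def read_landmarks(path) -> LandmarkSet:
    """Load a landmark JSON file (dialect in the module docstring)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        raw = payload["landmarks"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise LandmarkParseError(f"malformed landmark file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise LandmarkParseError(f"malformed landmark file {path}: "
                                 "'landmarks' must be an object")
    out = LandmarkSet(subject=str(payload.get("subject", "")))
    if payload.get("side") in ("L", "R"):
        out.side = Side(payload["side"])
    prov = payload.get("provenance", {})
    for name, coords in raw.items():
        try:
            pt = np.asarray([float(c) for c in coords], dtype=float)
            if pt.shape != (3,):
                raise ValueError("need exactly 3 coordinates")
        except (TypeError, ValueError) as exc:
            raise LandmarkParseError(f"bad coordinates for {name}: {exc}") from exc
        if name in _known_acronyms():
            out.points[name] = pt
            out.provenance[name] = Provenance(prov.get(name, "manual"))
        else:
            warnings.warn(f"unknown landmark acronym {name!r}; kept under 'extra'")
            out.extra[name] = pt
    return out


def write_landmarks(landmarks: LandmarkSet, path, bone: str = "") -> None:
    payload = {
        "subject": landmarks.subject,
        "bone": bone,
        "side": landmarks.side.value if landmarks.side else None,
        "landmarks": {k: [float(c) for c in p] for k, p in landmarks.points.items()},
        "provenance": {k: v.value for k, v in landmarks.provenance.items()},
    }
    if landmarks.extra:
        payload["extra"] = {k: [float(c) for c in p] for k, p in landmarks.extra.items()}
    Path(path).write_text(json.dumps(payload, indent=1))
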