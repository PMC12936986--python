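"""Synthetic corresponded bone cohorts with analytic ground truth.

Stylized parametric bones — not anatomically realistic surfaces, but
geometry with the full 45-landmark vocabulary, named regions (femoral head
sphere, neck, shaft slabs, ...) and exact vertex-to-vertex correspondence
across a cohort. They stand in for real training data so that every stage
of the pipeline (shape-model construction, cascaded fitting, landmark
transfer, frames, measurements) can be tested against known truth:

* every subject is the common template deformed by a smooth low-order
  displacement field with per-subject random coefficients, so cohorts are
  corresponded by construction;
* ground-truth landmarks are transported by the same field, exactly;
* the femoral head region of the *template* is an exact sphere patch of
  known centre and radius;
* closed meshes can be voxelized into label volumes to emulate voxel-wise
  segmentation masks.

All randomness flows through one seeded generator; the same seed
reproduces every fixture bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyRegionError, MeshValidationError
from .geometry import voxelize_parity
from .meshdata import (
    BoneLabel,
    LabelVolume,
    LandmarkSet,
    Provenance,
    Side,
    TemplateDefinition,
    TriangleMesh,
)
from .ssm import CorrespondedCohort

# World convention of the stylized right lower limb: +x lateral, +y anterior,
# +z superior; the knee joint line sits near z = 0 and the foot near z = -490.

FEMORAL_HEAD_CENTRE = np.array([0.0, 4.0, 400.0])
FEMORAL_HEAD_RADIUS = 24.0


# ---------------------------------------------------------------------------
# primitive constructors (deterministic vertex ordering)
# ---------------------------------------------------------------------------


def _ellipsoid(centre, radii, n_lat, n_lon, rotation=None):
    """UV ellipsoid with poles along local +z/−z; returns (V, F).

    Vertex 0 is the north (+z) pole, vertex −1 the south (−z) pole.
    """
    centre = np.asarray(centre, dtype=float)
    radii = np.asarray(radii, dtype=float)
    lats = np.linspace(0, np.pi, n_lat + 2)[1:-1]
    lons = np.linspace(0, 2 * np.pi, n_lon, endpoint=False)
    ring = np.stack([np.cos(lons), np.sin(lons)], axis=1)
    verts = [np.array([0.0, 0.0, 1.0])]
    for la in lats:
        verts.append(
            np.column_stack([np.sin(la) * ring[:, 0], np.sin(la) * ring[:, 1],
                             np.full(n_lon, np.cos(la))])
        )
    verts.append(np.array([0.0, 0.0, -1.0]))
    v = np.vstack([np.atleast_2d(x) for x in verts]) * radii
    if rotation is not None:
        v = v @ np.asarray(rotation, dtype=float).T
    v = v + centre

    faces = []
    # top cap (outward: CCW seen from outside)
    for j in range(n_lon):
        faces.append([0, 1 + j, 1 + (j + 1) % n_lon])
    for i in range(n_lat - 1):
        a = 1 + i * n_lon
        b = 1 + (i + 1) * n_lon
        for j in range(n_lon):
            j2 = (j + 1) % n_lon
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    south = 1 + n_lat * n_lon
    a = 1 + (n_lat - 1) * n_lon
    for j in range(n_lon):
        faces.append([south, a + (j + 1) % n_lon, a + j])
    return v, np.asarray(faces, dtype=np.int64)


def _tube(p0, p1, r0, r1, n_rings, n_seg):
    """Capped cone/cylinder from p0 to p1; returns (V, F)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise MeshValidationError("degenerate tube")
    w = axis / length
    ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u)
    vv = np.cross(w, u)
    angles = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
    circ = np.outer(np.cos(angles), u) + np.outer(np.sin(angles), vv)

    verts = [p0]
    for i in range(n_rings + 1):
        t = i / n_rings
        c = p0 + t * axis
        r = (1 - t) * r0 + t * r1
        verts.append(c + r * circ)
    verts.append(p1)
    v = np.vstack([np.atleast_2d(x) for x in verts])

    faces = []
    for j in range(n_seg):  # bottom cap
        faces.append([0, 1 + (j + 1) % n_seg, 1 + j])
    for i in range(n_rings):
        a = 1 + i * n_seg
        b = 1 + (i + 1) * n_seg
        for j in range(n_seg):
            j2 = (j + 1) % n_seg
            faces.append([a + j, b + j2, b + j])
            faces.append([a + j, a + j2, b + j2])
    top = 1 + (n_rings + 1) * n_seg
    a = 1 + n_rings * n_seg
    for j in range(n_seg):
        faces.append([top, a + j, a + (j + 1) % n_seg])
    return v, np.asarray(faces, dtype=np.int64)


def _thicken_patch(grid: np.ndarray, offset) -> tuple[np.ndarray, np.ndarray]:
    """Close an (nv, nu, 3) surface grid into a watertight slab.

    The outer layer is the grid itself; the inner layer is offset by a
    constant vector; boundary walls stitch the two layers.
    """
    nv, nu, _ = grid.shape
    outer = grid.reshape(-1, 3)
    inner = outer + np.asarray(offset, dtype=float)
    verts = np.vstack([outer, inner])
    N = len(outer)

    faces = []
    for i in range(nv - 1):
        for j in range(nu - 1):
            k = i * nu + j
            faces.append([k, k + nu, k + 1])
            faces.append([k + 1, k + nu, k + nu + 1])
            faces.append([N + k, N + k + 1, N + k + nu])
            faces.append([N + k + 1, N + k + nu + 1, N + k + nu])
    # perimeter walls, oriented away from the slab interior
    base = (nv - 1) * nu
    boundary = (
        [(j + 1, j) for j in range(nu - 1)]  # first row
        + [(base + j, base + j + 1) for j in range(nu - 1)]  # last row
        + [(i * nu, (i + 1) * nu) for i in range(nv - 1)]  # first column
        + [((i + 1) * nu + nu - 1, i * nu + nu - 1) for i in range(nv - 1)]
    )
    for a, b in boundary:
        faces.append([a, b, N + b])
        faces.append([a, N + b, N + a])
    faces = np.asarray(faces, dtype=np.int64)
    # make the winding globally consistent/outward via the signed volume
    vol = np.einsum(
        "ij,ij->i",
        verts[faces[:, 0]],
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]]),
    ).sum() / 6.0
    if vol < 0:
        faces = faces[:, ::-1]
    return verts, faces


def _rot_z(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


def _rot_x(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg):
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])


class _Assembly:
    """Accumulates components; tracks per-component vertex index ranges."""

    def __init__(self):
        self.vertices: list[np.ndarray] = []
        self.faces: list[np.ndarray] = []
        self.slices: dict[str, slice] = {}
        self._n = 0

    def add(self, name, v, f):
        self.faces.append(np.asarray(f) + self._n)
        self.vertices.append(np.asarray(v))
        self.slices[name] = slice(self._n, self._n + len(v))
        self._n += len(v)
        return self.slices[name]

    def build(self) -> tuple[np.ndarray, np.ndarray]:
        return np.vstack(self.vertices), np.vstack(self.faces)

    def indices(self, name) -> np.ndarray:
        s = self.slices[name]
        return np.arange(s.start, s.stop, dtype=np.int64)

    def nearest(self, vertices, name, anchor) -> int:
        """Global index of the component vertex nearest an anchor point."""
        idx = self.indices(name)
        d = np.linalg.norm(vertices[idx] - np.asarray(anchor, dtype=float), axis=1)
        return int(idx[np.argmin(d)])


# ---------------------------------------------------------------------------
# bone templates
# ---------------------------------------------------------------------------


def _res(n, resolution):
    return max(3, int(round(n * resolution)))


def _femur(resolution):
    a = _Assembly()
    # exact sphere patch: the femoral head
    v, f = _ellipsoid(FEMORAL_HEAD_CENTRE, [FEMORAL_HEAD_RADIUS] * 3,
                      _res(7, resolution), _res(12, resolution))
    a.add("head", v, f)
    v, f = _tube([40, -6, 352], [22, 0, 388], 12, 11, _res(4, resolution), _res(10, resolution))
    a.add("neck", v, f)
    v, f = _tube([3, 0, 30], [38, 0, 340], 14.5, 13.5, _res(16, resolution), _res(12, resolution))
    a.add("shaft", v, f)
    v, f = _ellipsoid([24, -10, -12], [15, 24, 16], _res(6, resolution), _res(10, resolution))
    a.add("lat_condyle", v, f)
    v, f = _ellipsoid([-24, -6, -13], [15, 24, 17.5], _res(6, resolution), _res(10, resolution))
    a.add("med_condyle", v, f)
    # trochlear groove: a V-profile anterior patch between the condyles
    v, f = _ellipsoid([0, -16, -4], [6, 6, 6], _res(4, resolution), _res(8, resolution))
    a.add("notch", v, f)
    nu, nv = 2 * _res(6, resolution) + 1, _res(6, resolution)
    us = np.linspace(-1, 1, nu)
    zs = np.linspace(-18, 6, nv)
    grid = np.array(
        [[[18 * u, 21 + 5 * abs(u) - 0.02 * z, z] for u in us] for z in zs]
    )
    gv, gf = _thicken_patch(grid, [0.0, -8.0, 0.0])
    a.add("trochlea", gv, gf)

    verts, faces = a.build()
    mid_row = (nv // 2) * nu
    troch0 = a.slices["trochlea"].start
    direct = {
        "FLC": a.slices["lat_condyle"].stop - 1,   # south pole: min-z by construction
        "FMC": a.slices["med_condyle"].stop - 1,
        "FLCP": a.nearest(verts, "lat_condyle", [24, -34, -12]),
        "FMCP": a.nearest(verts, "med_condyle", [-24, -30, -13]),
        "FLE": a.nearest(verts, "lat_condyle", [39, -10, -12]),
        "FME": a.nearest(verts, "med_condyle", [-39, -6, -13]),
        "FMS": a.nearest(verts, "med_condyle", [-38, -13, -5]),
        "FLCC": a.nearest(verts, "lat_condyle", [24, 10, -24]),
        "FMCC": a.nearest(verts, "med_condyle", [-24, 12, -26]),
        "COK": a.nearest(verts, "notch", [0, -22, -4]),
        "TRLP": troch0 + mid_row + nu - 1,
        "TRMP": troch0 + mid_row,
        "TGCP": troch0 + mid_row + nu // 2,
    }
    shaft_idx = a.indices("shaft")
    z = verts[shaft_idx, 2]
    zlo, zhi = z.min(), z.max()
    regions = {
        "femoral_head": a.indices("head"),
        "femoral_neck": a.indices("neck"),
        "femoral_shaft_proximal": shaft_idx[z >= zhi - 0.2 * (zhi - zlo)],
        "femoral_shaft_distal": shaft_idx[z <= zlo + 0.2 * (zhi - zlo)],
        "lat_condyle": a.indices("lat_condyle"),
        "med_condyle": a.indices("med_condyle"),
    }
    reference = {
        "FHC": FEMORAL_HEAD_CENTRE.copy(),
        "FNC": verts[regions["femoral_neck"]].mean(axis=0),
        "FA1": verts[regions["femoral_shaft_proximal"]].mean(axis=0),
        "FA2": verts[regions["femoral_shaft_distal"]].mean(axis=0),
    }
    marker = int(a.slices["head"].start)  # head north pole: proximal end
    return verts, faces, direct, regions, reference, marker


def _tibia(resolution):
    a = _Assembly()
    v, f = _ellipsoid([0, -2, -56], [39, 31, 9], _res(6, resolution), _res(14, resolution),
                      rotation=_rot_y(-2.0) @ _rot_x(7.0))
    a.add("plateau", v, f)
    v, f = _tube([0, 2, -400], [0, 0, -62], 11, 13, _res(16, resolution), _res(12, resolution))
    a.add("shaft", v, f)
    v, f = _ellipsoid([10, 14, -80], [7, 7, 9], _res(4, resolution), _res(8, resolution))
    a.add("tuberosity", v, f)
    v, f = _ellipsoid([-22, 21, -405], [8, 8, 11], _res(4, resolution), _res(8, resolution))
    a.add("med_malleolus", v, f)
    v, f = _ellipsoid([24, -21, -415], [8, 8, 11], _res(4, resolution), _res(8, resolution))
    a.add("lat_malleolus", v, f)
    v, f = _ellipsoid([0, 0, -408], [17, 18, 7], _res(4, resolution), _res(10, resolution),
                      rotation=_rot_y(1.5) @ _rot_x(-12.0))
    a.add("plafond", v, f)

    verts, faces = a.build()
    direct = {
        "TLCL": a.nearest(verts, "plateau", [39, -2, -54]),
        "TMCM": a.nearest(verts, "plateau", [-39, -2, -59]),
        "TLCA": a.nearest(verts, "plateau", [20, 26, -52]),
        "TLCP": a.nearest(verts, "plateau", [20, -30, -59]),
        "TMCA": a.nearest(verts, "plateau", [-20, 26, -53]),
        "TMCP": a.nearest(verts, "plateau", [-20, -30, -60]),
        "TLCC": a.nearest(verts, "plateau", [20, -2, -48]),
        "TMCC": a.nearest(verts, "plateau", [-20, -2, -49]),
        "TPPPL": a.nearest(verts, "plateau", [24, -28, -58]),
        "TPPPM": a.nearest(verts, "plateau", [-24, -28.8, -59]),
        "TTP": a.nearest(verts, "tuberosity", [14, 16, -76]),
        "TMM": a.nearest(verts, "med_malleolus", [-29, 22, -407]),
        "TLM": a.nearest(verts, "lat_malleolus", [31, -22, -417]),
        "MDTAS": a.nearest(verts, "plafond", [-16, 0, -410]),
        "LDTAS": a.nearest(verts, "plafond", [16, 0, -409]),
        "ADTAS": a.nearest(verts, "plafond", [0, 17, -407]),
        "PDTAS": a.nearest(verts, "plafond", [0, -17, -411]),
    }
    shaft_idx = a.indices("shaft")
    z = verts[shaft_idx, 2]
    zlo, zhi = z.min(), z.max()
    regions = {
        "tibial_shaft_proximal": shaft_idx[z >= zhi - 0.2 * (zhi - zlo)],
        "tibial_shaft_distal": shaft_idx[z <= zlo + 0.2 * (zhi - zlo)],
        "plateau": a.indices("plateau"),
        "plafond": a.indices("plafond"),
    }
    reference = {
        "TA1": verts[regions["tibial_shaft_proximal"]].mean(axis=0),
        "TA2": verts[regions["tibial_shaft_distal"]].mean(axis=0),
    }
    marker = a.nearest(verts, "plateau", [0, -2, -47])
    return verts, faces, direct, regions, reference, marker


def _patella(resolution):
    a = _Assembly()
    v, f = _ellipsoid([2, 36, -8], [24, 11, 17], _res(5, resolution), _res(10, resolution),
                      rotation=_rot_z(-16.0))
    a.add("body", v, f)
    # inferior apex: the distal pole of the patella; breaks the ellipsoid's
    # rotational symmetry so rigid correspondence is well defined
    v, f = _ellipsoid([2, 42, -24], [8, 7, 8], _res(4, resolution), _res(8, resolution))
    a.add("apex", v, f)
    verts, faces = a.build()
    direct = {
        "PMP": a.nearest(verts, "body", np.array([2, 36, -8]) + _rot_z(-16.0) @ [-24, 0, 0]),
        "PLP": a.nearest(verts, "body", np.array([2, 36, -8]) + _rot_z(-16.0) @ [24, 0, 0]),
    }
    marker = 0
    return verts, faces, direct, {"body": a.indices("body")}, {}, marker


def _talus(resolution):
    a = _Assembly()
    v, f = _ellipsoid([0, 2, -436], [22, 26, 14], _res(5, resolution), _res(10, resolution))
    a.add("body", v, f)
    # talar head/neck: anterior-medial protrusion; breaks the ellipsoid's
    # rotational symmetry so rigid correspondence is well defined
    v, f = _ellipsoid([-6, 30, -440], [10, 12, 9], _res(4, resolution), _res(8, resolution))
    a.add("head", v, f)
    verts, faces = a.build()
    direct = {
        "TDL": a.nearest(verts, "body", [20, 2, -427]),
        "TDM": a.nearest(verts, "body", [-20, 2, -428]),
    }
    marker = 0
    return verts, faces, direct, {"body": a.indices("body")}, {}, marker


def _calcaneus(resolution):
    a = _Assembly()
    v, f = _ellipsoid([2, -16, -462], [15, 38, 18], _res(6, resolution), _res(10, resolution),
                      rotation=_rot_x(22.0))
    a.add("body", v, f)
    # anterior process (towards the cuboid); breaks the ellipsoid's
    # rotational symmetry so rigid correspondence is well defined
    v, f = _ellipsoid([2, 18, -452], [9, 12, 8], _res(4, resolution), _res(8, resolution))
    a.add("anterior", v, f)
    verts, faces = a.build()
    direct = {
        "CIP": int(np.argmin(verts[:, 2])),
        "CIPA": a.nearest(verts, "body", [2, 15, -464]),
    }
    marker = int(np.argmax(verts[:, 2]))
    return verts, faces, direct, {"body": a.indices("body")}, {}, marker


def _metatarsal2(resolution):
    a = _Assembly()
    v, f = _tube([0, 78, -472], [0, 126, -466], 6, 5, _res(6, resolution), _res(8, resolution))
    a.add("shaft", v, f)
    v, f = _ellipsoid([0, 135, -465], [9, 9, 9], _res(5, resolution), _res(8, resolution))
    a.add("head", v, f)
    verts, faces = a.build()
    regions = {"metatarsal_head": a.indices("head"), "shaft": a.indices("shaft")}
    reference = {"MT2_HEAD": np.array([0.0, 135.0, -465.0])}
    marker = 0
    return verts, faces, {}, regions, reference, marker


_BUILDERS = {
    BoneLabel.femur: _femur,
    BoneLabel.tibia: _tibia,
    BoneLabel.patella: _patella,
    BoneLabel.talus: _talus,
    BoneLabel.calcaneus: _calcaneus,
    BoneLabel.metatarsal2: _metatarsal2,
}

SUPPORTED_BONES = tuple(_BUILDERS)


def make_template(bone_kind, resolution: float = 1.0) -> TemplateDefinition:
    """Deterministic stylized template for one bone.

    ``resolution`` scales the tessellation density (1.0 ≈ a few hundred to
    ~2000 vertices per bone). The femoral head region of the femur template
    is an exact sphere patch of known centre and radius.
    """
    bone = BoneLabel(bone_kind)
    if bone not in _BUILDERS:
        raise ValueError(f"unsupported bone kind: {bone_kind}")
    verts, faces, direct, regions, reference, marker = _BUILDERS[bone](resolution)
    mesh = TriangleMesh(verts, faces, bone, Side.right).validate()
    tpl = TemplateDefinition(
        mesh=mesh,
        bone_label=bone,
        direct_landmarks=direct,
        regions={k: np.asarray(v, dtype=np.int64) for k, v in regions.items()},
        reference_points={k: np.asarray(v, dtype=float) for k, v in reference.items()},
        proximal_marker=marker,
    )
    return tpl.validate()


def make_all_templates(resolution: float = 1.0) -> dict[BoneLabel, TemplateDefinition]:
    return {bone: make_template(bone, resolution) for bone in SUPPORTED_BONES}


# ---------------------------------------------------------------------------
# deformation model
# ---------------------------------------------------------------------------


@dataclass
class DeformationSpec:
    """Smooth low-order polynomial displacement fields + vertex noise.

    Each basis field maps world points to a displacement (mm per unit
    coefficient); per-subject coefficients are standard-normal draws scaled
    by ``sds``. ``noise_sd`` is isotropic per-vertex Gaussian surface noise
    (mm) applied to mesh vertices only — landmark truth follows the smooth
    field exactly. ``cap_mm`` bounds the allowed smooth displacement; a
    draw exceeding it is resampled (logged retry).
    """

    centre: np.ndarray
    half_extent: float
    sds: tuple[float, ...] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.1
    cap_mm: float = 40.0

    def n_fields(self) -> int:
        return len(self.sds)

    def basis(self, points: np.ndarray) -> np.ndarray:
        """(n_fields, n_points, 3) displacement per unit coefficient."""
        p = np.asarray(points, dtype=float)
        d = (p - self.centre) / self.half_extent  # normalized coords
        fields = [
            np.column_stack([np.zeros(len(p)), np.zeros(len(p)),
                             0.025 * (p[:, 2] - self.centre[2])]),  # axial scale
            np.column_stack([0.035 * (p[:, 0] - self.centre[0]),
                             0.035 * (p[:, 1] - self.centre[1]),
                             np.zeros(len(p))]),  # transverse scale
            np.column_stack([3.0 * d[:, 2] ** 2, np.zeros(len(p)),
                             np.zeros(len(p))]),  # coronal bow (quadratic)
        ]
        return np.stack(fields[: self.n_fields()])

    def displacement(self, points: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        c = np.asarray(coeffs, dtype=float)
        return np.einsum("k,kij->ij", c * np.asarray(self.sds), self.basis(points))

    def apply(self, points: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement(points, coeffs)


def default_deformation_spec(meshes, noise_sd: float = 0.1) -> DeformationSpec:
    """Spec whose normalisation covers the given mesh(es)."""
    if isinstance(meshes, TriangleMesh):
        meshes = [meshes]
    allv = np.vstack([m.vertices for m in meshes])
    lo, hi = allv.min(axis=0), allv.max(axis=0)
    return DeformationSpec(
        centre=0.5 * (lo + hi),
        half_extent=float(0.5 * np.linalg.norm(hi - lo)),
        noise_sd=noise_sd,
    )


@dataclass
class SubjectTruth:
    """Per-subject generating parameters + exact landmark positions."""

    coeffs: np.ndarray
    landmarks: LandmarkSet
    seed: int
    retries: int = 0


def _truth_landmarks(template: TemplateDefinition, spec, coeffs) -> LandmarkSet:
    out = LandmarkSet(side=Side.right)
    verts = template.mesh.vertices
    for name, idx in template.direct_landmarks.items():
        p = verts[idx] if spec is None else spec.apply(verts[[idx]], coeffs)[0]
        out.set(name, p, Provenance.ground_truth)
    for name, p in template.reference_points.items():
        q = p if spec is None else spec.apply(p[None, :], coeffs)[0]
        out.set(name, q, Provenance.ground_truth)
    return out


def complete_truth_midpoints(landmarks: LandmarkSet) -> LandmarkSet:
    """Fill TCP/TCD/TDC from their defining endpoint truth positions."""
    for name, (a, b) in (("TCP", ("TLCC", "TMCC")), ("TCD", ("TMM", "TLM")),
                         ("TDC", ("TDL", "TDM"))):
        if a in landmarks and b in landmarks:
            landmarks.set(name, 0.5 * (landmarks[a] + landmarks[b]),
                          Provenance.ground_truth)
    return landmarks


def sample_cohort(
    template: TemplateDefinition,
    n: int,
    spec: DeformationSpec | None = None,
    seed: int = 0,
) -> tuple[CorrespondedCohort, list[SubjectTruth]]:
    """Draw ``n`` corresponded subjects of one bone + their exact truth.

    Deformations are the spec's smooth basis fields with seeded normal
    coefficients; vertex noise (spec.noise_sd) perturbs surfaces only.
    Draws whose peak smooth displacement exceeds the spec's cap are
    resampled (retry count recorded on the subject truth).
    """
    if n < 2:
        raise MeshValidationError("cohort needs n >= 2")
    spec = spec or default_deformation_spec(template.mesh)
    rng = np.random.default_rng(seed)
    verts = template.mesh.vertices
    shapes = np.empty((n, len(verts), 3))
    truths = []
    for i in range(n):
        retries = 0
        while True:
            coeffs = rng.standard_normal(spec.n_fields())
            disp = spec.displacement(verts, coeffs)
            if np.linalg.norm(disp, axis=1).max() <= spec.cap_mm:
                break
            retries += 1
            if retries > 50:
                raise MeshValidationError("deformation cap repeatedly exceeded")
        noisy = verts + disp
        if spec.noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.noise_sd, size=verts.shape)
        shapes[i] = noisy
        truth = _truth_landmarks(template, spec, coeffs)
        truths.append(SubjectTruth(coeffs, complete_truth_midpoints(truth), seed, retries))
    return CorrespondedCohort(shapes, [f"synthetic:{seed}:{i}" for i in range(n)]), truths


@dataclass
class SyntheticSubject:
    """A full synthetic lower limb: one mesh per bone + 45-landmark truth."""

    meshes: dict[BoneLabel, TriangleMesh]
    landmarks: LandmarkSet
    coeffs: np.ndarray
    seed: int


def make_subject(
    templates: dict[BoneLabel, TemplateDefinition],
    seed: int = 0,
    spec: DeformationSpec | None = None,
) -> SyntheticSubject:
    """One multi-bone subject deformed by a single shared smooth field."""
    spec = spec or default_deformation_spec([t.mesh for t in templates.values()])
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(spec.n_fields())
    meshes = {}
    truth = LandmarkSet(subject=f"synth{seed:04d}", side=Side.right)
    for bone, tpl in templates.items():
        verts = spec.apply(tpl.mesh.vertices, coeffs)
        if spec.noise_sd > 0:
            verts = verts + rng.normal(0.0, spec.noise_sd, size=verts.shape)
        meshes[bone] = TriangleMesh(verts, tpl.mesh.faces.copy(), bone, Side.right)
        truth.update(_truth_landmarks(tpl, spec, coeffs))
    complete_truth_midpoints(truth)
    return SyntheticSubject(meshes, truth, coeffs, seed)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def voxelize(mesh: TriangleMesh, spacing: float = 1.0, pad_voxels: int = 2,
             label: int = 1) -> LabelVolume:
    """Rasterize a closed mesh into a label volume (inside test per component).

    The grid is padded ``pad_voxels`` beyond the bounding box; the affine
    maps voxel centres to world mm. Raises for open surfaces.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    tm = mesh.as_trimesh()
    components = tm.split(only_watertight=False)
    if len(components) == 0:
        components = [tm]
    for comp in components:
        if not comp.is_watertight:
            raise MeshValidationError("voxelize requires closed (watertight) components")
    lo = mesh.vertices.min(axis=0) - pad_voxels * spacing
    hi = mesh.vertices.max(axis=0) + pad_voxels * spacing
    # snap the origin to the spacing lattice so whole-voxel translations
    # of the mesh shift the mask exactly
    origin = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - origin) / spacing).astype(int)
    mask = np.zeros(tuple(shape), dtype=bool)
    for comp in components:
        mask |= voxelize_parity(np.asarray(comp.vertices), np.asarray(comp.faces),
                                origin, [spacing] * 3, shape)
    if not mask.any():
        raise EmptyRegionError("voxelization produced an empty mask")
    affine = np.eye(4)
    affine[:3, :3] *= spacing
    affine[:3, 3] = origin + 0.5 * spacing
    table = {label: mesh.bone_label} if mesh.bone_label else {}
    return LabelVolume(mask.astype(np.int16) * label, affine, table)
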