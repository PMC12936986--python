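"""Anatomical coordinate frames: the knee frame and the foot–ankle frame.

Knee frame (after Victor et al.): the z-axis is the femoral mechanical
axis, from the centre of the knee (COK, the most posterior point of the
trochlear groove, which is also the origin) to the femoral head centre
(FHC). The x-axis parallels the posterior condylar line (FLCP–FMCP)
orthogonalised against z; y completes the right-handed triad. The coronal
plane is spanned by (x, z), the sagittal by (y, z) and the axial by (x, y).

Foot–ankle frame: the z-axis is the world vertical (weight-bearing
acquisition: the scanner's horizontal plane is the ground); the y-axis is
the ground-plane projection of the line from the most plantar calcaneal
vertex to the second-metatarsal head centre (sphere fit); the origin is the
talus centroid.

Sign convention: x̂ points laterally on right limbs and is mirrored on left
limbs so that signed measurements share one convention across sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, IncompleteLandmarkError
from .landmarks import fit_sphere
from .meshdata import LandmarkSet, Side, TriangleMesh

PLANES = ("coronal", "sagittal", "axial")

#: In-plane axis pairs; the third axis is the plane normal.
_PLANE_AXES = {"coronal": ("x", "z"), "sagittal": ("y", "z"), "axial": ("x", "y")}


@dataclass
class AnatomicalFrame:
    """Origin + right-handed orthonormal axes defining the anatomical planes."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        for name in "xyz":
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        self.validate()

    def validate(self) -> "AnatomicalFrame":
        M = np.stack([self.x, self.y, self.z])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if not np.allclose(np.cross(self.x, self.y), self.z, atol=1e-9):
            raise DegenerateGeometryError("frame is not right-handed (x × y ≠ z)")
        return self

    def axis(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def plane_normal(self, plane: str) -> np.ndarray:
        a, b = _PLANE_AXES[plane]
        (third,) = set("xyz") - {a, b}
        return self.axis(third)

    def rotation(self) -> np.ndarray:
        """World→frame rotation matrix (rows x̂, ŷ, ẑ)."""
        return np.stack([self.x, self.y, self.z])

    def transformed(self, R, t) -> "AnatomicalFrame":
        R = np.asarray(R, dtype=float)
        return AnatomicalFrame(
            R @ self.origin + np.asarray(t, dtype=float),
            R @ self.x, R @ self.y, R @ self.z,
        )


def _unit(v, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def build_knee_frame(landmarks: LandmarkSet, side: Side = Side.right) -> AnatomicalFrame:
    """Knee coordinate system from COK, FHC, FLCP, FMCP.

    z = unit(FHC − COK); x = the posterior condylar direction (oriented
    medial→lateral per side) orthogonalised against z; y = z × x.
    """
    for name in ("COK", "FHC", "FLCP", "FMCP"):
        if name not in landmarks:
            raise IncompleteLandmarkError(f"missing landmark {name}")
    cok = landmarks["COK"]
    z = _unit(landmarks["FHC"] - cok, "mechanical axis (FHC−COK)")
    pcl = landmarks["FLCP"] - landmarks["FMCP"]  # medial → lateral on right limbs
    if side == Side.left:
        pcl = -pcl
    pcl_u = _unit(pcl, "posterior condylar line")
    if abs(pcl_u @ z) > 0.999:
        raise DegenerateGeometryError("PCL (nearly) parallel to the mechanical axis")
    x = _unit(pcl - (pcl @ z) * z, "orthogonalised PCL")
    y = np.cross(z, x)
    return AnatomicalFrame(cok, x, y, z)


def build_foot_frame(
    landmarks: LandmarkSet,
    calcaneus: TriangleMesh,
    talus: TriangleMesh,
    metatarsal2: TriangleMesh,
    metatarsal_head_region: np.ndarray | None = None,
    vertical=(0.0, 0.0, 1.0),
) -> AnatomicalFrame:
    """Foot–ankle frame from the calcaneus, talus and second metatarsal.

    ``vertical`` is the world up direction of the standing acquisition.
    The metatarsal head centre comes from a sphere fit over
    ``metatarsal_head_region`` vertex indices (the whole metatarsal mesh if
    omitted). The heel point is the most plantar calcaneal vertex.
    """
    for mesh, what in ((calcaneus, "calcaneus"), (talus, "talus"), (metatarsal2, "metatarsal")):
        if mesh is None or len(mesh.vertices) == 0:
            raise IncompleteLandmarkError(f"missing {what} mesh for the foot frame")
    z = _unit(np.asarray(vertical, dtype=float), "vertical")
    plantar = calcaneus.vertices[np.argmin(calcaneus.vertices @ z)]
    head_pts = metatarsal2.vertices
    if metatarsal_head_region is not None:
        head_pts = head_pts[np.asarray(metatarsal_head_region)]
    head_centre, _, _ = fit_sphere(head_pts)
    heel_to_toe = head_centre - plantar
    horiz = heel_to_toe - (heel_to_toe @ z) * z
    if np.linalg.norm(horiz) < 1e-9:
        raise DegenerateGeometryError("heel-to-toe direction is vertical")
    y = _unit(horiz, "foot axis")
    x = np.cross(y, z)
    return AnatomicalFrame(talus.vertices.mean(axis=0), x, y, z)


def project_to_plane(vector, frame: AnatomicalFrame, plane: str) -> np.ndarray:
    """2D coefficients of a 3D vector on the plane's two defining axes."""
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}")
    a, b = _PLANE_AXES[plane]
    v = np.asarray(vector, dtype=float)
    return np.array([v @ frame.axis(a), v @ frame.axis(b)])
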