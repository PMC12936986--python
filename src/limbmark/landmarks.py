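"""The 45-landmark registry, correspondence transfer, and indirect derivation.

36 landmarks are *direct*: they live at annotated template vertices and are
carried onto a patient bone by the vertex correspondence of the fitted
template, then snapped to the raw target surface to remove the residual
fitting offset. The remaining 9 are *indirect*:

* FHC — centre of a least-squares sphere fitted to the femoral-head region;
* FNC, FA1, FA2, TA1, TA2 — centroids of transferred region vertex sets
  (femoral neck; proximal/distal femoral shaft; proximal/distal tibial shaft);
* TCP = midpoint(TLCC, TMCC); TCD = midpoint(TMM, TLM); TDC = midpoint(TDL, TDM).

Indirect landmarks generally do not lie on the bone surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateGeometryError, IncompleteLandmarkError
from .geometry import SurfaceIndex
from .meshdata import (
    BoneLabel,
    LandmarkSet,
    Provenance,
    TemplateDefinition,
    TriangleMesh,
)

SNAP_CAP_MM = 2.0


@dataclass(frozen=True)
class LandmarkRecord:
    acronym: str
    bone: BoneLabel
    kind: str  # "direct" | "indirect"
    rule: str | None = None  # derivation rule id for indirect landmarks


def _rec(acr, bone, kind="direct", rule=None):
    return LandmarkRecord(acr, BoneLabel(bone), kind, rule)


#: All 45 landmark acronyms. TLM is anatomically on the distal fibula; the
#: stylized tibia template carries a lateral-malleolus stand-in, so it is
#: registered under the tibia here.
LANDMARK_REGISTRY: dict[str, LandmarkRecord] = {
    r.acronym: r
    for r in [
        _rec("FHC", "femur", "indirect", "sphere:femoral_head"),
        _rec("FNC", "femur", "indirect", "centroid:femoral_neck"),
        _rec("FA1", "femur", "indirect", "centroid:femoral_shaft_proximal"),
        _rec("FA2", "femur", "indirect", "centroid:femoral_shaft_distal"),
        _rec("FLC", "femur"),
        _rec("FMC", "femur"),
        _rec("FMCP", "femur"),
        _rec("FLCP", "femur"),
        _rec("FMCC", "femur"),
        _rec("FLCC", "femur"),
        _rec("COK", "femur"),
        _rec("FLE", "femur"),
        _rec("FME", "femur"),
        _rec("FMS", "femur"),
        _rec("TRLP", "femur"),
        _rec("TRMP", "femur"),
        _rec("TGCP", "femur"),
        _rec("PMP", "patella"),
        _rec("PLP", "patella"),
        _rec("TLCL", "tibia"),
        _rec("TLCA", "tibia"),
        _rec("TLCP", "tibia"),
        _rec("TLCC", "tibia"),
        _rec("TMCM", "tibia"),
        _rec("TMCA", "tibia"),
        _rec("TMCP", "tibia"),
        _rec("TMCC", "tibia"),
        _rec("TPPPL", "tibia"),
        _rec("TPPPM", "tibia"),
        _rec("TTP", "tibia"),
        _rec("MDTAS", "tibia"),
        _rec("LDTAS", "tibia"),
        _rec("ADTAS", "tibia"),
        _rec("PDTAS", "tibia"),
        _rec("TCP", "tibia", "indirect", "midpoint:TLCC,TMCC"),
        _rec("TA1", "tibia", "indirect", "centroid:tibial_shaft_proximal"),
        _rec("TA2", "tibia", "indirect", "centroid:tibial_shaft_distal"),
        _rec("TLM", "tibia"),
        _rec("TMM", "tibia"),
        _rec("TCD", "tibia", "indirect", "midpoint:TMM,TLM"),
        _rec("TDL", "talus"),
        _rec("TDM", "talus"),
        _rec("TDC", "talus", "indirect", "midpoint:TDL,TDM"),
        _rec("CIP", "calcaneus"),
        _rec("CIPA", "calcaneus"),
    ]
}

ALL_ACRONYMS = tuple(LANDMARK_REGISTRY)
DIRECT_ACRONYMS = tuple(a for a, r in LANDMARK_REGISTRY.items() if r.kind == "direct")
INDIRECT_ACRONYMS = tuple(a for a, r in LANDMARK_REGISTRY.items() if r.kind == "indirect")

assert len(ALL_ACRONYMS) == 45 and len(DIRECT_ACRONYMS) == 36


# ---------------------------------------------------------------------------
# Direct transfer
# ---------------------------------------------------------------------------


def transfer_direct(
    template: TemplateDefinition,
    fitted_surface: TriangleMesh,
    target_surface: TriangleMesh | None = None,
    snap_cap_mm: float = SNAP_CAP_MM,
) -> tuple[LandmarkSet, dict[str, float]]:
    """Carry the template's direct landmarks onto a fitted surface.

    Each direct landmark is the fitted surface's vertex at the template's
    stored index. If the raw target surface is supplied, the landmark is
    snapped to its nearest surface point (residual correction after the
    nonrigid refinement) unless the snap distance exceeds ``snap_cap_mm``.
    Returns the partial landmark set and the per-landmark snap distances.
    """
    if len(fitted_surface.vertices) != len(template.mesh.vertices):
        raise IncompleteLandmarkError(
            "fitted surface is not in template correspondence (vertex count differs)"
        )
    out = LandmarkSet()
    names = list(template.direct_landmarks)
    idx = np.array([template.direct_landmarks[n] for n in names], dtype=np.int64)
    pts = fitted_surface.vertices[idx]
    snap_dist = {n: 0.0 for n in names}
    if target_surface is not None and len(names):
        closest, dist, _ = SurfaceIndex(
            target_surface.vertices, target_surface.faces
        ).query(pts)
        snapped = dist <= snap_cap_mm
        pts = np.where(snapped[:, None], closest, pts)
        snap_dist = {n: float(d) for n, d in zip(names, dist)}
    for n, p in zip(names, pts):
        out.set(n, p, Provenance.direct)
    return out, snap_dist


# ---------------------------------------------------------------------------
# Sphere fitting
# ---------------------------------------------------------------------------


def fit_sphere(points: np.ndarray):
    """Least-squares sphere through a point cloud.

    Algebraic (Kåsa) initialisation followed by Gauss–Newton on the
    geometric objective Σ(‖pᵢ−c‖−r)². Returns ``(centre, radius, rms)``.
    Raises :class:`DegenerateGeometryError` for <4 or coplanar points.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 points")
    c0 = p.mean(axis=0)
    q = p - c0
    if np.linalg.svd(q, compute_uv=False)[-1] < 1e-9 * max(
        np.linalg.svd(q, compute_uv=False)[0], 1e-300
    ):
        raise DegenerateGeometryError("sphere fit: points are (nearly) coplanar")

    # Kåsa: ||p||^2 = 2 p·c + (r^2 - ||c||^2), linear in (c, k)
    A = np.hstack([2.0 * p, np.ones((len(p), 1))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = sol[:3]
    r2 = sol[3] + centre @ centre
    radius = float(np.sqrt(max(r2, 1e-300)))

    def residual(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    res = least_squares(
        residual,
        np.append(centre, radius),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=200,
    )
    centre = res.x[:3]
    radius = float(res.x[3])
    rms = float(np.sqrt(np.mean(residual(res.x) ** 2)))
    return centre, radius, rms


# ---------------------------------------------------------------------------
# Indirect derivation
# ---------------------------------------------------------------------------

_CENTROID_RULES = {
    "FNC": ("femur", "femoral_neck"),
    "FA1": ("femur", "femoral_shaft_proximal"),
    "FA2": ("femur", "femoral_shaft_distal"),
    "TA1": ("tibia", "tibial_shaft_proximal"),
    "TA2": ("tibia", "tibial_shaft_distal"),
}
_MIDPOINT_RULES = {
    "TCP": ("TLCC", "TMCC"),
    "TCD": ("TMM", "TLM"),
    "TDC": ("TDL", "TDM"),
}


def derive_indirect(
    landmarks: LandmarkSet,
    fitted_surfaces: dict[BoneLabel, TriangleMesh],
    templates: dict[BoneLabel, TemplateDefinition],
) -> LandmarkSet:
    """Complete a landmark set with the 9 indirectly derived landmarks.

    ``fitted_surfaces``/``templates`` are keyed by bone; the femoral head
    sphere and all centroid rules evaluate region vertex sets on the fitted
    (corresponded) surfaces. Raises :class:`IncompleteLandmarkError` naming
    the first missing dependency.
    """

    def region_points(bone_name: str, region: str) -> np.ndarray:
        bone = BoneLabel(bone_name)
        if bone not in fitted_surfaces or bone not in templates:
            raise IncompleteLandmarkError(
                f"missing fitted {bone_name} surface for indirect landmarks"
            )
        tpl = templates[bone]
        if region not in tpl.regions:
            raise IncompleteLandmarkError(f"template lacks region {region}")
        return fitted_surfaces[bone].vertices[np.asarray(tpl.regions[region])]

    out = LandmarkSet(subject=landmarks.subject, side=landmarks.side)
    out.update(landmarks)

    if BoneLabel.femur in fitted_surfaces:
        centre, _, _ = fit_sphere(region_points("femur", "femoral_head"))
        out.set("FHC", centre, Provenance.indirect)
    for name, (bone, region) in _CENTROID_RULES.items():
        if BoneLabel(bone) in fitted_surfaces:
            out.set(name, region_points(bone, region).mean(axis=0), Provenance.indirect)
    for name, (a, b) in _MIDPOINT_RULES.items():
        if a in out and b in out:
            out.set(name, 0.5 * (out[a] + out[b]), Provenance.indirect)
    return out


def assert_complete(landmarks: LandmarkSet) -> None:
    """Raise naming the first missing acronym if the 45-landmark set is partial."""
    for acr in ALL_ACRONYMS:
        if acr not in landmarks:
            raise IncompleteLandmarkError(f"missing landmark {acr}")
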