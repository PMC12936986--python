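"""Cascaded surface fitting: rigid init → global SSM → local SSMs → nonrigid ICP.

The cascade registers a corresponded shape-model template to an arbitrary
target bone surface (e.g. a marching-cubes reconstruction of a voxel
segmentation). Stages:

1. ``rigid_initialize`` — centroid/principal-axes alignment with the four
   proper-rotation sign disambiguations scored by surface distance, then
   trimmed rigid ICP.
2. ``fit_ssm`` — alternating optimisation of the similarity pose (Kabsch)
   and the mode coefficients α (least squares on the orthonormal mode
   basis, clamped to ±3√λ per mode).
3. ``fit_local`` — the same fit restricted to a terminal bone region,
   re-attached to the global surface through a cosine blending ramp.
4. ``nonrigid_icp`` — locally affine, stiffness-regularised deformation
   (per-vertex 3×4 transforms, graph-Laplacian stiffness descending over a
   geometric schedule) that preserves vertex correspondence.

Each accepted stage cannot worsen the mean symmetric surface distance:
a refinement that fails to improve the fit is discarded and flagged, which
makes the reported stage metrics non-increasing by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, MeshValidationError
from .geometry import SurfaceIndex, apply_transform, kabsch, vertex_normals
from .meshdata import TriangleMesh
from .ssm import ShapeModel

DEFAULT_CLAMP = 3.0
DEFAULT_MAX_OUTER = 30
DEFAULT_STIFFNESS_LEVELS = 8
DEFAULT_STIFFNESS_RANGE = (100.0, 1.0)
NRICP_DIST_REJECT_MM = 10.0
NRICP_NORMAL_REJECT_DEG = 60.0
BLEND_WIDTH_FRACTION = 0.05


@dataclass
class Pose:
    """Similarity transform x -> s·R·x + t."""

    R: np.ndarray
    t: np.ndarray
    s: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(points, self.R, self.t, self.s)

    def pull_back(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.t) @ self.R / self.s

    def compose(self, other: "Pose") -> "Pose":
        """self ∘ other (apply ``other`` first)."""
        return Pose(self.R @ other.R, self.s * self.R @ other.t + self.t, self.s * other.s)

    @classmethod
    def identity(cls) -> "Pose":
        return cls(np.eye(3), np.zeros(3), 1.0)


@dataclass
class StageMetrics:
    stage: str
    mean_distance: float
    p95_distance: float
    accepted: bool = True

    def as_dict(self):
        return {
            "stage": self.stage,
            "mean_distance_mm": self.mean_distance,
            "p95_distance_mm": self.p95_distance,
            "accepted": self.accepted,
        }


@dataclass
class FitResult:
    """Output of one fitting stage (or the whole cascade)."""

    alpha: np.ndarray
    pose: Pose
    fitted_surface: TriangleMesh
    stage: str
    stage_metrics: list[StageMetrics] = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def symmetric_surface_distance(
    mesh_a: TriangleMesh,
    mesh_b: TriangleMesh,
    index_b: SurfaceIndex | None = None,
):
    """Mean and 95th percentile of the pooled two-way vertex-to-surface distances."""
    index_b = index_b or SurfaceIndex(mesh_b.vertices, mesh_b.faces)
    index_a = SurfaceIndex(mesh_a.vertices, mesh_a.faces)
    d_ab = index_b.distance(mesh_a.vertices)
    d_ba = index_a.distance(mesh_b.vertices)
    pooled = np.concatenate([d_ab, d_ba])
    return float(pooled.mean()), float(np.percentile(pooled, 95))


# ---------------------------------------------------------------------------
# Rigid initialization
# ---------------------------------------------------------------------------


def _principal_frame(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    R = Vt
    if np.linalg.det(R) < 0:
        R[2] *= -1.0
    return R  # rows are principal axes


def rigid_initialize(
    source_points: np.ndarray,
    target: TriangleMesh,
    max_icp_iter: int = 50,
    trim_fraction: float = 0.10,
    quality_threshold_mm: float | None = None,
):
    """Rigidly place a model's mean shape onto a target surface.

    Matches centroids and principal axes, scores the four proper-rotation
    axis-sign choices by mean surface distance, then refines with trimmed
    point-to-point rigid ICP. Returns ``(Pose, mean_distance, flagged)``
    where ``flagged`` signals a poor fit (e.g. an unmirrored contralateral
    bone) when the final mean distance exceeds the quality threshold.
    """
    src = np.asarray(source_points, dtype=float)
    if not np.isfinite(src).all() or not np.isfinite(target.vertices).all():
        raise MeshValidationError("non-finite coordinates")
    index = SurfaceIndex(target.vertices, target.faces)

    Rs = _principal_frame(src)
    Rt = _principal_frame(target.vertices)
    cs = src.mean(axis=0)
    ct = target.vertices.mean(axis=0)

    # four proper rotations: flip pairs of principal axes
    flips = [np.diag(d) for d in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]
    best = None
    sub = src[:: max(1, len(src) // 400)]
    for F in flips:
        R = Rt.T @ F @ Rs
        t = ct - R @ cs
        d = index.distance(apply_transform(sub, R, t)).mean()
        if best is None or d < best[0]:
            best = (d, R, t)
    _, R, t = best

    # trimmed rigid ICP refinement
    keep = max(4, int(round((1.0 - trim_fraction) * len(src))))
    prev = np.inf
    for _ in range(max_icp_iter):
        moved = apply_transform(src, R, t)
        closest, dist, _ = index.query(moved)
        order = np.argsort(dist)[:keep]
        R, t, _ = kabsch(src[order], closest[order])
        mean_d = float(dist.mean())
        if prev - mean_d < 1e-6:
            break
        prev = mean_d
    moved = apply_transform(src, R, t)
    mean_d = float(index.distance(moved).mean())
    if quality_threshold_mm is None:
        quality_threshold_mm = 3.0 * target.mean_edge_length()
    flagged = mean_d > quality_threshold_mm
    return Pose(R, t, 1.0), mean_d, flagged


# ---------------------------------------------------------------------------
# SSM fitting
# ---------------------------------------------------------------------------


def fit_ssm(
    model: ShapeModel,
    target: TriangleMesh,
    pose0: Pose,
    max_outer: int = DEFAULT_MAX_OUTER,
    clamp: float = DEFAULT_CLAMP,
    tol_mm: float = 1e-4,
    with_scaling: bool = False,
    target_index: SurfaceIndex | None = None,
    template_faces: np.ndarray | None = None,
) -> FitResult:
    """Alternating pose/coefficient optimisation of a shape model to a target.

    Per outer iteration: (a) nearest point on the target surface for every
    model vertex, (b) similarity-Kabsch pose update, (c) α by projection of
    the pulled-back correspondences onto the orthonormal mode basis,
    clamped to ±clamp·√λ. Stops when the mean surface distance improves by
    less than ``tol_mm``; five consecutive increases raise
    :class:`ConvergenceError`.
    """
    index = target_index or SurfaceIndex(target.vertices, target.faces)
    sqrt_lam = np.sqrt(np.maximum(model.eigenvalues, 0.0))
    alpha = np.zeros(model.t)
    pose = Pose(pose0.R.copy(), pose0.t.copy(), pose0.s)

    prev = np.inf
    rises = 0
    history = []
    for it in range(max_outer):
        pts_model = model.synthesize_points(alpha)
        moved = pose.apply(pts_model)
        closest, dist, _ = index.query(moved)
        mean_d = float(dist.mean())
        history.append(mean_d)
        if mean_d > prev + 1e-12:
            rises += 1
            if rises >= 5:
                raise ConvergenceError(
                    "SSM fit diverged: distance increased 5 consecutive iterations",
                    details={"history": history},
                )
        else:
            rises = 0
        if prev - mean_d < tol_mm and it > 0:
            prev = min(prev, mean_d)
            break
        prev = min(prev, mean_d)

        R, t, s = kabsch(pts_model, closest, scale=with_scaling)
        pose = Pose(R, t, s)
        pulled = pose.pull_back(closest)
        alpha = model.project(pulled)
        np.clip(alpha, -clamp * sqrt_lam, clamp * sqrt_lam, out=alpha)

    fitted_pts = pose.apply(model.synthesize_points(alpha))
    faces = template_faces if template_faces is not None else np.zeros((0, 3), np.int64)
    fitted = TriangleMesh(fitted_pts, faces)
    d = index.distance(fitted_pts)
    metrics = StageMetrics("global", float(d.mean()), float(np.percentile(d, 95)))
    return FitResult(alpha, pose, fitted, "global", [metrics])


def _axial_coordinate(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    return c @ Vt[0]


def fit_local(
    global_result: FitResult,
    local_model: ShapeModel,
    target: TriangleMesh,
    max_outer: int = DEFAULT_MAX_OUTER,
    clamp: float = DEFAULT_CLAMP,
    blend_width_fraction: float = BLEND_WIDTH_FRACTION,
    target_index: SurfaceIndex | None = None,
) -> FitResult:
    """Refine one terminal region with its local model and blend it back in.

    The local model is initialised on the globally fitted region, fitted to
    the full target surface, and re-attached with a cosine vertex-weight
    ramp (width = ``blend_width_fraction`` of the axial extent) so the
    refined region meets the global surface without a seam.
    """
    if local_model.region_indices is None:
        raise MeshValidationError("local model carries no region index set")
    region = np.asarray(local_model.region_indices, dtype=np.int64)
    surf = global_result.fitted_surface
    index = target_index or SurfaceIndex(target.vertices, target.faces)

    region_pts = surf.vertices[region]
    R0, t0, _ = kabsch(local_model.mean_points, region_pts)
    res = fit_ssm(
        local_model,
        target,
        Pose(R0, t0, 1.0),
        max_outer=max_outer,
        clamp=clamp,
        target_index=index,
    )
    refined = res.fitted_surface.vertices  # (|region|, 3) in world coords

    # cosine blending ramp against the axial coordinate of the full surface
    coord = _axial_coordinate(surf.vertices)
    rc = coord[region]
    extent = coord.max() - coord.min()
    width = max(blend_width_fraction * extent, 1e-9)
    if rc.mean() >= coord.mean():
        ramp = (rc - rc.min()) / width  # proximal region: inner boundary at min
    else:
        ramp = (rc.max() - rc) / width
    w = 0.5 - 0.5 * np.cos(np.pi * np.clip(ramp, 0.0, 1.0))

    new_vertices = surf.vertices.copy()
    new_vertices[region] = (1.0 - w[:, None]) * surf.vertices[region] + w[:, None] * refined
    fitted = TriangleMesh(new_vertices, surf.faces, surf.bone_label, surf.side)
    d = index.distance(new_vertices)
    metrics = StageMetrics("local", float(d.mean()), float(np.percentile(d, 95)))
    return FitResult(res.alpha, res.pose, fitted, "local", [metrics])


# ---------------------------------------------------------------------------
# Nonrigid ICP (locally affine, stiffness-regularised)
# ---------------------------------------------------------------------------


def default_stiffness_schedule(
    levels: int = DEFAULT_STIFFNESS_LEVELS,
    start: float = DEFAULT_STIFFNESS_RANGE[0],
    stop: float = DEFAULT_STIFFNESS_RANGE[1],
) -> np.ndarray:
    return np.geomspace(start, stop, levels)


def nonrigid_icp(
    source: TriangleMesh,
    target: TriangleMesh,
    stiffness_schedule=None,
    max_iter_per_level: int = 5,
    dist_reject_mm: float = NRICP_DIST_REJECT_MM,
    normal_reject_deg: float = NRICP_NORMAL_REJECT_DEG,
    gamma: float = 1.0,
    tol: float = 1e-4,
    target_index: SurfaceIndex | None = None,
) -> TriangleMesh:
    """Deform ``source`` onto ``target`` with per-vertex affine transforms.

    Minimises a data term (distance of each transformed vertex to its
    nearest compatible target point; correspondences are dropped when
    farther than ``dist_reject_mm`` or with normals differing by more than
    ``normal_reject_deg``) plus a stiffness term (Frobenius difference of
    neighbouring transforms) whose weight descends over the schedule.
    Vertex count and topology are preserved — no re-meshing.
    """
    if stiffness_schedule is None:
        stiffness_schedule = default_stiffness_schedule()
    stiffness_schedule = np.asarray(stiffness_schedule, dtype=float)
    if stiffness_schedule.size == 0:
        raise ValueError("stiffness schedule is empty")
    source.validate()
    target.validate()

    V = len(source.vertices)
    edges = source.edges()
    E = len(edges)
    index = target_index or SurfaceIndex(target.vertices, target.faces)
    tgt_face_normals = np.cross(
        target.vertices[target.faces[:, 1]] - target.vertices[target.faces[:, 0]],
        target.vertices[target.faces[:, 2]] - target.vertices[target.faces[:, 0]],
    )
    nrm = np.linalg.norm(tgt_face_normals, axis=1)
    tgt_face_normals /= np.where(nrm > 0, nrm, 1.0)[:, None]
    cos_cut = np.cos(np.deg2rad(normal_reject_deg))

    # stiffness matrix M ⊗ G : E*4 rows
    g = np.array([1.0, 1.0, 1.0, gamma])
    rows = np.repeat(np.arange(4 * E), 2)
    cols = np.empty(8 * E, dtype=np.int64)
    vals = np.empty(8 * E)
    for k in range(4):
        cols[2 * k::8] = 4 * edges[:, 0] + k
        cols[2 * k + 1::8] = 4 * edges[:, 1] + k
        vals[2 * k::8] = g[k]
        vals[2 * k + 1::8] = -g[k]
    MG = sp.csr_matrix((vals, (rows, cols)), shape=(4 * E, 4 * V))
    MGtMG = (MG.T @ MG).tocsr()

    # data matrix structure D: row i has [x y z 1] at columns 4i..4i+3
    di = np.repeat(np.arange(V), 4)
    dj = (4 * np.arange(V))[:, None] + np.arange(4)

    # X holds per-vertex 4x3 transforms, stacked (4V, 3); init identity
    X = np.tile(np.vstack([np.eye(3), np.zeros(3)]), (V, 1))

    def deform(X):
        src = source.vertices
        out = np.empty((V, 3))
        blocks = X.reshape(V, 4, 3)
        out = np.einsum("vi,vij->vj", np.hstack([src, np.ones((V, 1))]), blocks)
        return out

    for alpha_s in stiffness_schedule:
        converged = False
        for _ in range(max_iter_per_level):
            current = deform(X)
            closest, dist, tri = index.query(current)
            src_normals = vertex_normals(current, source.faces)
            compat = np.einsum("ij,ij->i", src_normals, tgt_face_normals[tri])
            w = ((dist <= dist_reject_mm) & (compat >= cos_cut)).astype(float)
            if w.sum() < 3:
                w = np.ones(V)  # pathological rejection; fall back to all
            dvals = (np.hstack([source.vertices, np.ones((V, 1))]) * w[:, None]).ravel()
            D = sp.csr_matrix((dvals, (di, dj.ravel())), shape=(V, 4 * V))
            U = closest * w[:, None]
            A = (alpha_s**2) * MGtMG + D.T @ D
            B = D.T @ U
            Xnew = spla.spsolve(A.tocsc(), sp.csc_matrix(B)).toarray()
            change = np.linalg.norm(Xnew - X) / np.sqrt(V)
            X = Xnew
            if change < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"nonrigid ICP level (stiffness {alpha_s:.3g}) not converged")
    return TriangleMesh(deform(X), source.faces.copy(), source.bone_label, source.side)


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------


def cascade_fit(
    global_model: ShapeModel,
    target: TriangleMesh,
    template_faces: np.ndarray,
    local_models: list[ShapeModel] | None = None,
    max_outer: int = DEFAULT_MAX_OUTER,
    clamp: float = DEFAULT_CLAMP,
    stiffness_schedule=None,
    max_iter_per_level: int = 5,
) -> FitResult:
    """Run the full cascade and report per-stage symmetric surface distances.

    A refinement stage whose mean symmetric distance would exceed the
    previous stage's is discarded (flagged ``accepted=False``), so the
    reported sequence is non-increasing.
    """
    local_models = local_models or []
    index = SurfaceIndex(target.vertices, target.faces)

    pose0, init_d, init_flag = rigid_initialize(global_model.mean_points, target)
    result = fit_ssm(
        global_model, target, pose0,
        max_outer=max_outer, clamp=clamp,
        target_index=index, template_faces=template_faces,
    )
    surf = TriangleMesh(result.fitted_surface.vertices, template_faces,
                        target.bone_label, target.side)
    mean_d, p95 = symmetric_surface_distance(surf, target, index)
    metrics = [StageMetrics("global", mean_d, p95)]
    flags = {"rigid_init_flagged": bool(init_flag), "rigid_init_mean_mm": init_d}

    best = mean_d
    for lm in local_models:
        cand = fit_local(
            FitResult(result.alpha, result.pose, surf, "global"),
            lm, target, max_outer=max_outer, clamp=clamp, target_index=index,
        )
        cm, cp = symmetric_surface_distance(cand.fitted_surface, target, index)
        if cm <= best + 1e-9:
            surf = cand.fitted_surface
            best, p95 = cm, cp
            metrics.append(StageMetrics("local", cm, cp))
        else:
            metrics.append(StageMetrics("local", best, p95, accepted=False))

    deformed = nonrigid_icp(
        surf, target,
        stiffness_schedule=stiffness_schedule,
        max_iter_per_level=max_iter_per_level,
        target_index=index,
    )
    dm, dp = symmetric_surface_distance(deformed, target, index)
    if dm <= best + 1e-9:
        surf = deformed
        best = dm
        metrics.append(StageMetrics("nricp", dm, dp))
    else:
        metrics.append(StageMetrics("nricp", best, p95, accepted=False))

    return FitResult(result.alpha, result.pose, surf, "nricp", metrics, flags)
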