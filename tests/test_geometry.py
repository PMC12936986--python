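"""Oracle tests for the exact surface-distance and voxelization primitives."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import ConvexHull

import limbmark as lm
from limbmark.geometry import (
    apply_transform,
    closest_point_on_triangles,
    vertex_normals,
    voxelize_parity,
)

from .conftest import random_rotation


def _brute_force_closest(points, vertices, faces):
    """Independent oracle: trimesh's per-triangle closest point, min over all."""
    tris = vertices[faces]
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros((len(points), 3))
    for tri in tris:
        cp = trimesh.triangles.closest_point(
            np.repeat(tri[None], len(points), axis=0), points
        )
        d = np.linalg.norm(cp - points, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_p[better] = cp[better]
    return best_p, best_d


def test_point_triangle_distance_matches_trimesh_oracle():
    rng = np.random.default_rng(3)
    tris = rng.standard_normal((40, 3, 3)) * 5
    pts = rng.standard_normal((40, 3)) * 5
    mine = closest_point_on_triangles(pts, tris)
    oracle = trimesh.triangles.closest_point(tris, pts)
    np.testing.assert_allclose(mine, oracle, atol=1e-9)


def test_surface_index_matches_brute_force():
    rng = np.random.default_rng(7)
    mesh = lm.make_template("talus").mesh
    pts = rng.uniform(-60, 60, (120, 3)) + mesh.vertices.mean(axis=0)
    idx = lm.SurfaceIndex(mesh.vertices, mesh.faces)
    cp, d, tri = idx.query(pts)
    bp, bd = _brute_force_closest(pts, mesh.vertices, mesh.faces)
    np.testing.assert_allclose(d, bd, atol=1e-9)
    np.testing.assert_allclose(np.linalg.norm(cp - pts, axis=1), bd, atol=1e-9)


def test_surface_index_zero_on_surface_points():
    mesh = lm.make_template("patella").mesh
    # barycentric interior points of a few faces lie exactly on the surface
    tri = mesh.vertices[mesh.faces[::7]]
    pts = tri.mean(axis=1)
    d = lm.SurfaceIndex(mesh.vertices, mesh.faces).distance(pts)
    np.testing.assert_allclose(d, 0.0, atol=1e-9)


def test_kabsch_recovers_exact_rigid_transform():
    rng = np.random.default_rng(11)
    src = rng.standard_normal((50, 3)) * 10
    for seed in range(5):
        r = np.random.default_rng(seed)
        R_true = random_rotation(r)
        t_true = r.uniform(-30, 30, 3)
        dst = src @ R_true.T + t_true
        R, t, s = lm.kabsch(src, dst)
        assert s == 1.0
        np.testing.assert_allclose(R, R_true, atol=1e-10)
        np.testing.assert_allclose(t, t_true, atol=1e-9)
        assert np.linalg.det(R) > 0


def test_kabsch_with_scale():
    rng = np.random.default_rng(13)
    src = rng.standard_normal((30, 3))
    R_true = random_rotation(rng)
    dst = 2.5 * src @ R_true.T + np.array([1.0, -2.0, 3.0])
    R, t, s = lm.kabsch(src, dst, scale=True)
    np.testing.assert_allclose(s, 2.5, atol=1e-10)
    np.testing.assert_allclose(apply_transform(src, R, t, s), dst, atol=1e-9)


def test_kabsch_reflection_guard():
    # a mirrored cloud must still produce a proper rotation (det +1)
    rng = np.random.default_rng(17)
    src = rng.standard_normal((40, 3))
    dst = src.copy()
    dst[:, 0] *= -1
    R, t, s = lm.kabsch(src, dst)
    assert np.linalg.det(R) > 0.999


def test_vertex_normals_unit_and_outward_on_sphere():
    from limbmark.synthetic import _ellipsoid

    v, f = _ellipsoid([2, 36, -8], [24, 11, 17], 12, 18)
    mesh = lm.TriangleMesh(v, f)
    n = vertex_normals(mesh.vertices, mesh.faces)
    np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)
    # outward: normal roughly along the radial direction of the ellipsoid
    centre = mesh.vertices.mean(axis=0)
    radial = mesh.vertices - centre
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert (np.einsum("ij,ij->i", n, radial) > 0.2).mean() > 0.95


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _axis_aligned_box(lo, hi):
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    box = trimesh.creation.box(extents=hi - lo)
    box.apply_translation((lo + hi) / 2)
    return np.asarray(box.vertices), np.asarray(box.faces)


def test_voxelize_parity_box_exact_count():
    v, f = _axis_aligned_box([0, 0, 0], [5, 4, 3])
    origin = np.array([-1.0, -1.0, -1.0])
    shape = (8, 7, 6)
    mask = voxelize_parity(v, f, origin, [1.0] * 3, shape)
    # voxel centres at origin + (i+0.5): inside ⇔ centre strictly within box
    assert mask.sum() == 5 * 4 * 3
    idx = np.argwhere(mask)
    assert idx.min() == 1


def test_voxelize_parity_matches_convex_inside_test():
    from limbmark.synthetic import _ellipsoid, _rot_x

    v, f = _ellipsoid([2, -16, -462], [15, 38, 18], 14, 20,
                      rotation=_rot_x(22.0))
    mesh = lm.TriangleMesh(v, f)
    lo = mesh.vertices.min(axis=0) - 2
    spacing = np.array([1.5, 2.0, 1.0])
    shape = np.ceil((mesh.vertices.max(axis=0) + 2 - lo) / spacing).astype(int)
    mask = voxelize_parity(mesh.vertices, mesh.faces, lo, spacing, shape)

    hull = ConvexHull(mesh.vertices)  # a triangulated ellipsoid is convex
    ii, jj, kk = np.indices(tuple(shape))
    centres = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5
    centres = centres * spacing + lo
    vals = centres @ hull.equations[:, :3].T + hull.equations[:, 3]
    signed = vals.max(axis=1).reshape(tuple(shape))
    decided = np.abs(signed) > 1e-6  # exclude centres on the boundary itself
    np.testing.assert_array_equal(mask[decided], (signed < 0)[decided])


def test_voxelize_translation_equivariance():
    tpl = lm.make_template("talus")
    vol = lm.voxelize(tpl.mesh, spacing=2.0)
    shifted = lm.TriangleMesh(tpl.mesh.vertices + np.array([4.0, -6.0, 8.0]),
                              tpl.mesh.faces)
    vol2 = lm.voxelize(shifted, spacing=2.0)
    np.testing.assert_array_equal(vol.data, vol2.data)
    np.testing.assert_allclose(
        vol2.affine[:3, 3] - vol.affine[:3, 3], [4.0, -6.0, 8.0], atol=1e-12
    )


def test_voxelize_rejects_open_surface():
    tri = lm.TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
    with pytest.raises(lm.MeshValidationError):
        lm.voxelize(tri, 1.0)


def test_voxelize_volume_close_to_mesh_volume():
    tpl = lm.make_template("patella")
    vol = lm.voxelize(tpl.mesh, spacing=1.0)
    voxvol = float((vol.data > 0).sum())
    meshvol = float(tpl.mesh.as_trimesh().volume)
    assert abs(voxvol - meshvol) / meshvol < 0.05
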