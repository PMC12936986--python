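"""Landmark registry, sphere fitting, transfer and indirect derivation."""

import numpy as np
import pytest

import limbmark as lm
from limbmark.landmarks import INDIRECT_ACRONYMS, fit_sphere

from .conftest import random_rotation


def test_registry_counts_and_partition():
    assert len(lm.ALL_ACRONYMS) == 45
    assert len(lm.DIRECT_ACRONYMS) == 36
    assert len(INDIRECT_ACRONYMS) == 9
    assert set(lm.DIRECT_ACRONYMS) | set(INDIRECT_ACRONYMS) == set(lm.ALL_ACRONYMS)


def test_templates_cover_all_direct_landmarks(templates):
    covered = set()
    for tpl in templates.values():
        covered |= set(tpl.direct_landmarks)
    assert covered == set(lm.DIRECT_ACRONYMS)


def test_fit_sphere_exact_noiseless():
    rng = np.random.default_rng(1)
    centre = np.array([12.0, -7.0, 30.0])
    r = 24.0
    for _ in range(5):
        dirs = rng.standard_normal((60, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = centre + r * dirs
        c, rad, rms = fit_sphere(pts)
        np.testing.assert_allclose(c, centre, atol=1e-8)
        assert rad == pytest.approx(r, abs=1e-8)
        assert rms < 1e-8


def test_fit_sphere_partial_cap():
    # only a spherical cap (like the femoral head region) still fits exactly
    rng = np.random.default_rng(2)
    centre = np.zeros(3)
    theta = rng.uniform(0, 0.9, 80)  # cap of ~52 degrees
    phi = rng.uniform(0, 2 * np.pi, 80)
    pts = centre + 10.0 * np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], axis=1)
    c, rad, rms = fit_sphere(pts)
    np.testing.assert_allclose(c, centre, atol=1e-6)
    assert rad == pytest.approx(10.0, abs=1e-6)


def test_fit_sphere_noise_robust():
    rng = np.random.default_rng(3)
    dirs = rng.standard_normal((200, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.array([1.0, 2.0, 3.0]) + 15.0 * dirs + rng.normal(0, 0.1, (200, 3))
    c, rad, rms = fit_sphere(pts)
    np.testing.assert_allclose(c, [1, 2, 3], atol=0.05)
    assert rad == pytest.approx(15.0, abs=0.05)


def test_fit_sphere_degenerate_inputs():
    with pytest.raises(lm.DegenerateGeometryError):
        fit_sphere(np.zeros((3, 3)))
    coplanar = np.random.default_rng(0).standard_normal((30, 3))
    coplanar[:, 2] = 0.0
    with pytest.raises(lm.DegenerateGeometryError):
        fit_sphere(coplanar)


def test_femoral_head_region_sphere_recovery(femur_template):
    from limbmark.synthetic import FEMORAL_HEAD_CENTRE, FEMORAL_HEAD_RADIUS

    pts = femur_template.mesh.vertices[femur_template.regions["femoral_head"]]
    c, rad, rms = fit_sphere(pts)
    np.testing.assert_allclose(c, FEMORAL_HEAD_CENTRE, atol=1e-6)
    assert rad == pytest.approx(FEMORAL_HEAD_RADIUS, abs=1e-6)


def test_transfer_direct_identity(femur_template):
    lms, snap = lm.transfer_direct(femur_template, femur_template.mesh,
                                   femur_template.mesh)
    for name, idx in femur_template.direct_landmarks.items():
        np.testing.assert_allclose(
            lms[name], femur_template.mesh.vertices[idx], atol=1e-9)
        assert snap[name] < 1e-9
        assert lms.provenance[name] == lm.Provenance.direct


def test_transfer_direct_snap_cap(femur_template):
    # fitted surface offset 5 mm from the target: beyond the 2 mm cap the
    # landmark stays at the fitted vertex rather than jumping to the surface
    off = lm.TriangleMesh(femur_template.mesh.vertices + np.array([5.0, 0, 0]),
                          femur_template.mesh.faces)
    lms, snap = lm.transfer_direct(femur_template, off, femur_template.mesh)
    name = next(iter(femur_template.direct_landmarks))
    idx = femur_template.direct_landmarks[name]
    if snap[name] > 2.0:
        np.testing.assert_allclose(lms[name], off.vertices[idx], atol=1e-9)


def test_transfer_direct_requires_correspondence(femur_template):
    short = lm.TriangleMesh(femur_template.mesh.vertices[:-2],
                            np.array([[0, 1, 2]]))
    with pytest.raises(lm.IncompleteLandmarkError):
        lm.transfer_direct(femur_template, short)


def test_derive_indirect_completes_set(templates):
    lms = lm.LandmarkSet(side=lm.Side.right)
    fitted = {}
    for bone, tpl in templates.items():
        part, _ = lm.transfer_direct(tpl, tpl.mesh)
        lms.update(part)
        fitted[bone] = tpl.mesh
    out = lm.derive_indirect(lms, fitted, templates)
    lm.assert_complete(out)
    # midpoints are exact midpoints
    np.testing.assert_allclose(out["TCD"], 0.5 * (out["TMM"] + out["TLM"]), atol=1e-12)
    np.testing.assert_allclose(out["TCP"], 0.5 * (out["TLCC"] + out["TMCC"]), atol=1e-12)
    np.testing.assert_allclose(out["TDC"], 0.5 * (out["TDL"] + out["TDM"]), atol=1e-12)
    for name in INDIRECT_ACRONYMS:
        assert out.provenance[name] == lm.Provenance.indirect


def test_derive_indirect_missing_bone(templates):
    tpl = templates[lm.BoneLabel.tibia]
    lms, _ = lm.transfer_direct(tpl, tpl.mesh)
    out = lm.derive_indirect(lms, {lm.BoneLabel.tibia: tpl.mesh},
                             {lm.BoneLabel.tibia: tpl})
    assert "TA1" in out and "TCD" in out
    assert "FHC" not in out  # femur absent: quietly incomplete
    with pytest.raises(lm.IncompleteLandmarkError):
        lm.assert_complete(out)


def test_indirect_rigid_equivariance(templates):
    """Sphere fit and centroids commute with rigid motion of the inputs."""
    rng = np.random.default_rng(8)
    R = random_rotation(rng)
    t = rng.uniform(-40, 40, 3)
    lms = lm.LandmarkSet(side=lm.Side.right)
    fitted = {}
    for bone, tpl in templates.items():
        part, _ = lm.transfer_direct(tpl, tpl.mesh)
        lms.update(part)
        fitted[bone] = tpl.mesh
    base = lm.derive_indirect(lms, fitted, templates)

    moved_fitted = {
        b: lm.TriangleMesh(m.vertices @ R.T + t, m.faces) for b, m in fitted.items()
    }
    moved = lm.derive_indirect(lms.transformed(R, t), moved_fitted, templates)
    for name in INDIRECT_ACRONYMS:
        np.testing.assert_allclose(moved[name], R @ base[name] + t, atol=1e-6)
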