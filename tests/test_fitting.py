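"""Fitting-stage tests: rigid initialisation, SSM parameter recovery,
nonrigid ICP behaviour and the acceptance-gated cascade."""

import numpy as np
import pytest

import limbmark as lm
from limbmark.fitting import Pose

from .conftest import random_rotation


def _rotation_angle_deg(R):
    c = (np.trace(R) - 1.0) / 2.0
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


@pytest.fixture(scope="module")
def femur_bundle(trained_models):
    return trained_models[lm.BoneLabel.femur]


def test_pose_algebra():
    rng = np.random.default_rng(0)
    R = random_rotation(rng)
    p = Pose(R, np.array([1.0, 2.0, 3.0]), 1.0)
    pts = rng.standard_normal((10, 3))
    np.testing.assert_allclose(p.pull_back(p.apply(pts)), pts, atol=1e-12)
    q = Pose(random_rotation(rng), rng.standard_normal(3), 1.0)
    np.testing.assert_allclose(
        p.compose(q).apply(pts), p.apply(q.apply(pts)), atol=1e-10)


def test_rigid_initialize_recovers_transform(femur_bundle):
    tpl = femur_bundle.template
    rng = np.random.default_rng(21)
    R_true = random_rotation(rng)
    t_true = rng.uniform(-100, 100, 3)
    target = lm.TriangleMesh(tpl.mesh.vertices @ R_true.T + t_true, tpl.mesh.faces)
    pose, mean_d, flagged = lm.rigid_initialize(tpl.mesh.vertices, target)
    assert not flagged
    assert mean_d < 0.05
    assert _rotation_angle_deg(pose.R @ R_true.T) < 0.5
    np.testing.assert_allclose(pose.t, t_true, atol=0.5)


def test_rigid_initialize_quality_flag(femur_bundle):
    tpl = femur_bundle.template
    mirrored = tpl.mesh.mirrored()
    # a mirrored (contralateral) bone cannot fit rigidly as well as the
    # identical bone; with a tight explicit threshold it is flagged
    _, d_same, fl_same = lm.rigid_initialize(
        tpl.mesh.vertices, tpl.mesh, quality_threshold_mm=1.0)
    _, d_mir, fl_mir = lm.rigid_initialize(
        tpl.mesh.vertices, mirrored, quality_threshold_mm=1.0)
    assert not fl_same and d_same < 0.1
    assert fl_mir and d_mir > 1.0


def test_fit_ssm_parameter_recovery_single(femur_bundle):
    model = femur_bundle.global_model
    tpl = femur_bundle.template
    rng = np.random.default_rng(5)
    alpha_true = rng.uniform(-2, 2, model.t) * np.sqrt(model.eigenvalues)
    R_true = random_rotation(rng)
    t_true = rng.uniform(-50, 50, 3)
    pts = model.synthesize_points(alpha_true) @ R_true.T + t_true
    target = lm.TriangleMesh(pts, tpl.mesh.faces)

    pose0, _, _ = lm.rigid_initialize(model.mean_points, target)
    res = lm.fit_ssm(model, target, pose0, template_faces=tpl.mesh.faces)
    err = np.linalg.norm(res.alpha - alpha_true)
    assert err < 0.05 * np.linalg.norm(alpha_true)
    assert _rotation_angle_deg(res.pose.R @ R_true.T) < 0.5
    assert np.linalg.norm(res.pose.t - t_true) < 0.5


def test_fit_ssm_clamps_alpha(femur_bundle):
    model = femur_bundle.global_model
    tpl = femur_bundle.template
    # exaggerated target: 6 sd along mode 1 -> alpha must stay within ±3 sd
    alpha_big = np.zeros(model.t)
    alpha_big[0] = 6.0 * np.sqrt(model.eigenvalues[0])
    target = lm.TriangleMesh(model.synthesize_points(alpha_big), tpl.mesh.faces)
    res = lm.fit_ssm(model, target, Pose.identity(), template_faces=tpl.mesh.faces)
    bound = 3.0 * np.sqrt(model.eigenvalues) + 1e-9
    assert (np.abs(res.alpha) <= bound).all()


def test_nonrigid_icp_improves_and_preserves_topology(femur_bundle, limb_spec):
    tpl = femur_bundle.template
    subj = lm.make_subject({lm.BoneLabel.femur: tpl}, seed=9, spec=limb_spec)
    target = subj.meshes[lm.BoneLabel.femur]
    before, _ = lm.symmetric_surface_distance(tpl.mesh, target)
    with pytest.warns(UserWarning):
        # coarse schedule on purpose; levels may report non-convergence
        deformed = lm.nonrigid_icp(tpl.mesh, target,
                                   stiffness_schedule=[50.0, 5.0, 1.0],
                                   max_iter_per_level=3)
    after, _ = lm.symmetric_surface_distance(deformed, target)
    assert after < before
    np.testing.assert_array_equal(deformed.faces, tpl.mesh.faces)
    assert len(deformed.vertices) == len(tpl.mesh.vertices)


def test_nonrigid_icp_rejects_empty_schedule(femur_bundle):
    tpl = femur_bundle.template
    with pytest.raises(ValueError):
        lm.nonrigid_icp(tpl.mesh, tpl.mesh, stiffness_schedule=[])


def test_stiffness_schedule_descending():
    s = lm.default_stiffness_schedule()
    assert len(s) == 8
    assert s[0] == pytest.approx(100.0) and s[-1] == pytest.approx(1.0)
    assert (np.diff(s) < 0).all()


def test_cascade_fit_monotone_and_accepted_stages(femur_bundle, limb_spec):
    subj = lm.make_subject({lm.BoneLabel.femur: femur_bundle.template},
                           seed=31, spec=limb_spec)
    target = subj.meshes[lm.BoneLabel.femur]
    with pytest.warns(UserWarning):
        res = lm.cascade_fit(femur_bundle.global_model, target,
                             femur_bundle.template.mesh.faces,
                             femur_bundle.local_models)
    means = [m.mean_distance for m in res.stage_metrics]
    stages = [m.stage for m in res.stage_metrics]
    assert stages[0] == "global" and stages[-1] == "nricp"
    assert all(b <= a + 1e-6 for a, b in zip(means, means[1:]))
    assert not res.flags["rigid_init_flagged"]
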