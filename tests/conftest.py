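"""Shared fixtures: templates and trained models are expensive, so they are
built once per session. All randomness is seeded."""

import numpy as np
import pytest

import limbmark as lm


@pytest.fixture(scope="session")
def templates():
    return lm.make_all_templates()


@pytest.fixture(scope="session")
def femur_template(templates):
    return templates[lm.BoneLabel.femur]


@pytest.fixture(scope="session")
def limb_spec(templates):
    return lm.default_deformation_spec([t.mesh for t in templates.values()])


@pytest.fixture(scope="session")
def trained_models(templates, limb_spec):
    models = {}
    for i, (bone, tpl) in enumerate(templates.items()):
        cohort, _ = lm.sample_cohort(tpl, 12, limb_spec, seed=100 + i)
        models[bone] = lm.train_bone_models(tpl, cohort)
    return models


@pytest.fixture(scope="session")
def truth_landmarks(templates):
    """Ground-truth landmark set of the undeformed template limb."""
    from limbmark.synthetic import _truth_landmarks, complete_truth_midpoints

    truth = lm.LandmarkSet(side=lm.Side.right)
    for tpl in templates.values():
        truth.update(_truth_landmarks(tpl, None, None))
    return complete_truth_midpoints(truth)


@pytest.fixture(scope="session")
def truth_frames(templates, truth_landmarks):
    mt = templates[lm.BoneLabel.metatarsal2]
    return {
        "knee": lm.build_knee_frame(truth_landmarks),
        "foot": lm.build_foot_frame(
            truth_landmarks,
            templates[lm.BoneLabel.calcaneus].mesh,
            templates[lm.BoneLabel.talus].mesh,
            mt.mesh,
            mt.regions["metatarsal_head"],
        ),
    }


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation from a QR decomposition."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
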