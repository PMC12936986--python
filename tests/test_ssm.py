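"""Shape-model oracles: GPA invariances, PCA vs covariance eigendecomposition,
truncation on constructed spectra, and model round trips."""

import numpy as np
import pytest

import limbmark as lm
from limbmark.errors import AlignmentError

from .conftest import random_rotation


def _toy_cohort(n=8, v=12, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((v, 3)) * 10
    shapes = base[None] + scale * rng.standard_normal((n, v, 3))
    return lm.CorrespondedCohort(shapes, [f"s{i}" for i in range(n)])


def _constructed_cohort(eigvals, n, v, seed=0):
    """Cohort whose sample covariance has exactly the given eigenvalues."""
    rng = np.random.default_rng(seed)
    k = len(eigvals)
    modes, _ = np.linalg.qr(rng.standard_normal((3 * v, k)))
    # centred orthonormal coefficient columns
    raw = rng.standard_normal((n, k))
    raw -= raw.mean(axis=0)
    coeff, _ = np.linalg.qr(raw)
    coeff -= coeff.mean(axis=0)
    coeff, _ = np.linalg.qr(coeff)
    c = coeff * np.sqrt(np.asarray(eigvals) * (n - 1))
    mean = rng.standard_normal(3 * v)
    flat = mean[None] + c @ modes.T
    return lm.CorrespondedCohort(flat.reshape(n, v, 3), [str(i) for i in range(n)]), modes


def test_gpa_removes_random_rigid_transforms():
    cohort = _toy_cohort(scale=0.0)  # identical shapes
    rng = np.random.default_rng(5)
    shapes = np.stack([
        s @ random_rotation(rng).T + rng.uniform(-50, 50, 3) for s in cohort.shapes
    ])
    aligned, consensus = lm.generalized_procrustes(
        lm.CorrespondedCohort(shapes, list(cohort.provenance)))
    spread = aligned.shapes - consensus[None]
    assert np.abs(spread).max() < 1e-6


def test_gpa_consensus_centred():
    aligned, consensus = lm.generalized_procrustes(_toy_cohort())
    np.testing.assert_allclose(consensus.mean(axis=0), 0.0, atol=1e-9)


def test_gpa_rejects_degenerate():
    shapes = np.zeros((3, 5, 3))
    with pytest.raises(AlignmentError):
        lm.generalized_procrustes(lm.CorrespondedCohort(shapes, ["a", "b", "c"]))


def test_build_ssm_matches_covariance_eigendecomposition_oracle():
    # Acceptance-style oracle: eigenpairs of the explicit 3V x 3V covariance
    cohort = _toy_cohort(n=10, v=15, seed=2)
    model = lm.build_ssm(cohort, variance_threshold=1.0)
    flat = cohort.shapes.reshape(cohort.n, -1)
    cov = np.cov(flat, rowvar=False, ddof=1)
    w, vecs = np.linalg.eigh(cov)
    w = w[::-1]
    vecs = vecs[:, ::-1]
    k = model.t
    np.testing.assert_allclose(model.eigenvalues, w[:k], atol=1e-8)
    # eigenvectors up to sign
    for j in range(k):
        dot = abs(model.modes[:, j] @ vecs[:, j])
        assert dot == pytest.approx(1.0, abs=1e-8)
    # total variance conserved
    np.testing.assert_allclose(model.spectrum.sum(), np.trace(cov), atol=1e-8)


def test_build_ssm_modes_orthonormal_and_sign_convention():
    model = lm.build_ssm(_toy_cohort(n=9, v=20, seed=3))
    G = model.modes.T @ model.modes
    np.testing.assert_allclose(G, np.eye(model.t), atol=1e-10)
    arg = np.abs(model.modes).argmax(axis=0)
    assert (model.modes[arg, np.arange(model.t)] > 0).all()


def test_truncation_on_constructed_spectrum():
    # eigenvalues 8, 1.5, 0.5 -> cumulative fractions 0.80, 0.95, 1.00
    cohort, _ = _constructed_cohort([8.0, 1.5, 0.5], n=12, v=10, seed=4)
    assert lm.build_ssm(cohort, 0.98).t == 3
    assert lm.build_ssm(cohort, 0.95).t == 2  # exactly at the boundary
    assert lm.build_ssm(cohort, 0.90).t == 2
    assert lm.build_ssm(cohort, 0.80).t == 1
    assert lm.build_ssm(cohort, 0.50).t == 1
    m = lm.build_ssm(cohort, 1.0)
    assert m.t == 3
    np.testing.assert_allclose(sorted(m.eigenvalues, reverse=True),
                               [8.0, 1.5, 0.5], atol=1e-8)


def test_synthesize_project_roundtrip():
    cohort = _toy_cohort(n=8, v=10, seed=6)
    model = lm.build_ssm(cohort, 1.0)
    rng = np.random.default_rng(0)
    alpha = rng.standard_normal(model.t) * np.sqrt(model.eigenvalues)
    shape = model.synthesize(alpha)
    np.testing.assert_allclose(model.project(shape), alpha, atol=1e-9)
    pts = model.synthesize_points(alpha)
    assert pts.shape == (10, 3)
    np.testing.assert_allclose(pts.ravel(), shape, atol=0)


def test_model_save_load_roundtrip(tmp_path):
    cohort = _toy_cohort(n=6, v=8, seed=7)
    model = lm.build_ssm(cohort)
    p = tmp_path / "model.ssm"
    model.save(p)
    back = lm.ShapeModel.load(p)
    np.testing.assert_array_equal(back.mean, model.mean)
    np.testing.assert_array_equal(back.modes, model.modes)
    np.testing.assert_array_equal(back.eigenvalues, model.eigenvalues)
    assert back.variance_fraction == model.variance_fraction
    assert back.region_scope == model.region_scope


def test_local_region_extraction(femur_template):
    prox = lm.extract_local_region(femur_template, 0.2, "proximal")
    dist = lm.extract_local_region(femur_template, 0.2, "distal")
    assert len(prox) > 0 and len(dist) > 0
    assert not set(prox) & set(dist)
    v = femur_template.mesh.vertices
    # the femoral head (proximal by construction) must be in the proximal slab
    head = femur_template.regions["femoral_head"]
    assert np.isin(head, prox).mean() > 0.9
    assert v[prox][:, 2].mean() > v[dist][:, 2].mean()


def test_build_local_ssm_remembers_region(femur_template, trained_models):
    bundle = trained_models[lm.BoneLabel.femur]
    assert len(bundle.local_models) == 2
    for lmod in bundle.local_models:
        assert lmod.region_indices is not None
        assert lmod.vertex_count == len(lmod.region_indices)


def test_cohort_validation():
    with pytest.raises(Exception):
        lm.CorrespondedCohort(np.zeros((1, 5, 3)), ["only-one"])
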