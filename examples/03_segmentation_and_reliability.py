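"""Evaluate segmentation overlap metrics and measurement reliability.

Part 1 rasterizes a fitted surface and its target into label volumes and
computes DSC, HD and HD95 — the metrics used to audit upstream segmentations.
Part 2 builds a subjects x raters table of a measurement and computes the
absolute-agreement single-rater ICC with its Koo category, plus the MAE of
the automated values against the rater mean.
"""

import warnings

import numpy as np

import limbmark as lm
from limbmark.reliability import RatingTable
from limbmark.synthetic import default_deformation_spec, sample_cohort

warnings.filterwarnings("ignore", category=UserWarning)

# -- Part 1: segmentation metrics --------------------------------------------
template = lm.make_template("talus")
spec = default_deformation_spec(template.mesh)
cohort, _ = sample_cohort(template, 10, spec, seed=3)
models = lm.train_bone_models(template, cohort)

subject = lm.make_subject({lm.BoneLabel.talus: template}, seed=41, spec=spec)
target = subject.meshes[lm.BoneLabel.talus]
fit = lm.cascade_fit(models.global_model, target, template.mesh.faces)
fitted = lm.TriangleMesh(fit.fitted_surface.vertices, template.mesh.faces)

vol_auto = lm.voxelize(fitted, spacing=1.5)
vol_ref = lm.voxelize(target, spacing=1.5)
n = np.minimum(vol_auto.data.shape, vol_ref.data.shape)
a = lm.LabelVolume(vol_auto.data[: n[0], : n[1], : n[2]], vol_auto.affine)
b = lm.LabelVolume(vol_ref.data[: n[0], : n[1], : n[2]], vol_ref.affine)
print(f"DSC  : {lm.dice(a.data > 0, b.data > 0):.4f}")
print(f"HD   : {lm.hausdorff(a, b, 100):.3f} mm")
print(f"HD95 : {lm.hausdorff(a, b, 95):.3f} mm")

# -- Part 2: reliability ------------------------------------------------------
# simulate 15 subjects measured by 3 raters with small rater effects
rng = np.random.default_rng(12)
true_hka = 179.0 + rng.normal(0, 2.5, (15, 1))
raters = true_hka + rng.normal(0, 0.2, (1, 3)) + rng.normal(0, 0.4, (15, 3))
table = RatingTable(raters, measurement="HKA", units="deg")

value, category = lm.icc(table)
print(f"\nICC(2,1): {value:.3f} ({category})")

automated = true_hka.ravel() + rng.normal(0, 0.3, 15)
mean_err, sd_err = lm.mae(automated, raters.mean(axis=1))
print(f"MAE vs rater mean: {mean_err:.3f} ± {sd_err:.3f} deg")
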