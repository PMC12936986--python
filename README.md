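# limbmark

Automated three-dimensional lower-limb alignment measurements from bone
surface models, built around statistical shape model (SSM) fitting.

Given per-bone surface meshes of a lower limb (femur, tibia, patella, talus,
calcaneus, second metatarsal — e.g. extracted from weight-bearing CT
segmentations), `limbmark`:

1. fits a corresponded template to each bone with a cascade of
   rigid initialisation → global SSM fit → local (proximal/distal) SSM
   refinement → stiffness-scheduled nonrigid ICP;
2. transfers 36 directly annotated landmarks through the correspondence and
   derives 9 more (sphere fits, region centroids, midpoints) for a total of
   45 anatomical landmarks;
3. constructs the knee and foot–ankle anatomical coordinate frames;
4. evaluates 28 alignment measurements (HKA, JLCA, TT–TG, torsion and slope
   angles, patellofemoral indices, …) with explicit plane and angle
   conventions.

It also ships the supporting toolkit: segmentation overlap metrics
(DSC, Hausdorff distance, HD95), reliability statistics (absolute-agreement
single-rater ICC with Koo categories, MAE), a watertight mesh voxelizer, and
a fully deterministic synthetic lower-limb generator used for testing and
demonstration.

## Quick start (API)

```python
import limbmark as lm
from limbmark.synthetic import default_deformation_spec, sample_cohort

templates = lm.make_all_templates()
spec = default_deformation_spec([t.mesh for t in templates.values()])

models = {}
for i, (bone, tpl) in enumerate(templates.items()):
    cohort, _ = sample_cohort(tpl, 12, spec, seed=100 + i)
    models[bone] = lm.train_bone_models(tpl, cohort)

subject = lm.make_subject(templates, seed=1, spec=spec)
result = lm.process_subject(subject.meshes, models, subject="demo")
print(result.report.values["HKA"], result.report.values["TT-TG"])
```

See `examples/` for narrative walkthroughs of model building, full-limb
measurement, and segmentation/reliability evaluation.

## Quick start (CLI)

```bash
limbmark synth --out-dir demo --seed 1 --voxel 2.0   # synthetic subject
limbmark run --mesh femur=demo/femur.ply --mesh tibia=demo/tibia.ply \
             --mesh patella=demo/patella.ply --mesh talus=demo/talus.ply \
             --mesh calcaneus=demo/calcaneus.ply \
             --mesh metatarsal2=demo/metatarsal2.ply \
             --out-dir results                        # full pipeline
limbmark evaluate-seg --auto demo/femur.nii.gz --reference demo/femur.nii.gz
limbmark reliability --table ratings.csv
```

Subcommands: `build-ssm`, `fit`, `landmarks`, `measure`, `evaluate-seg`,
`reliability`, `synth`, `run`. All commands are thin wrappers over the
library; every run is deterministic given its inputs and seeds.

## Layout

- `src/limbmark/` — the library (`ssm`, `fitting`, `landmarks`, `frames`,
  `measurements`, `segmetrics`, `reliability`, `synthetic`, `pipeline`, `cli`)
- `docs/methods.md` — the mathematical conventions and algorithms
- `examples/` — runnable narrative scripts
- `scripts/acceptance.py` — end-to-end quantitative report
  (`python scripts/acceptance.py --seed 1 --out report.json`)
- `tests/` — pytest suite, including oracle-based acceptance tests

## Testing

```bash
pytest -q
```

The suite checks the numerics against independent oracles: explicit
covariance eigendecompositions for the SSM, brute-force surface and voxel
distances, closed-form constructed angles, ANOVA sum-of-squares ICC, and
byte-identical reruns for determinism.
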