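# Methods

This document records the mathematical conventions and algorithms the
library implements. Every default named here is a deliberate design
decision; the test suite pins the behaviour with independent oracles.

## 1. Statistical shape model (SSM)

A shape is a triangle mesh with V corresponded vertices, flattened to a
3V-vector. Given N aligned training shapes, the model is the linear
point-distribution model

    S = S̄ + P α

where S̄ is the mean shape, the columns of P are the leading eigenvectors
("modes") of the shape covariance C = 1/(N−1) Σ (Sᵢ−S̄)(Sᵢ−S̄)ᵀ, and α
weights the modes. Eigenpairs are computed from the SVD of the centred
N×3V data matrix (never the 3V×3V covariance): with singular values sᵢ,
the eigenvalues are λᵢ = sᵢ²/(N−1). Modes are truncated at the smallest t
whose cumulative variance fraction reaches the threshold (default 0.98);
the boundary is decided with `searchsorted(cumfrac, threshold − 1e-12) + 1`
so exact-boundary spectra are handled deterministically. Mode signs follow
a fixed convention (the largest-magnitude component of each mode is made
positive) so models are reproducible.

### Generalised Procrustes Analysis (GPA)

Training shapes are aligned by iterated removal of translation and rotation
(scale optional) to a running consensus; rotations use the Kabsch solution
with a determinant correction that forbids reflections. Iteration stops
when the consensus change falls below 1e-9 (at most 100 iterations).

## 2. Cascade fitting

A trained template is fitted to a patient surface in four stages. A
refinement stage is accepted only if it does not increase the mean
symmetric surface distance, so the reported per-stage sequence is
non-increasing by construction.

1. **Rigid initialisation** — principal-axes alignment over the four proper
   rotations that align the axes, refined by trimmed ICP (10% trim). The
   fit is flagged as low-quality when the mean distance exceeds 3× the
   target's mean edge length.
2. **Global SSM fit** — alternate between the optimal rigid pose (Kabsch on
   current correspondences) and the least-squares mode weights, clamping
   each αᵢ to ±3√λᵢ. Five consecutive increases of the objective raise a
   convergence error.
3. **Local refinement** — for long bones, separate local models of the
   proximal and distal 20% axial slabs are fitted and blended into the
   global result with a cosine ramp (blend width 5% of the axial extent).
4. **Nonrigid ICP** — locally affine per-vertex deformation (a 4×3 affine
   per vertex) regularised by graph-Laplacian stiffness (M ⊗ G with γ = 1),
   with the stiffness decreasing geometrically from 100 to 1 over 8 levels.
   Correspondences further than 10 mm or with normals disagreeing by more
   than 60° are rejected. Topology (faces, vertex count) is preserved.

Surface distance is the exact point-to-triangle distance (KD-tree pruned),
symmetrised by averaging both directions over sampled surface points.

## 3. Landmarks

45 landmarks are defined: 36 **direct** landmarks are vertex indices
annotated once on each bone template; after fitting they ride the
correspondence and are snapped to the nearest point of the raw patient
surface when that point is within 2 mm. 9 **indirect** landmarks are
derived geometrically:

- femoral head centre (FHC): least-squares sphere fit (algebraic Kåsa
  initialisation, Gauss–Newton refinement) to the femoral-head region;
- region centroids (FNC, FA1, FA2, TA1, TA2);
- midpoints (TCP, TCD, TDC) of named landmark pairs.

## 4. Anatomical frames

**Knee frame**: origin at the centre of the knee (COK); z is the unit
mechanical axis COK → FHC; x is the posterior condylar line FLCP−FMCP
(negated for left limbs) orthogonalised against z (Gram–Schmidt);
y = z × x. The coronal plane is spanned by (x, z), the sagittal by (y, z),
the axial by (x, y).

**Foot–ankle frame**: z is the vertical (scanner gravity) direction; y is
the ground-plane projection of the line from the plantar calcaneal point to
the second-metatarsal head centre (sphere fit); x completes the
right-handed triad; origin at the talus centroid.

Left limbs are mirrored into the right-handed convention before fitting and
mirrored back on output, so one template set serves both sides.

## 5. Measurements

28 measurements are defined declaratively (landmark pairs, projection
plane, angle convention). All angles use `atan2` of projected 2-D vectors
(never `arccos`), under one of four conventions:

- **directed** [0°, 180°] — e.g. HKA;
- **acute** [0°, 90°];
- **complement** (90° − acute) — slope angles measured from the plane
  normal to the mechanical axis (MTS, LTS);
- **signed** (−180°, 180°] — rotational alignment with lateral/medial sign.

TT–TG is the absolute x-component (mediolateral axis of the knee frame) of
the vector from the trochlear groove centre to the tibial tuberosity,
evaluated in the axial plane; the signed variant retains direction.
Measurements whose landmarks or frames are unavailable return NaN with a
flag; a missing bone never aborts a subject.

## 6. Segmentation metrics

Masks are compared on identical grids (shape, spacing, origin enforced).

- **DSC** = 2|A∩B| / (|A|+|B|); both-empty is defined as 1.0.
- **HD / HD95** are computed between the world-coordinate centres of
  boundary voxels (6-connectivity), max-symmetrised; HD95 uses the
  nearest-rank 95th percentile of each directed distance set before
  symmetrisation. Comparing an empty mask is undefined and raises.

## 7. Reliability statistics

The ICC is the absolute-agreement single-rater form from two-way ANOVA mean
squares

    ICC = (MSₛ − MSₑ) / (MSₛ + (k−1)·MSₑ + (k/n)(MSᵣ − MSₑ)),

the shared point estimate of the two-way random-effects model (ICC(2,1))
and the two-way mixed-effects absolute-agreement model. Perfect agreement
(identical rater columns) returns exactly 1.0. Categories follow the
Koo & Li cut points: < 0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90] good,
> 0.90 excellent. MAE reports the mean and sample SD (n−1) of absolute
errors against the rater mean.

## 8. Synthetic data

The generator builds stylized parametric bone templates (ellipsoid, tube
and thickened-patch primitives, all watertight) with annotated landmark
vertices and regions. Subjects are created by a shared smooth low-order
polynomial deformation field (axial scale 2.5%/SD, transverse scale
3.5%/SD, quadratic coronal bow 3 mm/SD), capped at 40 mm peak displacement
(draws beyond the cap are resampled), plus 0.1 mm Gaussian vertex noise
applied to surfaces only — ground-truth landmarks are transported exactly
by the smooth field, never by the noise. Every bone carries at least one
asymmetric feature so the rigid pose, and hence landmark identifiability,
is well defined. Generation is fully deterministic per seed.

Voxelization uses a z-column scanline parity test with jittered ray
origins, per watertight component, on a grid whose origin is snapped to
the spacing lattice; the affine maps voxel indices to world-mm voxel
centres at origin + (i + ½)·spacing, so translated meshes rasterize to
identical masks.
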