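# Methods

This note documents the models, parameters and numerical choices behind
`nodulecad`, what the synthetic phantoms do and do not emulate, and the
design decisions taken where the pipeline design was genuinely open.

## Pipeline model

The detection chain assumes a chest CT volume in Hounsfield units with
physical spacing carried (never resampled away), indexed `(slice, row, col)`
with millimetre coordinates everywhere a physical quantity appears.

**Lung segmentation.** The user marks one voxel inside each lung. After
curvature-flow denoising (10 iterations, time step 0.0625 — edge-preserving,
so the HU window boundaries move little), region growing collects the
6-connected component of `{−1000 ≤ HU ≤ −200}` around each seed. This
window spans lung air, parenchyma and the partial-volume shell but excludes
solid tissue, so solid nodules and vessels appear as holes and indentations;
a 3D morphological closing with a ball of 12 voxels pulls them back into the
mask. The mask volume is then gated against a reference lung volume
(default 3 545 668 voxels, a population average for adult thorax CT; for
phantoms the analytic cavity volume): a relative deviation above 0.60 —
applied two-sided, since a leaked mask is as wrong as a truncated one —
triggers a retry. Because re-growing identical inputs would be a no-op, each
retry widens the upper HU bound by +50 HU; after 3 attempts the caller is
asked for new seeds. The interactive "operator accepts the mask" step is
modelled as a status value, keeping the library non-interactive.

**Structure separation.** A gradient-magnitude map is built from per-axis
Gaussian derivative filters (σ = 1 mm) divided by the voxel spacing, so
anisotropic volumes get consistent HU/mm units. The watershed transform
floods this map inside the lung mask. Two knobs are fractions of the
in-mask magnitude range: `threshold` (default 0.01) floors near-flat noise,
and `level` (default 0.06) extracts markers by h-minima so basins shallower
than `level` merge into their neighbours. Both defaults were calibrated once
on the phantom suite: at level 0.06 every nodule — including small
juxtavascular nodules tangent to a vessel of nearly equal attenuation —
receives its own basin, at the cost of more noise fragments for the later
stages to absorb. Basin fragments inside the mask are split into 6-connected
components; components with equivalent diameter outside [3, 30] mm are
dropped (the system does not target sub-3 mm nodules), which also removes
the large air-background basins.

**Rule screening.** Comparisons are strict and applied in order
roundness → elongation → energy, with per-rule enable flags and directions:

| rule | definition | default | direction |
|---|---|---|---|
| roundness | area of equal-volume sphere / mesh surface area | 0.35 | discard if below |
| elongation | λ_max/λ_min of the second central moment matrix (mm) | 4.0 | discard if above |
| energy | √(Σ_slices Σ_ij P²_ij), 64-level GLCM, 1-px horizontal offset | 0.02 | discard if below |

Threshold magnitudes of 8.3×10⁴, 6.8×10⁴ and 3.3 are sometimes quoted for
these rules in the CAD literature; the first two are unreachable on the
dimensionless scales defined above (roundness ≤ ~1, and an elongation rule
reading "discard when *below* 6.8×10⁴" would discard everything), and 3.3
exceeds the energy's own bound √ns for objects spanning fewer than 11
slices. The defaults above therefore operate on the natural scales and were
calibrated once on the phantom suite; any combination, including the
literal one, is configurable.

**False-positive elimination.** Each kept candidate yields per-slice HOG
descriptors (9 orientations, 8×8-px cells, 2×2-cell blocks, L2-Hys) on its
bounding-box patch (+2 voxels margin, windowed to [−1000, 400] HU, min-max
scaled per slice patch; patches smaller than 16 px are bilinearly upscaled so
one block fits). Candidates span different numbers of slices, so the
concatenated descriptor has variable length; PCA cannot consume that, so
the concatenation is resampled by linear interpolation to a fixed 4096
values — an explicit, documented bridge. PCA keeps the smallest component
count whose cumulative explained variance reaches 0.80 (computed from the
full spectrum and truncated with a 10⁻¹² slack so exact-equality cases take
the smaller count). The binary SVM is RBF with C = 5 and γ = 1/n, n the
reduced dimension; its signed decision value is kept for ROC analysis.

**Malignancy scoring.** The seven descriptor vocabularies are graded
(e.g. marked/intermediate/none), so they are encoded ordinally — the printed
order of each vocabulary gives codes 0..k−1, scaled to [0, 1]; the encoding
is bijective over all 5832 combinations. The classifier is a one-vs-one RBF
SVM (C = 5, γ = 1/7; 10 pairwise machines for 5 degrees) returning the
degree plus five one-vs-rest score columns. Patient age and smoking history
are cohort framing, not model inputs.

**Evaluation.** The hit criterion is centroid-within-ground-truth-radius
with greedy one-to-one matching by distance (an overlap-fraction alternative
is configurable); extra detections on an already-matched nodule are false
positives. Sensitivity is the exact ratio TP/(TP+FN); A_z is the
trapezoidal area under the threshold-swept ROC curve, which equals the
Mann–Whitney statistic (verified against a pair-counting oracle to 10⁻¹²).
Cross-validation splits at the case level (default k = 10); the fixed
train/validation holdout sometimes called "leave-one-out" in the CAD
literature is implemented — and named — as a holdout, with the historical
name kept as an alias.

## The phantom: what it emulates, and what it does not

A phantom is a soft-tissue block (40 HU) with two ellipsoidal air cavities
(−880 HU; right larger than left, roughly 64/36 % of the total volume as in
real anatomy), two straight vessel tubes per lung (30 HU, radius
1.2–2.2 mm) running from the hilum outward, spherical nodules, and additive
Gaussian noise (σ = 20 HU, a plausible soft-reconstruction noise level;
configurable). Default grid: 40 slices of 1.5 mm, 0.7 mm in-plane pixels —
slice thickness and pixel size in the common clinical range, small enough
in-plane to resolve pleural contact geometry.

Nodule types: *isolated* (solid, 20 HU, clear of wall and vessels),
*juxtavascular* (solid, placed exactly tangent to a vessel tube),
*ground-glass* (−430 HU, midway between air and solid, per-pixel attenuation
well below solid), *juxtapleural* (solid, protruding 0.3 mm past the cavity
surface). A juxtapleural nodule deforms the pleura in reality — lung air
wraps its flanks down to a narrow attachment base — so the generator carves
a 1.6 mm air collar around each juxtapleural sphere except a base cap
(radius max(1 mm, r/4)) facing the wall. Without the collar the rigid
ellipsoid wall leaves a sub-voxel air gap ring around the contact that no
ball closing can recover at clinical voxel sizes; with it, mask recovery of
juxtapleural nodules is essentially complete, matching the closing's
purpose. Contact is placed on the lateral pleura (an in-plane direction)
where the finer pixel size resolves it.

Per-case sampling: 1–8 nodules (uniform), type mix 30/25/25/20 % for
isolated/juxtapleural/juxtavascular/ground-glass, diameters uniform within
per-type ranges (isolated 4–14 mm, juxtapleural 9–15 mm, juxtavascular
4–10 mm, ground-glass 5–14 mm) chosen so each type satisfies its placement
constraint inside the cavities; juxtapleural nodules start at 9 mm because a
smaller sphere is mostly attachment base, a geometry the closing step cannot
meaningfully recover at these voxel sizes. Ground truth records, for each
nodule, exactly the voxels whose centers fall inside its analytic sphere.
A malignancy degree is assigned from a fixed (type, diameter) table —
ground-glass and vascular attachment raise suspicion, small sharp solid
nodules lower it — and a companion generator maps degrees to the seven
descriptor vocabularies via per-degree prototypes with per-field ordinal
noise (flip probability 0.08), giving the CADx stage learnable structure
that stands in for radiologist consensus labels.

What the phantom does **not** emulate: airway trees, lobar fissures,
partial-volume and reconstruction-kernel effects, breathing or cardiac
motion, pathologies that alter lung opacity, non-spherical or spiculated
nodule shapes, and correlated CT noise textures. Passing the phantom suite
therefore demonstrates the *mechanics* of every stage (segmentation
recovery, basin separation, descriptor discrimination, classifier wiring,
reproducibility) — not clinical performance on patient data.

## Numerical choices

- **Closing** is computed with two exact Euclidean distance transforms
  (dilate = distance-to-mask ≤ r, erode = distance-to-background > r), which
  is identical to ball dilation-then-erosion (verified voxel-exact against a
  brute-force oracle) but linear-time; the input is padded by r+1 voxels so
  the image border cannot truncate the ball. The radius is in index space
  ("12 units" read as voxels), so anisotropic spacing elongates the physical
  ball along the slice axis.
- **Roundness meshes** a Gaussian-smoothed (σ = 1 voxel) copy of the
  candidate mask at level 0.5, because the raw binary staircase
  overestimates surface area by ~8 %; tiny candidates that smoothing would
  erase fall back to the binary mesh. The equal-volume sphere uses the
  mesh-enclosed volume (divergence theorem) so numerator and denominator
  describe the same surface; a digitized sphere then scores 0.95–1.0 at any
  radius. Degenerate unmeshable sets score 0 with a warning.
- **GLCM** quantizes to 64 levels over the candidate's own HU range (a
  grid over the full 16-bit range would be a 65536² matrix and would put
  all mass in a few cells); slices with fewer than two candidate pixels
  contribute zero with a warning. Uniform candidates hit the closed form
  √ns exactly.
- **Elongation** of a single voxel is defined as 1; collinear sets return
  +inf (which the discard-if-above rule handles naturally).
- **Watershed determinism**: markers come from h-minima labelling, and all
  flooding runs on the same normalized map, so identical inputs give
  identical label maps.
- **Seeds for phantoms** are auto-suggested as the free-air voxel nearest
  each cavity center (a nodule may occupy the exact center).
- **Reproducibility**: every stochastic step (phantom sampling, noise,
  splits, SVM seeding) derives from an explicit integer seed;
  `run_cade` twice with the same config and seed yields byte-identical
  candidate tables.

## Study sizes

The shipped experiments use 40 phantom cases (30 train / 10 test) for the
detection study and 500 balanced samples for the diagnosis study — sizes at
which the phantom statistics are stable while the whole suite stays
comfortably runnable on a laptop-class single CPU.

## Known limitations

- The volume gate's reference (3 545 668 voxels) is meaningful only for
  scan geometries resembling its origin; with very different spacing it
  should be overridden (as `LungSegConfig.for_phantom` does).
- Severe parenchymal pathology that alters lung opacity breaks the
  HU-window growing step by construction; the gate can only detect, not
  repair, this.
- The rule thresholds and watershed level are calibrated on phantom
  statistics; clinical data would need recalibration on annotated cases.
- HOG resampling to a fixed length mixes per-slice descriptor positions for
  objects spanning many slices; a slice-attention or 3D descriptor would be
  the modern alternative and is out of scope.
- The malignancy stage consumes radiologist-reported descriptors;
  computing those seven features from the image itself is deliberately not
  attempted.
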