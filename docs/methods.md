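# Methods

`dentmorph` implements a taxonomic-attribution workflow for lower deciduous
second molars (dm2) built around outline geometric morphometrics, with two side
analyses: lateral enamel-thickness indices from segmented microCT volumes and
radiocarbon calibration of associated layer dates.  This note records the
models, the defaults and their rationale, the numerical choices, and what the
synthetic data can and cannot establish.

## Crown orientation and outline extraction

A crown mesh is oriented into a canonical occlusal frame before any 2-D
analysis.  The cervical line (an ordered 3-D point loop digitized at the
enamel–root boundary) defines the reference plane by total least squares: the
plane minimizing summed squared orthogonal distances, computed from the
smallest singular vector of the centered points.  The plane becomes z = 0 with
the occlusal side positive; caller-supplied fissure direction hints set the
mesiodistal axis along x and the buccal side toward +y (fissure digitization is
a manual step on real specimens, so the hints are inputs, not detected).  The
canonical convention is a **left** lower molar: mesial = +x, buccal = +y,
occlusal = +z.  Right-side specimens are mirrored across the y–z plane (faces
re-wound to keep outward orientation) and the mirror flag is stored in the
returned frame.

The occlusal silhouette is the outer boundary of the mesh footprint on z = 0,
computed by rasterizing the projected triangles (default grid 0.02 mm) and
tracing the largest closed contour.  Rasterization was chosen over exact
polygon union because surface-scan meshes are frequently non-watertight; the
resolution is a config knob and tests verify ~1 % area convergence on analytic
shapes.  By default only geometry at z ≥ 0 is projected (the crown above the
cervical plane); a flag projects the full footprint.

## Pseudo-landmarks and size normalization

Each closed outline is reduced to k = 16 pseudo-landmarks at the intersections
of equiangular rays from the outline's **area centroid** (shoelace centroid)
with the boundary.  The first ray points buccally (+y); successive rays step
clockwise in the occlusal view (buccal → mesial → lingual → distal).  Only the
first ray's direction is anatomically fixed; the rotational direction of the
remaining rays is a convention, recorded in the configuration metadata so
reference datasets digitized with the opposite convention can be re-indexed.
Where a ray crosses the boundary more than once (non-convex outlines) the
farthest crossing is kept, because the crown silhouette is the outermost
contour.

Size is removed by scaling each configuration to unit **centroid size**,
CS = √Σᵢ‖xᵢ − x̄‖², the standard geometric-morphometrics size measure, computed
about the landmark mean.  The ray origin is the area centroid while CS centers
on the landmark mean; both choices are deliberate and logged.  There is no
rotational (Procrustes) alignment: radial directions are already fixed by
anatomy, so configurations are compared in the oriented frame.  Crown
diameters (MD, BL) are the bounding-box extents of the oriented outline.

## Shape space, screens and group testing

Normalized configurations are flattened to 32-vectors and eigendecomposed
about their mean (SVD of the centered data; eigenvalues are ddof = 1 sample
variances).  PCA runs on the covariance matrix without per-coordinate
standardization — after unit-CS scaling all coordinates share units.  The
number of retained PCs is the smallest k whose cumulative variance fraction
reaches a target (default 0.92).

Distributional screens run per PC: Shapiro–Wilk normality within each group
and Fligner–Killeen variance homogeneity across groups (scipy
implementations).  Degenerate cases (groups under 3, constant scores) are
flagged and reported as NaN rather than raised.

Group differences are tested with pairwise two-group PERMANOVA on Euclidean
distances over **all** n−1 PCA coordinates (classification, by contrast, uses
the variance-fraction selection; the two conventions are intentionally
different and both configurable).  The statistic is Anderson's distance-based
pseudo-F; p-values use the add-one permutation convention
(1 + #{F* ≥ F}) / (1 + N_perm) with N_perm defaulting to 9,999 and an explicit
seed, and Bonferroni correction over the number of pairs.  Each pair is tested
on its own rows only.  The pseudo-F for two groups reduces exactly to the
classical ANOVA F in the univariate case, which the tests exploit as an
oracle; scikit-bio's PERMANOVA serves as an independent cross-check of the
statistic.

Groups whose adjusted pairwise p exceeds 0.05 are merged into one class before
classification — the operational version of pooling statistically
indistinguishable reference samples (e.g. Upper-Paleolithic and recent
*H. sapiens* into a single modern-human class).

## Classifiers

Three supervised models are trained on the selected PC scores:

* **FDA** — flexible discriminant analysis: the class-indicator matrix is
  regressed on an adaptively built hinge (MARS) basis, linear discriminant
  analysis in that basis space yields canonical variates, and posteriors come
  from a multinomial logistic model on the variates.  The logistic calibration
  replaces the usual Gaussian class-conditional posterior because hinge
  features are strongly non-Gaussian within classes; with Mahalanobis-based
  posteriors a specimen exactly between two symmetric groups can receive a
  posterior far from 1/2 even though it sits on the decision boundary.
* **MARS** — multivariate adaptive regression splines on the indicator matrix,
  implemented in-package: the forward pass greedily adds mirrored hinge pairs
  (candidate knots restricted to ≤ 32 quantiles per predictor), the backward
  pass deletes terms under generalized cross-validation
  GCV = (RSS/n)/(1 − C/n)², C = terms + d·knots with knot penalty d = 3 and
  distinct knot locations counted once (a mirrored pair shares its knot).
  Defaults: additive (degree 1), max 21 terms.  Posteriors are the clipped,
  renormalized fitted indicators.
* **RF** — random forest (scikit-learn), 500 trees, √p features per split,
  vote-share posteriors, explicit seed.

Model validation is repeated stratified 10-fold cross-validation (default 10
repeats, re-randomized from a named seed); folds are stratified so the
smallest reference group still appears in every training split, and the fold
count degrades gracefully when a class has fewer members than folds.  Accuracy
is the pooled per-fold fraction correct.

## Synthetic study populations

The generator draws closed outlines from a radial harmonic model
r(θ) = R₀(1 + Σⱼ aⱼcos jθ + bⱼsin jθ), with per-taxon coefficient means and
independent Gaussian coefficient noise (diagonal covariance — the simplest
controllable effect-size knob).  Outlines are star-shaped by construction,
matching the assumption of centroid-ray landmarking; non-star-shaped edge
cases are built as explicit polygons in the tests.  Realisations with
non-positive radius are rejected and redrawn (cap 100).  The packaged
two-group preset places the contrast on the second harmonic — a bucco-distal
enlargement for the Neanderthal-like group versus a narrowing for the
modern-human-like group — at a base radius of 4.5 mm (deciduous-molar crown
scale) and coefficient sd 0.02.

Because both groups are Gaussian with equal diagonal covariance in coefficient
space, the Bayes accuracy has the closed form Φ(Δ/2) with Δ the Mahalanobis
separation, and a Monte-Carlo likelihood-ratio oracle verifies it.  The
classifier-recovery studies use Δ = 3.29 (Bayes ≈ 0.95) with 60 outlines per
group; the pipeline demo uses Δ = 2.5 (Bayes ≈ 0.89) with 31 per group, a
sample size on the order of the larger reference groups in published dm2
comparative samples.  What passing these tests shows: the full pipeline
(landmarking → PCA → classifier) loses almost none of the information the
generative model provides.  What they do not show: performance on real crowns,
whose shape variation is not harmonic-Gaussian, whose outlines carry wear and
restoration artifacts, and whose group covariances differ.

Voxel phantoms are prismatic dentine cores (with an optional central
paraboloid basin, default basin radius half the minimum outline radius) under
a uniform Euclidean-dilation enamel shell, built on a grid starting at the
cervical plane.  Slab volumes and surfaces of the cylindrical phantom have
closed forms used as oracles.  Cervical-line fixtures are noisy planar
ellipses.

## Lateral enamel thickness

The lateral slab runs from the cervical plane to a parallel cutting plane
through the lowest EDJ point in the mid-occlusal basin.  "Mid-occlusal basin"
is operationalized (the study protocol gives no algorithmic definition) as:
the topmost dentine voxel of each column whose immediate occlusal neighbour is
enamel (this excludes lateral-wall EDJ voxels, which have more dentine above),
restricted to columns within the central 60 % of the cervical footprint's
directional radius (config knob).  The cutting height is the minimum such
voxel's upper face.

Within the slab, Ve and LDPV are voxel counts × voxel³.  SEDJ is measured on a
triangulated interface: marching cubes on the signed distance field of the
dentine label (inside minus outside Euclidean distance transforms), smoothed
with a 1-voxel Gaussian — raw binary or unsmoothed distance isosurfaces
overestimate curved areas by 5 % and more, while the smoothed field is within
≈0.5 % on the cylinder phantom.  Triangles are kept when the voxels straddling
them are dentine on one side and enamel on the other, clipped exactly
(Sutherland–Hodgman) against the two planes with a half-voxel margin at the
top — the slab is half-open, so a flat EDJ lying exactly in the cutting plane
belongs to the occlusal cap, consistent with voxel-center volume counting.
Damaged sides (e.g. a fractured distal face) are excluded by an angular sector
mask about the crown's vertical centroid axis, applied to both voxels and
triangles.  LAET = Ve/SEDJ (mm) and LRET = LAET/LDPV^(1/3) (scale-free) are
derived fields recomputed from the stored measurements, so the defining
identities hold exactly.

## Radiocarbon calibration

A conventional age t ± σ is calibrated against an IntCal-format curve (comment
headers; comma/whitespace columns cal BP, ¹⁴C age, 1σ; extra columns ignored)
on a 1-year grid obtained by linear interpolation of the tabulation.  The
posterior includes the combined-uncertainty normalization 1/√(σ² + σ_c²)
(OxCal-style); its effect is negligible but the choice is fixed.  HPD regions
accumulate grid points in descending density to the exact 1σ/2σ coverages
68.27 % / 95.45 %, merge contiguous runs, and report [older, younger] cal BP
bounds rounded to 10 years — the granularity of published date tables.  Mass
conservation, HPD nesting, and agreement of the identity-curve endpoints with
Gaussian quantiles are tested; with the published IntCal20 tabulation supplied
at `data/external/intcal20.14c` the suite additionally reproduces published
68.3 % ranges for two ultrafiltered charcoal/bone dates (the tabulation is not
bundled; it requires a download).

## Pipeline and reproducibility

A single YAML config drives the full analysis; all seeds are named fields, the
provenance block records the config hash and seed, and regenerating with an
identical config yields an identical report (no timestamps enter the output).
Stage-level logging reports record counts so filtering effects are auditable.
Errors carry the stage name (and specimen id where known).  The CLI exposes
`simulate`, `landmarks`, `diameters`, `shapespace`, `enamel`, `voxel-phantom`,
`calibrate` and `run-all`.

### Problem sizes used by the shipped studies

Classifier recovery runs 60 + 60 outlines at 256 outline points; the
permutation-calibration study runs 1,000 null datasets of 8 + 8 specimens with
199 permutations each; the enamel phantom uses 0.05 mm voxels (≈1.6 M voxels)
with a 0.2/0.1/0.05 mm refinement ladder; calibration uses a 20,001-point
calendar grid.  These sizes were chosen so every oracle comparison is
decisively resolved by the available statistical power.

## Known limitations

* The harmonic generator cannot produce non-star-shaped outlines, cusp-level
  anatomy, or wear facets; conclusions about real-specimen accuracy require
  the published reference landmark data.
* Enamel metrics assume isotropic voxels and a canonical pose with z = 0 at
  the cervical plane; no wear simulation or whole-crown (occlusal) thickness.
* Calibration covers single dates only — no Bayesian sequence/phase modeling
  or reservoir corrections.
* FDA's logistic posterior calibration is a deliberate departure from
  Gaussian class-conditional posteriors; decision boundaries are essentially
  unchanged but reported probabilities differ near the boundary.
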