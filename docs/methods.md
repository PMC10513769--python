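# Methods

`gliometry` quantifies contrast-enhancing tumor burden on 3D label-map
segmentations (e.g. from automated glioblastoma segmentation tools) and
derives longitudinal response-assessment statistics from the resulting
per-time-point burden series. This note documents the conventions, the
algorithms, the tunable parameters, and the known numerical behaviour.

## Data model and coordinates

All geometry is computed in physical millimetres. Voxel index `i` (0-based)
maps to position `origin + i * spacing` (voxel-center convention). NIfTI
volumes are reoriented to the closest canonical (RAS) axis order on load, so
array axis 2 is the superior–inferior (axial, through-plane) direction for
conventional acquisitions; the axial axis can be overridden for unusual
geometries. Label semantics are configurable (`label_map` selects which
integer labels count as contrast-enhancing tumor), because segmentation
tools disagree on label codes; without a map, any nonzero voxel is
enhancing.

Resampling to isotropic voxels (default 1.0 mm, nearest neighbour,
outer-edge alignment) is the recommended preprocessing and is on by default
in the pipeline; the measurement operators themselves work at any native
anisotropic spacing in mm.

## Lesion separation

Two enhancing voxels belong to the same lesion when they touch by a face,
an edge, or a corner — 26-connectivity in 3D, and correspondingly
8-connectivity for in-slice regions. Lesions are ordered by descending
voxel count (ties by lexicographically smallest voxel index) so outputs are
reproducible. No minimum-size filter is applied at extraction: size-based
filtering is a separate, opt-in response-assessment step (below).

## Bidimensional (2D) measurement

Per lesion and axial slice, the binary mask is converted to 0.5-level
marching-squares contours (foreground treated as 8-connected). This
convention makes the single-voxel case well defined: a 1 mm voxel yields a
diamond through its four face midpoints with both diameters exactly 1.0 mm.
Contour edges are subdivided to a sub-voxel arc-length step (default
0.1 mm) while preserving the original vertices. Contours are assembled into
polygonal regions with holes.

The longest diameter d1 is the longest segment between any two contour
vertices of one region that lies entirely inside the region; containment is
tested by sampling the segment at ≤ 0.2 mm and evaluating closed-set
point-in-polygon membership. The search is exhaustive over vertex pairs,
implemented lazily: pairs are visited in decreasing length order and the
first contained pair is the maximum (pairs within 1e-6 mm are collected as
ties). d1 is maximized over all slices and in-slice regions of the lesion
— lexicographic optimization, as in Macdonald-style practice: d1 first,
then the perpendicular d2 on d1's slice and region. d2 is the longest
contained vertex-pair segment whose angle to d1 lies within 90° ± 2°
(configurable); it is not required to intersect d1. Ties in d1 resolve
toward the larger d2, then lexicographically by endpoints. The product
d1·d2 per lesion, summed over lesions, gives the SPD.

### Digitization bias of the 0.5-level convention

The 0.5 level of linearly interpolated *binary* occupancy sits at the
midpoint between the last foreground and first background sample. On
diagonal directions this midpoint lies up to ~0.4 mm outside the true
object boundary at 1 mm spacing. Because d1/d2 are exhaustive maxima, they
preferentially find these bulges: on a digital sphere of diameter 20 mm the
measured 2D diameters are 20.62 mm (+3.1%) and the product is 425 mm²
(+6.25% over the continuous cross-section's 400 mm²). This is a property of
the convention, not a search error — an independent all-pairs brute force
over the same polygon returns the identical value, and every diametral
chord of that polygon already exceeds 20.0 mm. The bias shrinks roughly
linearly with voxel size and is smaller for objects whose extreme chords
align with the grid (a 30 mm grid-aligned ellipsoid axis measures +0.5%).
Users comparing against continuous ground truth should expect maxima-type
measurements on binary masks to run a few percent high at 1 mm resolution.

## Volumetry and sphericity

Volume is the foreground voxel count times the single-voxel volume — exact
for the digital object. Sphericity is Wadell's
ψ = π^(1/3)·(6V)^(2/3)/A with V the voxel-count volume and A the surface
area of the 0.5-level marching-cubes mesh. The stair-stepped mesh of a
binary mask inflates A by several percent, so digital spheres score
ψ ≈ 0.92–0.93 rather than 1.0; relative comparisons between shapes (the
intended use) are unaffected. For lesions of only a few voxels the coarse
mesh makes ψ unreliable (it can exceed 1).

## 2.5D measurement

The longest diameter is freed from the axial plane: d1 is the longest
segment between surface-mesh vertices (0.5-level marching cubes, matching
the 2D contour convention) that stays inside the lesion, where "inside"
means trilinearly interpolated occupancy ≥ 0.5 sampled at ≤ 0.2 mm. For
meshes above 2500 vertices the candidate set is decimated by a
deterministic stride that always retains the convex-hull vertices, so
extreme-distance candidates survive. A plane perpendicular to d1 is then
swept along its extent at 0.5 mm steps; per plane, the mesh–plane
intersection curve is computed and d2 is the longest fully-contained chord
between curve points, maximized over planes. The d1 direction cosines are
reported per lesion so direction instability between follow-ups can be
inspected; the 2D measurement's restriction to axial slices acts as a
regularizer that this mode deliberately removes.

By construction the 2.5D d1 search space is a superset of the 2D one, so
2.5D d1 ≥ 2D d1 up to discretization slack (≤ 1%).

## Response-assessment rules

Defaults follow the guideline parameters exactly and apply **no** lesion
filters — every segmented lesion contributes to the burden, the mode
recommended for automated segmentations whose fragmentation would otherwise
interact badly with size filters:

| parameter | default | meaning |
|---|---|---|
| `measurability_mm` | 10.0 | both d1 and d2 must reach this (inclusive) |
| `max_target_lesions` | 5 | cap on target lesions when the limit is on |
| `threshold_2d` | 0.25 | fractional SPD increase over nadir ⇒ progression |
| `threshold_volume` | 0.40 | fractional volume increase over nadir ⇒ progression |
| `apply_measurability`, `apply_target_limit` | off | opt-in filters |

The "five largest" ranking uses the per-lesion value of the metric being
aggregated (2D product for SPD, volume for volumetry), ties by lesion id.
The measurability threshold is applied in mm regardless of native spacing.
Non-measurable lesions are counted and their share of the total 2D and
volume burden is reported.

## Longitudinal statistics

- **Trend labels**: increasing / decreasing / constant per adjacent
  time-point pair; "constant" uses a relative tolerance of 1e-9
  (effectively exact equality — continuous measures rarely tie).
  Trend agreement between two methods is the percentage of matching labels,
  pooled over all patients' transitions (a per-patient breakdown is also
  available through the library).
- **Spearman's rho** via average-tie fractional ranks (scipy). For the
  TTP–OS correlation the p-value is the exact two-sided permutation value
  (full enumeration) for n ≤ 9 patients and the t-approximation otherwise.
- **ICC** is the two-way, single-measurement consistency form, ICC(3,1) =
  (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error) from a two-way
  ANOVA without interaction. Consistency (not absolute agreement) is the
  right variant here because a constant per-rater offset does not affect
  relative response assessment; the implementation is offset-invariant by
  construction and is cross-checked against pingouin's ICC table in a test.
- **Time-to-progression**: scanning time points in order, the reference is
  the running minimum of the metric over all prior time points including
  baseline (`auto`), or the value at the most recent expert-flagged nadir
  (`expert`; preferred when flags exist, since automated under-segmentation
  can wrongly re-assign the reference). The first time point with value
  ≥ (1+threshold)·reference is progression (the comparison is inclusive);
  its days-from-surgery is the TTP. Never-progressing series get
  TTP = overall survival. The clock origin is the first resection. If the
  reference is 0 (complete disappearance) and enhancing burden reappears,
  progression is called at that time point and flagged (`zero_nadir_call`)
  — the relative increase is undefined there. New-lesion-based progression
  is intentionally not part of the TTP engine (size thresholds only);
  lesion counts are reported alongside. TTP is weakly monotone in the
  threshold by construction.
- **Threshold sweep**: mean (automated TTP − expert TTP) in days per
  candidate threshold, the quantity used to study tool-specific threshold
  adaptation.

## Phantoms

The phantom module is the stand-in for imaging data: voxelized solids with
closed-form geometry (voxel foreground iff its center lies inside the
solid). Kinds: spheres, ellipsoids (with in-plane rotation), boxes,
multifocal scenes, and fragmented shells — sectors of a spherical shell
band emulating recurrence scattered along a resection-cavity wall, with
gaps ≥ a configurable arc (default 3 mm at the narrowest radius) so
26-connectivity cannot merge fragments. Ground truth records closed-form
volume, axial and 3D diameters where analytic, and per-fragment volumes.
Identical specs produce byte-identical masks; all randomness flows through
one explicitly passed seeded generator.

Voxelization accuracy: volumes of digital spheres spanning ≥ 12 voxels are
within 3% of the closed form; smaller digital balls can deviate by ~5%
(e.g. r = 5 mm: +5.4%), which the growth-series design accounts for.

Growth series scale a baseline sphere so true volumes follow
V_t = V_0·∏(1+g_i). The seeded sampler draws per-step growths from a fixed
option set and rejects traces whose ratio-to-running-minimum comes within
0.08 of the 1.25/1.40 progression boundaries (or whose radii leave the
grid). Measured digital-sphere volumes over the radius range visited carry
at most ~5.4% pairwise ratio distortion, so the 0.08 margin guarantees the
measured trace crosses exactly where the true trace does — the
exact-recovery property is deterministic, not seed-dependent. Rater tables
(subject effect + rater offset + noise) provide an analytic expected ICC =
σ²_subject/(σ²_subject+σ²_noise).

What the phantoms do **not** emulate: MRI intensities, segmentation error
beyond fragmentation/multifocality, registration differences between
follow-ups, irregular (non-convex, infiltrative) lesion shapes, and
longitudinal lesion identity. Passing phantom tests therefore demonstrates
the correctness of the measurement and assessment machinery, not the
fidelity of any upstream segmentation.

## Problem sizes and runtime choices

Tests run on grids ≤ 72³, lesions up to ~30 mm, 20 growth series of 5 time
points, and oracle batches of ~60 random 2D regions / 20 random 3D lesions
/ 50 random 16³ volumes; the complete suite and the acceptance script each
finish in a few minutes on one CPU. Oracle-equivalence tests use a 0.5 mm
contour refinement step (still sub-voxel) to keep all-pairs brute force
tractable; accuracy-oriented tests use the 0.1 mm default.

## Known limitations

- No longitudinal lesion matching/tracking across time points.
- No DICOM input, no registration, no raw-MRI handling.
- The 2.5D plane sweep covers d1's extent at a fixed step; pathological
  lesions whose widest perpendicular section falls between planes can be
  underestimated by up to the step's geometric effect.
- Maxima-type measurements on binary masks carry the positive digitization
  bias quantified above; it is a property of the 0.5-level convention
  shared by the 2D and 2.5D modes.
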