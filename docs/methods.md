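# Methods

## The problem and the model

The proximal tibia of the mouse presents, proximal to distal, four
compartments: epiphyseal trabecular bone, the non-calcified growth-plate
cartilage band, the fine newly-formed primary spongiosa, and the mature
secondary spongiosa. Trabecular morphometry is only comparable across
animals when the analysed volume of interest (VOI) is anchored on the
*transitional interfaces* between these compartments — Z_eg
(epiphysis/growth plate), Z_gp (growth plate/primary) and Z_ps
(primary/secondary) — rather than on a fixed distance below the growth
plate, because treatments that expand the primary spongiosa move Z_ps
while leaving a fixed offset in place.

`tibmorph` detects these landmarks with the regional probability
distribution method: a per-slice classifier emits probabilities
P(z, C) over the four compartments; after rolling-median smoothing the
landmarks are the first equality points of adjacent class probabilities
in the scan direction (Z_eg proximal→distal, Z_ps distal→proximal, Z_gp
inside the interval they bound). On discrete slices the crossing is
located as the first sign change of D(z) = P(z, a) − P(z, b), with the
sub-slice position obtained by linear interpolation of D; this removes
the half-voxel bias of reporting whole slice indices. An exact zero at a
slice yields that slice's z. Multiple equality points caused by residual
noise are resolved by taking the first crossing in the scan direction,
which matches the min(z)/directional definition of the landmarks.

The probability rows are re-normalized after median filtering (medians of
columns need not sum to one); the correction is of order 1e-3 and has no
measurable effect on crossings. A compartment whose smoothed probability
never reaches the absence threshold (default 0.5 — it must dominate
somewhere to count as present) is declared absent; when the primary
spongiosa is absent, Z_gp and Z_ps are undefined and the fallback
landmark Z_gs (growth plate meets secondary spongiosa, the first crossing
of P(z,1) = P(z,3)) is reported instead. More than two absent
classes aborts: the profile is then not a tibia-like succession.

## Slice classifier

The classification backbone is pluggable. The implemented backbone,
`feature_baseline`, is a multinomial logistic regression (scikit-learn,
lbfgs, standardized inputs) on 13 per-slice descriptors: bone-area
fraction, medullary bone-area fraction, connected-component count, a mean
trabecular-thickness proxy (2× mean in-plane EDT of the bone phase), a
low-intensity-band score capturing the cartilage seam (fraction of the
silhouette interior with intensity in [0.2, 0.55] of the volume-
normalized range), and an 8-bin radial mean-intensity profile. It is
deterministic given the training set and seed, which makes end-to-end
landmark tests reproducible. The conventional deep recipe (cross-entropy,
SGD, learning rate 1e-3, batch 64) is retained in `TrainConfig` for
optional CNN backbones, which are not required by any part of the
pipeline or tests.

Annotation handling follows standard multi-rater practice: per-slice
majority vote with ties broken toward the lowest class code (the
most-proximal-compatible compartment) and a logged warning; k-fold
cross-validation splits at the *bone* level so slices of one bone never
straddle the train/validation boundary (slice-level splitting would leak
near-duplicate neighbouring slices). Evaluation reports per-class
precision, recall and F1 (harmonic mean); a class with zero support has
undefined recall and is reported as absent rather than zero.

## Preprocessing

Otsu's threshold (256-bin histogram, exhaustive between-class-variance
scan, ties toward the lower threshold, strictly-greater comparison) +
largest connected component (26-connectivity in 3D) segments the bone
from the holder; slices are cropped to the *volume-level* 3D bounding box
— per-slice cropping would make slice geometry mutually inconsistent —
min–max normalized *per volume* (per-slice normalization would destroy
the cartilage/bone contrast the classifier relies on across z), and
resized to 384×384 with linear interpolation. Non-square crops are
resized anisotropically by default; a `pad_square` switch zero-pads
first for users who prefer aspect preservation.

## Phantom generator

The synthetic phantom emulates: an annular cortical shell; the four
compartments stacked along z with optionally sinusoidally undulating
interfaces (amplitude/period are free knobs — no quantitative tortuosity
data exists to fit them); trabecular texture per compartment as a
thresholded Gaussian random field; the cartilage band rendered at an
intensity between marrow and bone so that Otsu assigns it to background,
as in real scans; Gaussian PSF blur and additive Gaussian noise; optional
rigid misalignment of the emitted volume (ground truth stays canonical
with the applied transform recorded).

Texture calibration is closed-form: white noise smoothed with a Gaussian
kernel of width σ and thresholded at the standard-normal quantile of
(1 − BV/TV) gives the target volume fraction by construction (the field
is standardized within each compartment region before thresholding), and
the mean local thickness of the foreground is empirically
(1.15 + 3.1·BV/TV)·σ voxels over the relevant range (BV/TV 0.1–0.35,
σ 1–4), which is inverted to choose σ. Generated compartments land
within ±0.03 of the target BV/TV and ±2 voxels of the target thickness;
a target thickness below 2 voxels is rejected as unresolvable.

Ground-truth label semantics are *region occupancy*: every medullary
voxel carries the compartment code of the region it lies in (marrow
between trabeculae included), the bone phase being carried separately in
the trabecular mask. This is what makes the annotator slice rules well
defined on the truth: "a stripe of compartment X traverses the medulla
uninterrupted anterior→posterior" is implemented as a single 8-connected
component of the code touching both the anterior-most and posterior-most
medullary rows of the slice. The derived landmarks report the interface
*plane*: a distal-most-slice rule yields the distal face of that slice,
the proximal-most-slice rule (Z_eg: first slice with any cartilage) its
proximal face — with flat interfaces the landmarks then equal the
cumulative compartment heights exactly.

Default conditions: 5 µm voxels, 1.5 mm lateral extent, heights
0.5/0.1/0.3/1.2 mm (epiphysis/growth plate/primary/secondary), cortical
thickness 0.1 mm, textures BV/TV 0.35/0.30/0.12 and Tb.Th 70/30/50 µm for
epiphysis/primary/secondary — the ranges reported for untreated adult
C57BL/6 mice. A coarse 10 µm preset (0.96 mm lateral,
0.4/0.1/0.25/0.7 mm heights) is used for the end-to-end test loops;
cohorts draw heights ±10 %, BV/TV ±0.02 (s.d.) and 0.01 mm boundary
undulation so landmark positions genuinely vary across "animals". The
phantom deliberately omits beam hardening, ring artifacts and
polychromatic physics; passing tests therefore demonstrate the method's
behaviour under geometric/textural variation and noise, not robustness
to scanner artifacts.

## Geometry and VOIs

Alignment: first principal axis of the bone-mask voxel coordinates → +z;
the unsigned PCA axis is signed by putting the end with the larger
cross-sectional area (the epiphysis) at z = 0 (overridable); in-plane
rotation sends the mean ridge direction — per-slice furthest point from
the centroid within the proximal 65–75 % of the bone length — to +x.
Volumes are resampled with linear interpolation, masks nearest-neighbor.

VOIs are half-open z-intervals `[ref + offset, ref + offset + height)`
with `round(height/voxel)` slices (1 mm at 5 µm = exactly 200 slices), so
adjacent VOIs sharing a reference never share a slice; whether the 1 mm
heights include the reference slice is not standardized anywhere, and the
half-open convention was chosen for exact reproducible counts. The
epiphyseal VOI grows proximally: `[Z_eg − 0.25, Z_eg)`. When no
precomputed trabecular mask is supplied, a substitute threshold-based
segmentation (Otsu; per-slice cortical shell = bone components touching
the silhouette boundary; trabecular = bone ∩ medulla) is used — it is
explicitly *not* equivalent to a learned segmentation and the pipeline
prefers user-supplied masks.

## Morphometry

Local thickness follows the largest-inscribed-sphere definition,
computed as EDT → distance ridge → sphere painting. The ridge keeps a
voxel p unless a 26-neighbor q satisfies edt(q) ≥ edt(p) + |p−q| (the
ball at q then provably contains the ball at p), so pruning is exact and
the painted map equals painting from every foreground voxel — which is
also the brute-force oracle the tests compare against. Painted diameter
is 2·edt − 1 voxels (voxel-center to background-center distance, less one
voxel for the two half-voxel boundary layers), which reproduces analytic
balls and slabs within one voxel. The array border counts as background,
so edge bins are biased thin — one reason the depth profiles use 20 µm
bins rather than per-slice values.

BV/TV = trabecular/medullary voxel count; Tb.Th/Tb.Sp are voxel-weighted
*means* of the thickness map over the bone/background phase, with the
background restricted to the medulla so the cortical shell and exterior
never count as separation (the bounding region is not standardized; the
medullary choice matches the magnitudes conventional in tibia studies).
Depth profiles bin the same 3D thickness maps (computed once on the full
VOI) in half-open 20 µm bins; per-bin B.Ar/T.Ar voxel counts sum exactly
to the 3D counts and their volume-weighted mean equals the 3D BV/TV
identically.

## Statistics

* Paired TOST: one-sided t-tests of mean(d) ≤ −bound and ≥ +bound,
  p = max of the two, equivalence at p ≤ α (default bound 0.05 mm,
  α 0.05). Treated as paired because model and raters annotate the same
  bones. Zero-variance differences strictly inside the bounds report
  p = 0 with a degenerate-variance note rather than NaN.
* Model-vs-raters verdict: all pairwise TOSTs within one landmark ×
  group cell form the Bonferroni family (6 pairs for 3 raters + model;
  correcting across landmarks as well would conflate distinct questions
  and is not done — the family definition is logged in the output);
  the model passes when equivalent to ≥ 2 raters.
* ICC is fixed to ICC(2,1) — two-way random effects, absolute agreement,
  single measure (pingouin) — the standard choice for interchangeable
  raters; intra-operator ICC uses a subject × repeat matrix per rater.
* 3D morphometry: one-way ANOVA; Tukey HSD (statsmodels) only when the
  omnibus p ≤ 0.05; Shapiro–Wilk and Levene reported as diagnostics,
  never gating. Depth-resolved: per-bin ANOVA, Games–Howell (pingouin)
  when significant, colors blue (p > 0.05), light blue
  (0.01 < p ≤ 0.05), orange (0.001 < p ≤ 0.01), red (p ≤ 0.001); each
  band includes its upper edge, so p = 0.010 is orange. Bins are tested
  independently (no multiplicity across depth levels).

## Problem sizes in the test loops

The end-to-end landmark validation trains on 20 and evaluates on 10
coarse-preset phantoms (~96×96×145 voxels each, ≈4300 slices total), a
cohort size at which the ±0.05 mm recovery criterion and the TOST
equivalence are stable across seeds. Oracle comparisons for local
thickness run on random 40³ masks, where the exhaustive sphere-fitting
oracle is exact and fast. The statistical calibrations use 1000
simulated replicates (4 groups × n = 5 for ANOVA size; n = 8 paired
differences at the bound for TOST size).

## Known limitations

* The substitute trabecular segmentation is intensity-based and will
  misclassify thick trabeculae fused to the cortex; supply learned masks
  for real data.
* The phantom's trabecular texture is isotropic; real trabeculae are
  preferentially oriented along load paths.
* The feature baseline assumes the intensity conventions of the
  preprocessing chain (bone bright, cartilage intermediate); heavily
  beam-hardened scans would need descriptor retuning or a CNN backbone.
* Landmark detection requires a probability profile that actually
  crosses; profiles from severely truncated scans (missing epiphysis or
  diaphysis) yield absent landmarks with diagnostics, not extrapolation.
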