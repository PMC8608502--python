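# Methods

This note records the models, algorithms, parameter choices, and numerical
conventions behind `lungcad`, and what the synthetic validation does and
does not demonstrate.

## Conventions

Voxel index order is `(k, i, j)` = (slice, row, column), 0-based. World
coordinates are millimetres, ordered `(z, y, x)` to pair with the index
axes: `world = origin + index ⊙ spacing`. Intensities are Hounsfield units
(HU), clamped to the 12-bit CT range [−1024, 3071] at load time; `write_volume`
quantises HU volumes to int16 (1 HU), which is lossless for integer-valued
HU and below scanner noise otherwise. Masks are stored as uint8 and
round-trip bit-exactly. DICOM slices are ordered by spatial position, never
by file name; slice spacing comes from inter-slice position gaps, falling
back to the median gap (with a logged warning) when gaps vary by more than
10%, as happens with dropped slices.

## Lung segmentation

**Optimal threshold.** The isodata fixed-point iteration starts at the
volume mid-range and updates `T ← (mean{HU<T} + mean{HU≥T})/2` until the
update is ≤ `tolerance_hu` (default 0.5 HU, max 100 iterations). The
returned threshold satisfies the fixed-point property to that tolerance and
lies strictly between the two class means. A constant volume is rejected as
degenerate; non-convergence raises an error carrying the last threshold.
Against an exhaustive integer-HU scan for the fixed-point condition on
bimodal Gaussian histograms, the iteration agrees to well under 1 HU.

**Connectivity selection.** Air voxels (below threshold) are labelled with
6-connectivity (faces only — diagonal connectivity can leak through thin
mediastinal walls). Components touching any border face are ambient air and
are dropped; components touching *only* the top face are kept by default
(the trachea enters there on clinical scans) unless `lung.remove_airway` is
set. Of the interior components, the largest `lung.keep_components`
(default 2; a merged anterior junction yields 1) exceeding
`lung.min_volume_ml` survive. The function default for the minimum volume
is 400 ml — the clinical scale of an adult lung — while the shipped
pipeline config uses 50 ml to match the ~160 ml phantom lungs; the key
exists precisely so the scale can follow the data.

**Cavity filling** is 2D per slice with 4-connected background flood
filling: any in-slice background region not connected to the slice border
becomes foreground. This restores vessels and solid nodules that
thresholding removed from the lung interior. The operation is extensive
(output ⊇ input) and idempotent.

**Contour repair** recovers juxtapleural nodules — dense tissue attached to
the chest wall that thresholding excludes together with the body, leaving a
notch in the lung contour. Each in-slice connected component is compared
with its 2D convex hull; a hull *pocket* is filled when (a) its mouth — the
pixels where it meets the exterior — is at most `2·repair.ball_radius_mm`
wide (default 5 mm, i.e. mouths up to 10 mm, covering nodules up to ~10 mm
diameter), (b) it is at least 2 pixels deep and 3 pixels large (1-pixel-deep
pockets are digitisation steps of a convex contour, not indentations), and
(c) it does not touch another component (filling there would bridge the two
lungs across the mediastinum). A plain morphological closing was considered
and rejected: the closing ball partially penetrates any notch mouth
narrower than its diameter and strands the outer notch layer, recovering
only ~50% of a 3 mm notch where the pocket rule recovers it entirely. The
fill iterates to a per-slice fixed point (the digital hull of a partially
filled contour can expose one further pocket), which makes the operation
idempotent by construction; it remains extensive. Repair runs 2D per slice
so anisotropic slice spacing needs no resampling.

## Ring-filter detection

The response at in-lung voxel `x` and scale `r` is the disk/annulus
contrast `T(x, r) = meanHU(disk r) − meanHU(annulus r … a·r)` with annulus
factor `a = 1.6`; the per-voxel response is the maximum over
`detect.radii_mm` (default {2, 3, 4, 6, 8, 10} mm, covering the clinically
interesting 4–20 mm nodule diameters), floored at zero, with ties going to
the smallest radius so output is deterministic. Radii are converted to
pixels via the in-plane spacing; a radius below one pixel is a
configuration error. Filtering is 2D per slice — robust to the anisotropic
layer spacing of clinical scans — via FFT convolution; a response below
1e-6 HU is treated as zero so a contrast-free interior scores exactly zero
despite FFT round-off. Means are computed over in-mask pixels only, and a
voxel is scored only when at least 25% of its annulus lies inside the mask,
which suppresses pleural-edge artifacts. The operator is invariant to
global HU offsets and linear in nodule/background contrast.

**Candidate extraction.** Voxels with response ≥
`detect.response_threshold` (default 100 HU contrast) are clustered with
full 3D 26-connectivity (this also merges in-plane responses across
adjacent slices). Because a nodule's response region can connect to a
vessel network's, each cluster is split at its well-separated response
local maxima (minimum peak distance = `detect.min_separation_mm`) by a
watershed on the inverted response — standard blob-detection non-maximum
suppression; without the split, one candidate could stand for several
nodules with a centroid dragged many millimetres. Each basin yields one
candidate at its response-weighted centroid (snapped to the basin peak if
rounding leaves the mask), with the peak's best radius as the scale.
Candidates closer than `min_separation_mm` (default 4 mm) in world distance
are merged keeping the stronger; output is sorted by descending response.
On noise-free disks the peak response reproduces the analytic contrast
within 1% at the matching scale, and localization error on isolated
phantom nodules at 650 HU contrast and 20 HU noise is ≤ 2 mm.

## Features and screening

A candidate region is delineated by region growing from the brightest
voxel in the 3³ neighbourhood of the centroid (the response-weighted
centroid of a basin can land on an air voxel between structures; growing
from air would flood the growth box), accepting 26-connected voxels with
HU ≥ seed − `classify.growth_delta_hu` (default 150 HU, tolerant to noise
at sd ≤ 50), inside the lung mask, within a box of half-width
`2·radius_mm`. Regions under 3 voxels raise a feature-extraction error and
the candidate is rejected.

Descriptors: physical volume and equivalent spherical diameter;
circularity `4πA/P²` on the peak slice (most region voxels), with the
Crofton perimeter estimate and a cap at 1.1 absorbing small-region
discretisation; elongation as the square root of the extreme eigenvalue
ratio of the 3D second-moment tensor in mm — chosen over a 2D measure
because a through-plane vessel looks circular in any single slice;
mean/max HU; contrast against a 2-voxel dilated shell; and the mean HU
gradient magnitude (per mm, spacing-aware) over border voxels. Contrast and
shape features are invariant to global HU offsets; mean/max shift with
them.

**Screening.** The default false-positive reducer is a rule set — all of
`equivalent_diameter_mm ≥ 3`, `circularity ≥ 0.6`, `elongation ≤ 2.5`,
`contrast_hu ≥ 100` — with the score reported as the fraction of rules
passed. The size rule is 3 mm rather than the 4 mm clinical reporting
cutoff because partial-volume averaging on a 2 mm slice grid makes a 4 mm
nodule measure slightly small. The elongation and circularity rules are
what reject vessel fragments; the contrast rule rejects mask-edge noise.
An alternative trained classifier — a Fisher linear discriminant on
z-scored features, with the pooled within-class covariance solved with a
small ridge (escalated with a warning when features are near-collinear)
and the boundary at the class-mean midpoint — is available via
`classify.mode: linear` and a model JSON. Its logistic score is the exact
posterior under the shared-covariance Gaussian model, and its held-out
accuracy on known two-Gaussian features sits within a few points of the
numerically integrated Bayes rate. The screening stage treats
classification as nodule vs non-nodule; class names are configurable.

## Evaluation

A truth nodule is *detected* when a candidate centroid lies within
`max(hit_distance_mm, nodule radius)` of its centre (default 5 mm).
Matching is greedy by ascending distance, one candidate per truth, ties
broken by descending candidate response — deterministic and standard in
CAD scoring. Unmatched candidates are false positives; results report
sensitivity in percent and false positives both in total and per set
(exact and rounded to the nearest integer, the rounding clinical summaries
use). Sensitivity is monotone in the hit distance, and aggregate counts
equal the sum of per-set counts.

## The phantom generator

The generator emulates the variability the pipeline must tolerate: HU
contrast between air, lung parenchyma, soft tissue and nodules; anisotropic
voxels; vessels as confusable bright elongated structures; the three
clinically distinct nodule placements; and additive noise. Defaults: a
64×128×128 grid at (2, 1, 1) mm — desk-scale but anisotropic like clinical
CT; background −1000 HU; a (58, 52, 58) mm soft-tissue body ellipsoid at
40 HU; two (45, 35, 24) mm lung ellipsoids at −850 HU offset ±28 mm,
leaving an 8 mm mediastinum; 8 seeded random-walk vessel tubes of radius
0.8–1.5 mm at 50 HU confined to the lungs; nodules as spheres with a
linear partial-volume ramp one mean-voxel wide at the boundary; Gaussian
noise at sd 20 HU (sd 30 is the documented upper bound for the Dice
guarantee). Nodule HU defaults to −200 (650 HU contrast over lung) — a
solid-nodule contrast, deliberately easier than ground-glass opacities,
which are out of scope. The default spec carries one nodule of each
placement class; `isolated_nodule_spec(n, seed)` builds detection
benchmarks with well-separated isolated nodules (≥ 3 mm clearance from the
pleura, ≥ 12 mm between surfaces, diameters 6–16 mm).

Placement semantics are enforced by construction: vessels keep a
`radius + 2 mm` clearance from isolated nodules (otherwise every "isolated"
nodule would be de facto juxtavascular), juxtavascular nodules receive a
companion tube starting at their surface, and juxtapleural nodules are
centred on the lung boundary and carve their sphere out of the returned
lung truth mask — the truth describes the air-like lung region as imaging
sees it, which is also what makes the repair test meaningful. One RNG seed
is split into named substreams (vessels, companions, noise), so enabling
vessels never changes the noise realisation; a fixed (spec, seed) pair is
bit-reproducible.

**What the phantom does not model:** airways and the trachea, lobar
fissures, real vascular trees, the anterior junction where the two lungs
meet, ground-glass or cavitating nodules, scanner physics (beam hardening,
reconstruction kernels, streaks), and patient motion. Passing the phantom
suite therefore shows the algorithmic chain is correct and stable under the
modelled variation — it does not certify clinical performance, which
depends on exactly the unmodelled effects (juxtavascular attachment alone
already halves screening sensitivity on the default phantom).

## Problem sizes and determinism

Validation runs use the 64×128×128 phantom (one pipeline run ≈ 2 s), 5
seeds for segmentation and end-to-end checks, 10 seeds for the threshold
oracle, 50 random masks for the morphological-operator laws, and 1000
examples per class for the classifier — sizes at which every check is
comfortably reproducible on one CPU. All pipeline stages are deterministic
given their input; the only randomness is the seeded phantom and classifier
data generation, so repeated runs with a fixed seed produce byte-identical
candidate CSVs.

## Known limitations

* Thresholding assumes a bimodal HU histogram; contrast-enhanced or
  severely diseased lungs (consolidation, effusion) can defeat it.
* The 2D-per-slice ring filter under-responds to nodules spanning few
  slices at large slice spacing; a 3D spherical-kernel variant would help
  at the cost of resampling.
* The repair rule fills any narrow-mouthed boundary pocket, nodule or not;
  on real scans this can absorb small pleural irregularities.
* The rule screen's elongation cut rejects genuinely juxtavascular nodules
  whose grown region includes the attached vessel; separating nodule from
  vessel (e.g. by morphological opening of the region) is future work.
* Circularity uses the in-plane metric of the mean in-plane spacing; on
  grids with strongly unequal row/column spacing it is approximate.
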