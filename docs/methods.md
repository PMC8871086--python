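# Methods

## Color segmentation

An 8-bit sRGB ROI is converted to CIE 1976 L\*a\*b\* under D65 (sRGB transfer
function, via scikit-image). K-means with k = 3 (Lloyd's algorithm,
k-means++ initialization, best of 10 restarts by inertia, tolerance 1e-4 on
centroid movement, at most 300 iterations, fixed default seed 0) clusters the
pixels on the chromatic **(a\*, b\*) coordinates only**: in an H&E stain the
eosin/hematoxylin contrast is chromatic, while L\* mostly encodes section
thickness and illumination. L\* is then used for what it is good at — naming
the clusters: the cluster with the highest mean L\* becomes **background**
(unstained, near-white), the lowest becomes **foreground** (hematoxylin-dark
nuclei, glands, follicles), and the remaining one **collagen**. Two clusters
whose mean L\* agree to within 1e-6 make the roles undecidable and raise an
error rather than guessing. k stays fixed at 3 even for ROIs that genuinely
lack a class (e.g. pure scar with no background); the role rule still
applies and the downstream percentages simply reflect the resulting split.
Clustering is per ROI, not per slide, so centroids adapt to local stain
intensity.

## Collagen density

The collagen mask (as {0, 1}) is convolved with an **airy-disk kernel**: the
weight at pixel offset ρ is [2·J1(x)/x]² with x = 3.8317·ρ/r, so the central
weight is 1 and the first zero falls at ρ = r; the kernel is truncated there
and normalized to unit sum. It is a smooth, rotationally symmetric,
compactly supported local average — the same kernel weights the vector
summation below, which is what makes the variance a ratio of two like-scaled
convolutions. Borders use reflect padding so an all-collagen mask maps to
density 1 everywhere (to within the kernel's 1e-9 unit-sum normalization).
Default radius r = 16 px.

## Fiber orientation

For every collagen-positive pixel the mask is sampled along line segments of
length 2·w + 1 through the pixel (nearest-pixel sampling) at n evenly spaced
axial candidate angles k·180°/n; an angle's score is the number of
collagen-positive samples, and θ is the arg-max, ties broken toward the
smaller angle for determinism. A pixel whose best score is ≤ 1 — no support
beyond itself, an isolated point — is marked invalid, as is every
collagen-negative pixel. Defaults: window radius w = 8 px, n = 18 angles
(10° steps), chosen so that a 3-px-wide fiber several windows long is
resolved to its drawing angle exactly (the worst-case quantization error is
half a step, 5°). The score counts binary mask samples rather than grayscale
intensity variance; on segmented H&E the binary collagen mask is the
available signal, and the count is what the synthetic ground truth can
verify directly.

Angles are axial (θ ≡ θ + 180°), measured counter-clockwise from the +column
axis with rows increasing downward: a one-row horizontal stripe scores
θ = 0°, and rotating the mask by 90° rotates the field by 90° mod 180.

## Directional variance

On valid pixels the doubled-angle components X = cos 2θ, Y = sin 2θ (zero
elsewhere) are convolved with the same airy kernel; R = √(Xc² + Yc²) and

    V = 1 − R / m,

where **m is the kernel-smoothed validity mask**, not the raw collagen mask.
Using the same kernel and the same support for numerator and denominator
makes R ≤ m a pointwise triangle inequality, so V ∈ [0, 1] holds exactly
rather than approximately; V is additionally clipped against ≤ 1e-9
floating-point overshoot. Pixels with m = 0 are invalid, never a division
error — background is routine, not exceptional. Closed forms used as test
anchors: constant θ gives V = 0; an even mix of two orthogonal orientations
gives V = 1 (the doubled angles cancel); a p : (1−p) orthogonal mix gives
V = 1 − |2p − 1|.

## Per-ROI metrics and statistics

FS% and CAS% are percentages of **all ROI pixels**; CDM% is the mean of the
density map × 100; DV% is the mean of V over **valid pixels only** (reported
as NaN, never 0, when no pixel is valid). These denominators are the
simplest self-consistent choice and are stated here prominently because
figure-level percentage conventions vary between studies.

Two groups of ROI metrics are compared with the **pooled-variance Student's
t-test** (two-sided; Welch's correction available behind a flag), three or
more with one-way ANOVA; zero-variance degenerate inputs follow the p = 1
convention when the means agree and raise otherwise. No multiple-testing
correction is applied across the four metrics; callers comparing many
metrics should correct downstream.

## Synthetic generator

`histoscar.synthetic` renders what the pipeline needs to be testable: a
near-white background, eosin-pink collagen fibers as thick anti-aliased
segments (default width 3 px, length 1.5× the frame diagonal so fibers span
the ROI), hematoxylin-purple ellipses for hair follicles/glands and small
ellipses for nuclei, and i.i.d. Gaussian pixel noise (sd 5). Per-fiber axial
angles follow the standard axial construction — von Mises on doubled angles,
κ = 0 being isotropic — so κ directly controls the expected directional
variance. Ground truth records the last-drawn class per pixel ("last drawn
wins", simple and deterministic) and the fiber's drawing angle on collagen.
The palette's pairwise (a\*, b\*) separations exceed 40 units (a spec with
separations under 15 is rejected as untestable) and its mean-lightness
ordering (background > collagen > structure) matches real H&E.

Fiber counts for a target coverage come from the Poisson-overlap law
1 − exp(−N·c·w/A) with mean chord c = 0.85·√A, a geometric constant
calibrated once against the drawing routine; rendered coverage lands within
a few percent of the target.

Presets model the three regions of a thermally injured dermis:

| preset | coverage target | κ | follicles/glands | nuclei |
|---|---|---|---|---|
| normal | ~50% | 0 | yes | yes |
| scar | ~90% | 8 | none | yes |
| mixed | left half scar, right half normal | | | |

Scar tissue keeps its nuclei: injury destroys follicles and glands, but
cells repopulate the scar, and those nuclei are also what keeps a
three-cluster segmentation well-posed on pure-scar ROIs. The scar preset's
mean fiber angle is drawn per seed so replicate ROIs differ in alignment
direction as real sections do.

What the generator does **not** emulate: stain variation between slides,
out-of-focus blur, fiber curvature and branching, chromatin texture inside
nuclei, and the continuous eosin intensity gradients of real collagen.
Passing tests therefore demonstrate that the algorithms recover known
structure under controlled conditions, not that they are robust to every
slide-preparation artifact.

### Dataset utilities

Rotation augmentation emits every image at every angle of the default
{0°, 90°, 180°, 270°} set (right angles are lossless pixel rearrangements;
other angles require an explicit interpolation flag), quadrupling a dataset,
e.g. 93 → 372. The seeded train/validate/test split takes
⌊n·f_val⌋ and ⌊n·f_test⌋ with the remainder to train — the rule that maps
372 at (0.64, 0.16, 0.20) to exactly 239/59/74.

## Numerical and design notes

* All randomness is seeded: the generator through its spec, K-means through
  its seed argument, the split through its seed; identical inputs give
  identical outputs.
* Nearest-centroid ties in K-means resolve toward the lower cluster index
  (scikit-learn's argmin convention), and orientation-score ties toward the
  smaller angle, keeping runs deterministic.
* 16-bit inputs are rescaled to 8-bit with the exact full-range integer map
  v·255 // 65535; JPEG input is refused by default because its lossy chroma
  handling shifts exactly the (a\*, b\*) coordinates the clustering uses.
* Problem sizes in the test-suite and acceptance script (ROIs from 96² to
  750×500, 10 ROIs per group, 2000-replicate null calibration) were chosen
  as the smallest at which every property is comfortably expressed.

## Known limitations

* The orientation estimator quantizes to 180°/n; sub-step accuracy would
  need interpolation over the score profile.
* On very dense masks (coverage near 1) line scores saturate and the
  estimated field gets noisy; the directional-variance ordering between
  aligned and isotropic tissue survives, but per-pixel angles there are less
  reliable than on sparse masks.
* Percent metrics are reported without physical units; scanner resolution
  (µm/pixel) is not used in any computation.
* Whole-slide pyramidal formats, stain normalization across slides, and
  stain deconvolution are out of scope; inputs are plain PNG/TIFF ROIs with
  optional externally produced masks.
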