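# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `octaquant`. All image operations run on calibrated rasters
of exactly 1 um per pixel, so pixel counts convert to physical units by
powers of ten; point coordinates are `(x, y)` in micrometres with the
origin at the top-left corner of the cropped image.

## Image preprocessing

En face angiograms (8-bit grayscale, one per eye per plexus) are cropped to
the scan region using the sidecar's crop box, then resampled to 1 um/px
with bilinear interpolation using the device's per-axis scaling (e.g. a
525 px crop at 5.60 um/px becomes 2940 px). Bilinear interpolation for
intensities and nearest-neighbour for masks avoid overshoot outside
[0, 255] and mask fuzz.

Enhancement is a median filter followed by a white top-hat, both with disc
structuring elements. The capillary caliber (~8 um) sets the scale
separation: the median radius (default 3 um) despeckles below the
capillary scale and the top-hat radius (default 15 um) flattens every
structure much wider than a capillary while passing vessels. A
consequence worth remembering: the top-hat *removes* structures wider than
about twice its radius, which is why large-vessel segmentation (below)
does not run on the enhanced image.

Binarization is an adaptive local-mean threshold: a pixel is vessel iff
its intensity exceeds the mean over a surrounding window *plus* an offset.
The sign of the offset matters: with `mean + offset`, a featureless
neighbourhood (constant or pure speckle) produces no foreground, which is
the behaviour a perfusion measurement needs. Defaults are a 200 um window
and an offset of 5 (8-bit units). The window must span several capillary
spacings: with a window comparable to the inter-capillary distance the
local mean rises to the vessel level inside dense beds and vessel
interiors fall below threshold (we measured ~0.05 perfusion
under-recovery at a 60 um window on synthetic angiograms); 200 um is wide
enough to estimate the background yet local enough to track illumination
gradients. The offset must exceed the residual noise floor after median
smoothing. Both are configurable and recorded in the run's resolved
configuration.

The binarized map is then *cleaned* before any morphometry: a 2 um
closing re-joins threshold-fragmented segments, objects smaller than
50 px and holes smaller than 30 px are removed. Without this step
speckle fragments inflate the skeleton length by 20-60% and the
area/length diameter collapses correspondingly.

Large vessels (SVC only) are segmented from the median-smoothed raw
calibrated image: global Otsu threshold, a 3 um closing, a binary opening
with a disc of the caliber-floor diameter (default 20 um) so only
structures at least that wide survive, and — when the survivors are still
intensity-heterogeneous — a second Otsu split on their intensities that
keeps only the bright components (arterioles and venules carry a
distinctly stronger flow signal than merged capillary clutter; the second
stage is skipped for two-level images where it would be degenerate).
Subtracting this mask from the binarized SVC map yields the
microvasculature used for all SVC capillary metrics.

## FAZ segmentation and regional geometry

The foveal avascular zone is segmented on the deep plexus: white top-hat,
Gaussian smoothing (sigma 5 um), Canny edges with hysteresis thresholds at
the 70th/90th intensity-gradient percentiles, a 12 um closing that welds
the vessel-wall edges into a vascularized territory, filling of enclosed
holes smaller than 0.02 mm^2 (a plain hole fill would swallow the FAZ
itself, which is exactly an enclosed avascular pocket), and an opening of
the avascular complement with a 30 um disc. That final opening is the
load-bearing step: it severs the narrow inter-capillary corridors that
would otherwise connect the FAZ to the peripheral background and let the
segmented region leak. The FAZ is the avascular 4-connected component
containing the image center (or the nearest one within 0.5 mm, largest on
ties); no such component, or a candidate spanning more than 30% of the
field, raises a segmentation failure and the eye is excluded with a
recorded reason.

Area is the foreground pixel count times 1e-6 mm^2. The boundary length
uses a polygonal estimator: the marching-squares contour resampled into
chords of at least 5 px (1/200 of the contour length for large shapes).
Raw chain-code or marching-squares lengths follow the pixel staircase and
overestimate smooth boundaries by ~5%, which biases circularity
(4*pi*A/P^2) of a digital disc down to ~0.90; the chord resampling removes
that bias (disc ~0.996, axis-aligned square ~pi/4) and the length-scaled
spacing keeps the estimate stable under magnification. Absolute
circularity values always depend on the perimeter estimator; comparisons
between groups measured with the same estimator are meaningful,
comparisons of absolute values across software are not.

The DVC FAZ centroid anchors the foveal disc (1 mm diameter) and the
parafoveal annulus (1-2.5 mm) for *both* plexuses of that eye, so SVC and
DVC descriptors refer to the same retinal location. The same segmentation
operator is applied to the SVC image to report SVC FAZ area/circularity;
a failure there is flagged but does not exclude the eye. OCT thickness
sectors are centered on the thickness-derived fovea instead; the two
centers are never silently mixed.

## Microvascular descriptors

For each (region x plexus): perfusion density (vessel-pixel fraction),
skeleton density (centerline length per area, 1/mm, from
topology-preserving thinning), vessel perimeter index (vessel boundary
length per area, 1/mm, from the polygonal contour of the full vessel map
counting chords whose midpoint lies in the region — clipping first would
manufacture boundary along the region rim), and mean vessel diameter
defined as vessel area / centerline length (um). That definition makes
`diameter x skeleton_density = 1000 x perfusion_density` an exact
identity, and it is the definition consistent with the reference cohort's
printed values (0.14 perfusion / 6.0 mm^-1 skeleton = 23.3 um); the
alternative `2 x area / perimeter` is not.

Fractal dimension uses Hausdorff box counting: boxes from a dyadic ladder
(default 4...512 px) tile the region's bounding box, a box counts when it
contains at least one vessel pixel inside the region, and the dimension is
the OLS slope of log N against log(1/eps), clamped to [0, 2]. Scales with
fewer than 4 occupied boxes are dropped from the top of the ladder
(slope stability). The estimator reproduces 2.0 on a filled square, 1.0 on
a line, and log8/log3 on a depth-5 Sierpinski carpet to within 0.01.

Lacunarity uses the gliding-box definition Lambda(r) = <M^2>/<M>^2 at unit
stride, where M is the vessel mass of each box position whose center pixel
falls inside the region. Lambda >= 1 always, with equality iff all box
masses are equal. The default box is 512 px, the setting under which the
reference cohort's values were reported; when a region's bounding box is
smaller the box shrinks to the largest power of two that fits and the row
is flagged. Note that with disc/annulus regions the boxes near the rim see
partial masses; that is part of this estimator's definition, and absolute
lacunarity values are comparable only at matching settings.

## Thickness sectors

Per-layer thickness maps (Retina, mRNFL, GCIPL, INL, OPL-ONL, ELM-IS/OS)
arrive on the acquisition raster with A-scan/B-scan spacings in mm. The
fovea is the argmin of the total-retina map smoothed with a uniform
circular kernel of 0.05 mm radius (pixels whose centers fall inside the
radius; ties resolved toward the map center; a flat map warns and returns
the center). Maps are resampled to a regular 0.02 mm grid with 2-D cubic
interpolation (local cubic, which reproduces planes to <0.01 um; axes
with fewer than 4 samples fall back to linear), and sector means are
averages over the 1 mm disc and 1-2.5 mm annulus. Sectors that extend
beyond the map warn and average available points.

## Synthetic data

The generators exist to provide exact ground truth, not biophysical
realism. Angiograms: capillary trees grow from peripheral seeds toward
the rim of a clean avascular ellipse by recursive midpoint displacement
(controllable, cheap), a jittered terminal arcade closes the FAZ rim as in
a real fovea, tubes are rendered at 8-12 um caliber (Gaussian
cross-profile, sigma 1.5 um) over a dim background, and multiplicative
gamma speckle (shape 4) is applied. The SVC carries 2-4 large vessels
(32-48 um) rendered with a stronger signal, matching the flow-signal
contrast that makes Otsu-based large-vessel separation possible on real
scans. Defaults mirror the targeted acquisition: a 2940 um field at
1 um/px, FAZ ~0.5 mm^2, parafoveal vessel fractions of ~0.23 (SVC
microvasculature) and ~0.37 (DVC). Each capillary tree draws from its own
seeded substream, so raising the density parameter extends the vessel set
without perturbing existing trees — the measured response is monotone by
construction, which the tests exploit.

What the generator does not emulate: real OCT-A speckle statistics and
motion artifacts, capillary dropout pathology, plexus-specific loop
morphology, projection artifacts between plexuses. Passing recovery tests
therefore demonstrates that the measurement chain is unbiased under
controlled conditions, not that it is robust to every clinical artifact.

Ground-truth recovery (20 seeds at the default field): FAZ area within
~0.5%, centroid within ~1 um, regional perfusion within 0.015, parafoveal
area/length diameter within 8%. The *foveal* diameter is not used as a
recovery criterion: in the synthetic fovea the vessels merge into the
terminal ring annulus, whose rasterized "caliber" is neither the generator
input nor stable between the measured and truth skeletons (loop structure
differs); the fovea's diameter is still computed and reported.

Thickness maps are per-layer sheets with a Gaussian pit (depth per layer,
negative depths model the outer-layer bump) plus smooth noise; the Retina
map is the exact sum of its layers. Cohorts draw a subject-level random
effect plus eye-level noise so the inter-eye correlation is exactly rho
(default 0.5) with the group means and SDs of the reference clinical
cohort (49 PD subjects / 40 controls, ~10% missing eyes); covariates (age,
sex, hypertension, MoCA, UPDRS-III, duration) follow the published
demographics.

## Statistics

Group comparisons are GEE fits with an exchangeable working correlation
over the subject and robust (sandwich) standard errors — two eyes of one
participant are not independent, and ignoring that understates
uncertainty. The univariate model regresses the descriptor on group; the
adjusted model adds age, sex and hypertension. Effect sizes are Cohen's d
in the unweighted form |m1 - m2| / sqrt((s1^2 + s2^2)/2), which is the
form consistent with the reference cohort's printed effect sizes (the
df-weighted pooled-SD form is not). p-values are uncorrected for multiple
comparisons by default, matching the reference analysis; a flag enables
Benjamini-Hochberg via statsmodels for users who want it.

Diagnostic models are logistic GEEs: a null model with the a priori
confounders (age, sex, hypertension) and a full model adding the
candidate descriptor(s); their difference is tested with a joint Wald test
on the added coefficients, and discrimination is read from ROC curves
built on the fitted probabilities, with AUC and a DeLong 95% CI (the CI
method is our choice; none was stated for the reference analysis). One
numerical guard: the moment estimator of the exchangeable correlation can
run past 1 when the outcome is constant within cluster (both eyes share
the diagnosis), making the working covariance indefinite; the estimate is
clipped to [-0.49, 0.95], which keeps clusters of two meaningfully
weighted and matches the inside-the-valid-region behaviour of mature GEE
implementations. Complete separation is detected from the fitted values
and flagged rather than hidden.

Calibration, measured by the acceptance script on simulated cohorts
(200 replicates, 500 subjects, rho = 0.5, FAZ-area-sized group shift):
group-effect estimates unbiased within Monte-Carlo error, robust 95% CI
coverage between 0.92 and 0.96 across seeds, exchangeable alpha recovered
at ~0.50, and a group-independent predictor scores AUC ~0.5.

## Problem sizes and degenerate inputs

Validation runs use a 2940 um field (the targeted acquisition geometry) for
the 20-seed recovery sweep and compact 1700 um eyes for unit tests; the
statistical suites use 200 replicates. Degenerate inputs have defined
behaviour throughout: empty regions, empty masks and empty skeletons raise
typed errors or return flagged sentinel values (FD 0 on an empty mask);
flat images yield empty vessel masks; flat thickness maps return the map
center with a warning; eyes whose FAZ cannot be segmented are excluded
with a machine-readable reason rather than contaminating cohort tables.

## Known limitations

* Absolute circularity and lacunarity depend on estimator settings;
  only within-package comparisons are meaningful.
* The SVC FAZ is measured with the DVC operator applied to the SVC image;
  on real data the plexuses converge near the fovea and SVC FAZ values
  should be read with the same caution as in the reference analysis.
* The adaptive-threshold defaults were chosen for 8-bit angiograms with
  speckle comparable to the synthetic model; heavily different devices
  will need the window/offset re-examined.
* Proprietary volume containers are out of scope; thickness maps must be
  exported to the documented TSV format upstream.
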