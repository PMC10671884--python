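# Methods

## The AVLR model

The arteriovenous length ratio treats each retinal image (or annular region
of it) as two populations of centerline segments — arteries and veins — and
summarizes their length morphology by the ratio of unweighted class means,

    avlr_m = mean_{artery segments}(m) / mean_{vein segments}(m),

for nine per-segment measures m: chord length, arc length, distance metric
(DM), inflection count metric (ICM), its "binomial" variant (ICMb), sum of
angles metric (SOAM), normalized total curvature (NC), standard deviation of
absolute curvature (SDAC) and smoothed centerline length (CL). Unweighted
means are used deliberately: the ratio then answers "is a typical artery
segment longer/more tortuous than a typical vein segment", independent of
how many fragments the skeleton splitter produced. The literature names
these metrics without fixing formulas; the definitions below are the
canonical tortuosity-literature ones and are normative for this package.

For a segment with ordered raster path p_0 … p_{N-1}:

* chord C = |p_{N-1} − p_0|; arc L = Σ |p_{i+1} − p_i| (1 or √2 per step).
* DM = L / C. For closed paths (C ≈ 0) C is replaced by ε = 1e−6 and the
  segment flagged `degenerate_chord` rather than dividing by zero.
* ICM = (n_inflections + 1) · DM with inflections counted as sign
  alternations of the smoothed signed curvature; the +1 makes a zero-
  inflection curve reduce to DM instead of annihilating it.
* ICMb replaces the count with the number of positions where consecutive
  unit Frenet normals differ by squared distance > 1 (a flip larger than
  60°, the classical criterion; through flat stretches the last nonzero
  curvature sign is carried forward).
* SOAM = Σ |Δθ_i| / L in rad/px (degrees are a display option, not a math
  change); NC = Σ |κ_i| ds_i / L; SDAC = std(|κ|).
* CL is the polyline length of the smoothed sub-pixel centerline, kept
  distinct from the raw chain-code L so both "arc" and "centerline" are
  well-defined and non-identical.

Arc vs CL matters: chain-code length on 8-connected digital curves is
biased upward — about +5% averaged over directions, up to +8% for stretches
sloping near 22.5° — so DM inherits that bias, while CL (measured on the
smoothed spline) is within ~2–3% of the true length. Both are reported; the
ratios largely cancel the bias because artery and vein segments share the
same rasterization.

## Curvature estimation

Raw skeleton paths turn only in multiples of 45°, so tangents differentiated
from them are digitization noise. The smoothing chain is:

1. truncated moving average of the coordinates (odd window, default 5 px,
   endpoints retained; `window=1` disables all smoothing);
2. cubic smoothing spline parameterized by cumulative arc length, with
   residual budget s = 0.5·N px² (N = path length) — i.e. an assumed
   digitization noise of ~0.7 px — evaluated at 1 px spacing;
3. tangents from consecutive differences; signed curvature = turning angle
   between consecutive tangents / local mean step.

The spline stage was added because a moving average alone cannot serve both
small radii (over-smoothing kills curvature at r ≈ 30 px) and large radii
(residual jitter at r ≈ 100 px doubles SOAM); with it, SOAM and mean |κ|
land within ~2% of 1/r across r = 30–100 px. All differential quantities
are computed in a local frame anchored at the path's first pixel, which
makes the metrics exactly translation-invariant (spline numerics are not,
otherwise) — shifted copies of a curve give bit-identical metrics, so
mirror-symmetric artery/vein scenes give ratios of exactly 1. Exactly
collinear paths bypass the spline entirely and report identically zero
curvature, turning and inflections.

Inflection counting collapses near-zero curvature runs (below 5% of the
peak smoothed |κ|, with an absolute floor of 1e−9) before counting sign
alternations, so straight interludes between bends contribute no spurious
inflections. Segments shorter than 5 px cannot support curvature
estimation; they keep chord/arc/DM, are flagged `too_short`, and are
excluded from image-level means.

## Optic disc and ROIs

The disc is found as the largest bright connected component after
thresholding the luminance image at a brightness quantile (default 0.995)
and opening with a 5 px disc element; center = centroid, radius =
sqrt(area/π). The quantile adapts to exposure but assumes the disc occupies
more than (1 − quantile) of the frame and is the brightest large structure;
images violating that (severe pathology, over-exposure) use the manual
override, which is honored everywhere downstream. Ring ROIs use the
half-open annulus [a·R, b·R) on Euclidean distance, so adjacent rings
sharing a radius partition without double counting; vessels crossing the
rim are truncated at the last inside pixel (keeping whole intersecting
segments is a configuration switch deliberately not defaulted, as
truncation matches the visual "ring cut").

## Skeleton processing

Thinning uses Guo–Hall (`skimage.morphology.thin`), chosen over the default
skeletonization because its centerlines carry less zig-zag (chain-code bias
~5% vs ~6–7% on circle phantoms). Spur removal walks from each endpoint
(pixel with exactly one 8-neighbor) and deletes the twig if it attaches to
a junction with arc length < `min_spur` (default 10 px at the ~2000 px
image scale; configurable). The attachment pixel itself joins the twig when
its remaining neighbors are mutually 8-connected — removing it then cannot
disconnect the main structure — otherwise it is a true junction center and
stays. The sweep iterates to a fixpoint. Branch points are pixels with ≥ 3
skeleton neighbors; thinning emits 2×2 clusters of them at crossings, so
clusters are collapsed to their most central pixel for reporting while the
full cluster is removed when splitting into segments. Segments whose both
ends touch branch pixels and whose arc is ≤ `max_junction_len` (default
5 px) are junction debris ("L-shaped artifacts") and are pruned. Segment
class is the pixel-majority vote; ties and crossing-dominated fragments
become *unknown* and never enter either class mean.

## Statistics

Summary statistics per metric and class use ddof = 1 (std reported as 0 for
a single segment). A ring with zero usable segments of either class yields
flagged-missing ratios, never NaN propagation or division errors — small
2–3 ROD rings legitimately lack one class. Segment-wise ratio features
divide each segment's metric by the image-level mean of the opposite class,
the only construction whose class-wise mean reproduces the image-level
ratio algebraically.

Eye comparison reports per metric: difference (right − left), log-ratio,
and the bounded asymmetry index |r − l| / ((r + l)/2) ∈ [0, 2]. The cohort
test is the paired Wilcoxon signed-rank on left vs right with zero
differences dropped; it is nonparametric because the ratio features are
right-skewed. Calibration measured by simulation: type-I error at α = 0.05
is within [0.03, 0.07] over 1000 null cohorts of 30 pairs. No multiple-
testing correction is applied across the nine metrics; raw p-values are
reported per metric.

## Synthetic phantoms

The generator renders a bright disc (intensity 235 on background 20) plus
vessel curves drawn from parametric forms (line, circular arc, sine, cubic
Bézier) at a given stroke width (default 3 px, typical of thin retinal
vessels at fundus resolution). Ground truth per curve — chord, arc by dense
numeric integration at 10⁴ samples, interior inflection count, total
turning, mean |κ| — is computed from the parametric form and never touches
pipeline code, so it is a genuinely independent oracle. Rendering is
deterministic per seed; anti-aliasing is off by default so palette decoding
is exact (anti-aliased rasters exercise the palette's per-channel
tolerance, default 30). Pixels painted by both classes become *unknown*
(crossings belong to neither class).

`sample_population` draws cohorts: per scene 5–15 artery and 5–15 vein
curves in disjoint horizontal bands (no crossings, none under the disc),
along-axis lengths LogNormal(log 120, 0.25) clipped to [40, 220] px on a
640² canvas, sine amplitudes 2–5 px — gentle, vessel-like undulation —
scaled by `tortuosity_level`, artery lengths multiplied by `artery_scale`.
The defaults emulate a balanced, healthy-like vasculature where every AVLR
ratio should approach 1; `artery_scale` ≠ 1 emulates asymmetric elongation.

What the phantoms do *not* emulate: fundus texture and illumination
gradients, vessel caliber variation and central light reflex, true branching
trees (cohort curves are disjoint by design; junction behavior is tested on
dedicated Y/+/crossing phantoms), label noise from an imperfect
artery/vein classifier, and pathology. Passing tests therefore demonstrate
correctness of the geometry pipeline and the ratio statistics, not
robustness to segmentation errors in clinical images.

## Problem sizes and numerical choices

The validation suite uses semicircle radii 30–100 px, sines of 1–3 periods
(amplitude 20, wavelength 100), 30-image cohorts per scale factor on 640²
canvases, 50 disc placements on 400² canvases, and 1000 simulated cohorts
for test calibration — sizes at which every quantity's sampling error is
well below the tolerance it is checked against. Key tolerances, all
measured on phantoms: chain-code arc within 6% of truth (direction-averaged
bias ~5%), smoothed centerline within 3%, SOAM/mean-curvature within 10% of
1/r, cohort median ratio recovery within 10% of the imposed scale.

## Known limitations

* Chain-code bias makes raw `arc` and `dm` systematically high by ~5%; use
  `cl`-based quantities when absolute lengths matter. The ratios are far
  less affected because the bias cancels between classes.
* The quantile-threshold disc detector assumes the disc is the brightest
  large structure; bright exudates larger than the disc would defeat it
  (use the manual override).
* A 1-px protrusion on a line has three neighbors and is junction debris
  rather than an endpoint twig; it survives spur removal and is left to the
  junction-artifact pruner.
* Inflection counts on nearly-straight noisy segments are sensitive to the
  5%-of-peak zero floor; counts are reliable for clearly curved vessels.
* No vessel caliber measurement: the width-ratio biomarker (AVR) is out of
  scope by design.
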