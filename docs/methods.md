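# Methods

This note documents the models, conventions, parameters and known
limitations of `fundusgeom`.  Conventions throughout: pixel centers,
origin top-left, x rightward, y downward, 0-based; positions `(x, y)`;
lengths in px (images) or mm (MRI), pressures in mmHg, angles in
degrees; all contours closed.

## Synthetic fundus scenes

`synthgen.generate_vessel_tree` grows `n_roots` binary trees outward
from the rim of a bright optic disc at the image center.  Segments are
straight; at each bifurcation the inter-daughter angle is drawn
uniformly from `angle_range_deg` and the daughter pair is oriented
symmetrically about the local radial direction, which keeps each tree
inside its own azimuthal wedge and makes the recorded angle exact truth
rather than an approximation.  Widths taper geometrically
(`width_taper` per generation, floored at 1 px); whole trees carry one
artery/vein label (vein roots wider by 4/3, matching the venular/
arteriolar caliber ratio of healthy eyes) and labels interleave around
the disc.  A layout is rejected and redrawn (bounded retries) if any two
non-adjacent segments come closer than their half-widths plus 2 px, so
the rendered mask skeletonizes to the true topology — bifurcation-count
recovery is then a meaningful test, not luck.

Rendering strokes each polyline with a circular brush of diameter equal
to the width: the binary mask is the set of pixel centers within
width/2 of the centerline and the image is anti-aliased, so the interior
distance transform recovers the width to sub-pixel accuracy.  Veins are
drawn `av_contrast` intensity units darker than arteries (default 30 on
a 0–255 scale; the brightness cue real analyzers use).  The disc is a
bright ellipse with minor/major aspect drawn from [0.9, 1.0] and random
orientation; its *major* axis equals the nominal DD, so the
smallest-circumscribed-circle definition is exercised nontrivially.  A
dark surround outside a circular camera field (radius 0.47 × image
size) emulates the 45° fundus frame.  Gaussian sensor noise
(default SD 4) is added last.

Defaults (4 roots, depth 2, angles 40–110°, artery root width 8 px,
taper 0.75, DD 80 px, 512² image) describe a disc-centred 45° photograph
at moderate resolution.  The geometry benchmark sweep
(`recovery_sweep_specs`) varies root widths 7–9 px (veins to 12 px,
deepest branches ~4.3 px), DD 60–98 px, angles 40–110°.

What the renderer does **not** emulate: vessel curvature and tortuosity,
central reflex, arteriovenous crossings (trees are disjoint by
construction; the degree-4 exclusion rule is tested on hand-built
masks), pigmentation texture, pathology (hemorrhage, edema), and
illumination falloff.  Passing recovery tests therefore demonstrates
correctness of the geometric measurement chain, not clinical-grade
robustness on photographs.

## Cohort simulation

`synthgen.generate_cohort` draws a paired case-control table: two rows
(affected + contralateral eye) per subject.  Subject-level variables
(age, sex, height, BMI, hypertension duration) are shared within
subject; weight is derived as BMI × height², keeping the three mutually
consistent.  Eye-level variables (IOP, OA and ICA-C6 diameters, ONSASW
at 3/9/15 mm, relative calibers, AVR, eight quadrant angle means) are
drawn independently per eye from the (group × eye-role) cell's
published mean ± SD, as normals truncated at 0 (the physiologic floor;
this shifts only the high-CV CRVO-affected IOP cell appreciably, and
moment tests compare against the truncated expectation).  Hypertension
duration is zero-inflated log-normal — BRVO: P(0) = 0.6,
lognormal(ln 6, 1); CRVO: P(0) = 0.8, lognormal(ln 4, 1) — calibrated
once to the published medians/IQRs (BRVO median 0 with Q3 = 4.5 y, CRVO
IQR degenerate at 0).  Sex is Bernoulli at the published group male
fractions (18/34, 16/25).

Two deliberate simplifications, both documented limitations:

- **AVR is drawn as its own measured column** from its published
  mean ± SD rather than computed as relA/relV per row.  The simulator
  emulates the study's measurement *table*, in which AVR is its own
  summarized row; a ratio of independent normals would not recover the
  published AVR moments.  The identity AVR ≡ relA/relV holds exactly in
  the measurement pipeline, where it is structural.
- **No inter-eye or inter-variable correlation** is modeled (none is
  published).  Eyes are exchangeable within subject apart from the
  affected-eye effect; `effects=False` replaces every affected-eye
  distribution with its contralateral counterpart, giving an exact null
  for calibration tests.

## Image pipeline

*Preprocessing.*  "De-noising" is a 3×3 median filter plus a light
Gaussian (σ = 0.5).  The ROI is the largest bright connected component
(Otsu threshold), hole-filled; its radius comes from its area.
Intensities inside the ROI are rescaled by the 1st–99th percentile to
[0, 1]; CLAHE (clip 0.01) sharpens edges.  Both the enhanced and the
merely normalized image are kept: adaptive equalization flattens exactly
the global artery/vein brightness contrast, so A/V discrimination and
disc detection read the normalized image while segmentation reads the
enhanced one.  Constant images pass through with the full frame as ROI.

*Segmentation.*  Backends are a registry; learned models plug in
without touching the pipeline, and a `truth` backend passes a supplied
mask through for testing.  The shipped baseline is multiscale Sato
vesselness (dark ridges, σ ∈ {1, 2, 3}) normalized to its ROI maximum,
hysteresis-thresholded at (0.2, 0.4), confined to an ROI eroded by 8 px
(the field border is itself a strong ridge) and cleaned of objects
under 40 px.  Because percentile normalization would stretch pure
sensor noise into ridge-like structure on a vessel-free image, the
backend returns an empty mask when the raw ROI dynamic range is below
0.1 (noise level); with vessels present the range is ~5× that.
Hysteresis is monotone in both cuts, so lowering thresholds never
shrinks the mask.

*A/V discrimination.*  Each centerline edge gets a median normalized
intensity; each connected tree is classified as a whole (so one tree
gets one label, the topological-consistency rule), by a deterministic
1-D two-means split of tree medians; the darker cluster is "vein"
(configurable inversion flag).  Vessel pixels inherit the label of the
nearest centerline pixel.

*Optic disc.*  Localization: brightest compact blob of the heavily
smoothed (σ = 8) normalized image inside the eroded ROI, with a radius
estimate from the blob area.  A candidate whose search window touches
the image border raises rather than silently truncating.  The
neighborhood is resampled in polar coordinates (1° angular, 0.5 px
radial resolution) and Canny edges (σ = 2) of the polar image are
filtered to falling (bright→dark) radial gradients.  Per-angle edge
selection is two-pass: the strongest edge per ray gives a robust median
rim radius; the final radius per ray is the *outermost* falling edge
within [0.75, 1.3] of that median (rays that run along a vessel see
extra falling edges far beyond the rim, which a single outermost-edge
rule would chase).  Gaps are circularly interpolated and a 7-wide
circular median filter removes isolated vessel-entry spikes before the
max-sensitive final step: DD and the disc center are the diameter and
center of the smallest enclosing circle (Welzl's algorithm,
deterministic seeded point order) of the unwrapped contour.  On the
benchmark sweep this recovers DD within 1.4% worst-case.

## Geometry

*Centerline.*  Topology-preserving thinning (`skimage.skeletonize`); a
plain morphological erosion would disconnect the skeleton, and the
branching-angle analysis needs the connected graph.  The skeleton is
traced into a multigraph: node sites are pixels whose 8-neighbor count
differs from 2, adjacent node pixels merge into one node, chains of
degree-2 pixels become edges.  Cleaning: tiny self-loops and short
parallel duplicate edges (< max(3·spur_len, 8) px — skeleton "bubbles"
at junctions) are removed; terminal spurs shorter than `spur_len`
(default 5 px) hanging off junctions are pruned; pass-through nodes are
fused.  Isolated short segments with both ends free are kept — they are
small vessels, not artifacts.

*Diameters.*  Tangents from centered differences over ±3 chain pixels;
the diameter at a point is the orthogonal chord length, with the two
boundary crossings located to sub-pixel precision by bilinear
interpolation of the mask at 0.25 px steps (0.5 level).  Points within
2 px (arc length) of a junction and 3 px of any chain end are excluded
— junction blobs and rounded tips bias the chord; chords that fail to
cross the boundary (mask edge) are skipped and tallied.  Mean absolute
width error on the benchmark is ~0.24 px.

*Calibers.*  Points are kept when their distance from the disc center
is within [1.0, 1.5] DD — the zone read literally as measured from the
disc *center*; much caliber literature measures 0.5–1.0 DD from the
disc *margin*, which coincides for DD-sized discs, and a
`zone_from_margin` flag provides the alternative.  Per vessel, the
retained run is split into 10 equal-arc sections; section means are
pooled per class with equal weight (the aggregation level is otherwise
unspecified in the source conventions).  relA = meanA/DD,
relV = meanV/DD, AVR = meanA/meanV ≡ relA/relV.  A missing class flags
the summary incomplete and leaves AVR undefined.  One reading note: the
phrase "arteriolar-to-venular diameter ratio … divided by the disc
diameter" conflates two quantities; the only reading consistent with
the published magnitudes (relA ≈ 0.06, relV ≈ 0.08, AVR ≈ 0.75) is the
one implemented, and the package flags rather than silently assumes it.

*Angles.*  Bifurcations are degree-3 nodes; degree-≥4 nodes
(arteriovenous crossings) are excluded and tallied separately.  The
parent is the incident edge with the largest mean measured diameter
(tie-break: longer chain).  Daughter directions are least-squares line
fits over chain pixels from arc length 4 px (skipping the junction
blob, where the skeleton bends toward the bisector) to 4 + 16 px from
the node; shorter daughters use their full chain and are flagged.  Mean
absolute angle error on the benchmark is ~0.9°, worst case ~3.5°.
Quadrants: image-up = superior; nasal = image-right for OD, mirrored
for OS; ties resolve superior/nasal; the disc center itself raises.
Eye-level per-quadrant values are means over that quadrant's
bifurcations.

## ONSASW / TLCPD

ONSASW = (mean of ONSD axes − mean of OND axes)/2; by linearity this
equals the per-axis half-differences averaged, so observer averaging
order is immaterial.  Valid stations are exactly 3, 9, 15 mm
retrobulbar; a sheath narrower than its nerve is rejected per axis.
TLCPD = IOP − CSFP, possibly negative.  CSFP is an *input*: the
estimation regression sometimes used to derive it from systemic
variables is cited but not given in the source, so the package does not
invent it.

## Statistics

Test routing mirrors SPSS practice: Shapiro–Wilk for n < 50 and a
Lilliefors-corrected Kolmogorov–Smirnov test otherwise decide
normality (both samples must pass); Levene's test (mean-centered, the
SPSS default) decides pooled-t vs Welch.  Independent nonparametric
comparisons use Mann–Whitney U (exact for small untied samples,
tie-corrected normal approximation otherwise — scipy's `auto`); paired
designs gate on the normality of differences into paired t vs Wilcoxon
signed-rank.  The 2×2 chi-square is the *uncorrected* Pearson statistic
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)): on the published sex table
(18,16;16,9) the uncorrected statistic reproduces the printed 0.722
where the Yates-corrected value (0.340) does not.  Two-sided α = 0.05
everywhere, no multiplicity correction, matching the workflow being
reproduced.

Logistic models are maximum-likelihood (Newton/IRLS, tol 1e-8, max 100
iterations) with Wald 95% CIs; OR = exp(coef).  Perfect separation is
detected per covariate and raised by name; non-convergence raises with
the iteration count; listwise deletion is counted and reported.  In the
assembled report each imaging marker enters its own model together with
the adjusters (age, hypertension duration, BMI, IOP for the
CRVO-vs-BRVO model; IOP for the affected-vs-fellow model) — the source
does not state whether markers entered jointly, and per-marker models
avoid collinearity among correlated calibers.  Marker ORs are per SD of
the marker: relative calibers live on a ~0.01 scale where per-unit odds
ratios overflow any useful range.  The analysis unit is the eye with
within-subject clustering ignored, as in the reproduced workflow; a
`cluster_robust` option provides a subject-clustered sandwich variance.

A calibration note: a full report runs ~70 hypothesis tests, so even on
a perfect null cohort about 3–4 false positives per run are expected at
α = 0.05.  Null-cohort tests therefore check the false-positive *rate*
against its binomial band, not the absence of any significant result.

## Problem sizes and numerical choices

The test suite and acceptance script use: 20 benchmark images (512²) for
geometry recovery; 5000/2000 null replicates for two-sample/ANOVA
calibration; n = 5000 for logistic recovery; 10⁴ subjects per group for
cohort moments; 200 per group for the end-to-end contrast — sizes at
which every stochastic check has comfortable margin while the whole
suite runs in about a minute.  Determinism: a single seed fans out to
per-stage substreams keyed by stable stage names (CRC32), so stage
order never perturbs another stage's draws; Welzl's point shuffle and
the two-means initialization are fixed, making every geometric output
bit-reproducible.

## Known limitations

- Straight-segment vasculature: tortuosity-dependent biases of the
  chord diameter estimator are untested.
- The classical ridge baseline is tuned to the renderer's contrast
  regime (Dice ≈ 0.86 there); real photographs need a learned backend
  plugged into the registry.
- Cohort columns are independent; any analysis exploiting covariance
  (e.g. multivariate adjustment benefits) sees an idealized world.
- The disc detector assumes one bright disc well inside the field;
  myopic crescents, peripapillary atrophy and disc-edge pathology are
  out of scope.
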