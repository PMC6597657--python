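# Methods

This note records the models, conventions and numerical choices behind
octmorph, and what the synthetic validation does and does not establish.

## Coordinate and unit conventions

Rows are axial with anterior at smaller row index; axial positions are
micrometres measured posteriorly from the image top. A-scan `j` is centred
at `(j + 0.5) · lateral_pitch`. Default pixel pitches are 3.9 µm axially
and 20 µm laterally (600 A-scans across a 12 mm scan). Lateral distances
convert to degrees of visual angle linearly at 292 µm/°, the model-eye
small-angle factor; this is deliberate, because axial-length calibration
is unreliable in developing or buphthalmic eyes. The cup, rim and pit
areas are consequently mixed-unit (degree · micrometre): lateral degrees
times axial micrometres. All of these are configurable through `ScanMeta`
and the measurement configs.

## The B-scan simulator

Scans are rendered as piecewise-constant reflectivity per layer with
exact axial partial-volume integration (a pixel crossed by a boundary
gets the coverage-weighted mixture), so sub-pixel boundary positions
survive pixelisation and the noise-free limit is exactly segmentable —
the design criterion for the reflectivity model. Noise is mean-one
gamma-distributed multiplicative speckle (dispersion 0.5 by default),
additive Gaussian background noise (SD 0.02) and Gaussian point-spread
blur (1 px), applied in that order from a single integer seed; identical
configuration and seed give byte-identical images.

**Disc scans.** Bruch's membrane is a flat band terminating at the two
disc edges (fractional lateral coverage in the edge column keeps the
termination sub-pixel-accurate). The ILM lies `rim_height` (default
120 µm) anterior to the offset plane at the rim, descends through a
parabolic (or cosine) cup of the requested diameter and depth — the cup
diameter is realised exactly at the offset plane, the depth exactly below
it — and climbs a linear shoulder between cup edge and rim. A bright
nerve-fibre band of per-side thickness rides under the ILM outside the
disc. Scan height adapts to the geometry; width covers the disc plus 7°
on each side.

**Fovea scans.** Per-layer thickness profiles are piecewise linear in
eccentricity through knots at 0°, 1° and 2°, constant beyond, chosen so
the zone summaries reproduce their inputs exactly: the value at 0° is the
`central` input, the [0,1]° mean equals the `paracentral` input, and the
[2,6]° plateau equals the `nasal`/`temporal` input. The pit rim is a
smooth parabolic-cap bump on the ganglion-cell complex at ± half the pit
width; its amplitude is solved so the rim peak sits exactly `pit_depth`
above the central ILM point after the whole 2–6° plateau is lowered by
the bump's in-zone mean (keeping the zone-mean thickness exact without
step edges, which lateral filters would smear). This couples feasibility:
the pit depth must at least equal the central-to-peripheral thickness
difference (~82 µm at the defaults) and at most ~190 µm before the
plateau compensation would exhaust the ganglion-cell layer; the generator
raises outside that range. A `pit_depth` of zero therefore requires
near-uniform layer profiles, which produce a flat inner surface; the pit
measurer reports that degenerate case as zero depth and area with a
`flat_pit` flag (see below). Default layer thicknesses are typical of a
young child's macula; the ELM is an 8 µm band at 55% depth of the ONL+IS
slab with reflectivity `elm_contrast` (default 2.0) times its
surroundings, rendered only when present. Optional BM tilt and sinusoidal
warp exercise the flattening stage.

## The cohort sampler

Per-eye parameters are drawn as independent truncated normals at the
published per-group means ± SD (rejection sampling within physical
bounds; e.g. CDR in [0,1]). Two eyes of a participant are coupled through
a Gaussian copula with correlation 0.6 — a typical inter-eye correlation
for ocular biometry — which leaves the marginals untouched but gives the
mixed model a real clustering structure to estimate. A configurable
fraction of case participants is unilateral (default 0.65): the affected
eye draws from the case distribution, the fellow eye from the control
distribution. With 20 case participants this yields 27 affected eyes, the
denominator the published sensitivities imply. Diagnostic analyses use
one eye per control participant by default (20 control eyes, matching the
published specificity denominators); both-eye analysis is available.

Two deliberate simplifications: the cup-to-disc-diameter constraint is
*not* enforced during sampling (enforcing it would bias the cup-diameter
marginal away from the published summary; it is clamped only when a
cohort row is turned into a renderable geometry), and the CDR is sampled
as its own marginal rather than derived as cup/disc (the derived ratio
would have SD ≈ 0.25, contradicting the published 0.173). Cohort rows are
therefore marginally faithful but not jointly consistent across
parameters — adequate for the per-parameter analyses performed here, and
the reason image-level pipelines derive the rim height from the sampled
rim area and width.

## Segmentation

All detectors are per-A-scan gradient detectors with ordered constrained
search. Sub-pixel localisation uses parabolic interpolation of the
gradient extremum, which is exact for a partial-volume step; the ILM uses
a mid-level crossing on the vitreous side instead, because the posterior
edge of a very thin nerve-fibre band (≈1.5 px at the foveal centre)
contaminates the gradient parabola. Noise handling is adaptive: axial
Gaussian smoothing (σ 0.8 px) and lateral curve despiking switch on only
when the image's high-frequency noise estimate exceeds a small floor, so
clean scans are analysed unfiltered. Lateral smoothing is applied to
*curves*, never to the image around sloped boundaries (an image-space
median mixes a thin sloped band into its surroundings), and despiking
replaces a sample by the rolling median only when it deviates by more
than 10 µm — a plain rolling median would clip the genuine extrema at the
pit vertex and rim apex. Short per-curve gaps are bridged from the local
median; long gaps stay missing, and downstream operators check their own
coverage rather than interpolating silently.

On disc scans, the RPE/BM band is located from the column-median depth
profile; band strength is the mean over the band rows, a column carries
the band where its strength exceeds the floor plus half the
flank-to-floor contrast, and the floor (the prelaminar-tissue level, a
90th percentile of the opening) and the opening extent are iterated to a
fixpoint because a deep cup drags the opening's median to the vitreous
level. Edges are interpolated sub-pixel on the unfiltered strength
profile. Fovea scans are segmented in two passes: anchors first (ILM, the
strong outer-retinal fall, the strong ONL/IS–OS/RPE rise), then interior
interfaces as the strongest correct-sign gradient extremum in the ordered
window (the two ganglion-complex/inner-nuclear rises are taken as the two
strongest and assigned anatomically, with plateau ties merged); a second
pass median-smooths each interior boundary's depth relative to the outer
anchor and re-localises within ±9 µm of that prediction, using laterally
averaged gradients for the laterally flat deep interfaces. Ordering is
re-imposed after smoothing and finally asserted.

ELM detectability resamples the ONL+IS slab of every column to a common
fractional-depth axis, averages across columns, and scores the profile
peak over its median; detection threshold 1.2 (a contrast ratio; 1.0
means no band). Slabs thinner than 3 px are flagged indeterminate.

## Measurement conventions

Cup depth is the perpendicular distance from the segment joining the two
rim edges (the outermost sub-pixel ILM–offset-plane intersections inside
the disc — the outermost-crossing rule maximises the cup diameter when
the ILM crosses the plane more than twice). Crossings extrapolate the
cup-side branch of the ILM where it meets the rim, because interpolating
across the wall/rim slope kink biases the cup diameter outward by up to a
pixel. If the ILM never crosses the plane, the cup metrics are zero, the
result is flagged `no_cup`, and the whole disc counts as rim. RNFL is
sampled by default at 6° from the disc centre; sampling from the disc
margins is available (`rnfl_from="margin"`) since both conventions appear
in the field. The 150 µm plane offset is configurable.

Pit metrics are measured on the flattened scan (all curves re-expressed
relative to a straightened BM). Rims are the global per-side ILM
elevation maxima, plateau ties broken toward the pit (deterministic and
conservative), with a 9-point quadratic apex refinement because despiked
curves slightly flatten the apex; depth is the axial chord-to-ILM
distance at the deepest point (parabolic sub-pixel); the pit centre is
the single A-scan at the ILM minimum, sub-pixel by parabolic fit. A flat
inner surface raises "no pit rims found" from `measure_pit`; the
`measure_fovea` assembler converts that degenerate into zero depth and
area with a `flat_pit` flag so cohort pipelines keep running.

## Statistics

Each parameter is compared with a linear mixed model — outcome ~ group +
eye + age, random intercept per participant, REML — and the group effect
reported as the squared Wald t against F(1, m) with containment
denominator degrees of freedom m = participants − 3 (the between-
participant design columns), a reproducible and conventional choice since
no software default is canonical. Singular fits fall back to OLS and are
flagged. A Welch t-test on participant means is provided as the simpler
alternative path some summary tables use. Bonferroni m defaults to the
family size (9 for the optic-nerve family), configurable. Percent-of-
control is 100 · value / control-group mean per eye; by linearity the
mean of per-eye percentages equals the percentage of means, which is how
the published group-level percentages (165%, 159%, 36.4%, 87%) are
reproduced exactly from the summary statistics.

Diagnostic accuracy uses the eye as the unit of analysis (27 affected /
20 control eyes), ties at a threshold counting as test-positive for ≥
rules. All four rates carry exact Clopper–Pearson 95% intervals
(beta-quantile construction). Clopper–Pearson was chosen because it
uniquely reproduces the published sensitivity/specificity intervals
(e.g. 17/20 → 62.1–96.8); two published anomalies are noted rather than
corrected: a sensitivity lower bound printed as 61.2 where 22/27 gives
61.9, and an upper bound printed as 97.7 where 24/27 gives 97.65. The
published predictive-value intervals match neither Clopper–Pearson nor
Wilson; this package reports Clopper–Pearson throughout. Youden-optimal
thresholds search the midpoints between consecutive distinct observed
values (plus optional user candidates), ties broken toward higher
specificity and then toward the rounder value.

`counts_from_rates` recovers confusion counts from printed rates by
exhaustive enumeration of shared denominators — the smallest n for which
every rate equals a rounded x/n for exactly one x — and errors on
ambiguity. The published sensitivities force n = 27 and the
specificities n = 20.

## Problem sizes and tolerances

Noise-free recovery is asserted to one pixel-equivalent per parameter
(0.0685° laterally, 3.9 µm axially; areas to one axial pixel over their
lateral extent). Area measurements are cross-checked against a
brute-force pixel-count oracle (1 µm × 0.005° cells, < 1% relative
difference on randomised geometries); the exact intervals against
numeric test inversion for every (x, n ≤ 30) to < 0.05 percentage
points; threshold search against exhaustive search on 50 random cohorts.
Monte-Carlo segmentation checks use 8–20 seeded scans per condition with
mean absolute boundary error thresholds of 2 px. The statistical
simulations use 500 null replicates (size), 200 effect replicates at
n = 20/20 (power at p < 0.001), and 200 replicates of 2000 + 2000
participants for the threshold-selection distribution, whose population
optimum for the published cup-depth distributions lies at ≈ 632 µm
(the equal-density point), comfortably bracketing the published 600 µm
cutoff.

## Limitations

The simulator emulates layer geometry and first-order OCT image
statistics, not real tissue: no vessels or vessel shadows at the disc, no
motion or corneal-oedema artefacts beyond global blur/contrast loss, no
retinal curvature beyond the optional BM tilt/warp, no volumetric (3-D)
scans, and piecewise-constant reflectivity rather than realistic texture.
Passing tests therefore establish the correctness of the geometry,
statistics and detection logic under the stated image model — not
segmentation validity on real hand-held OCT exports, which are out of
scope. Layers thinner than ~2 axial pixels are at the resolution limit:
a zero-thickness layer between two same-sign edges is not identifiable by
the ordered search, which is why default central thicknesses are kept
strictly positive. Cohort rows are marginally faithful but not jointly
consistent across parameters, and the published per-eye raw data are not
available, so the study's exact F statistics and p-values are covered by
distribution-level simulation rather than numeric reproduction.
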