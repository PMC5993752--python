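# Methods

This note documents the models, parameter choices and numerical decisions
behind `fundusqa`, in the spirit of a package's own methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Contact-free trans-pars-planar/trans-scleral illumination frees the whole
pupil for imaging and gives wide-field fundus photographs without
pharmacologic dilation, at the cost of strongly red-dominated images (long
wavelengths penetrate sclera and choroid far better). Quantitative use of
such images needs: channel balancing for visualisation, vessel
segmentation from the green channel, artery/vein separation, and the
clinical summary metrics (diameter, tortuosity, arteriolar-to-venular
ratio). Because no pixel-level truth exists for real fundus photographs,
the package ships a synthetic scene generator whose every vessel has known
geometry; all recovery claims in the test suite are claims about these
phantoms, not about clinical images.

## Synthetic scene generator

**Geometry.** `n_primary_vessels` (default 6) polylines radiate from a
disc-like origin at (0.38, 0.5) of the field, alternating artery/vein so
both classes are always present. Each centerline is a straight ray plus a
lateral sinusoid of amplitude `tortuosity_amplitude × wavelength`
(default 0.07, jittered ±30% per vessel) completing 2–3 full periods, with
a smoothstep amplitude ramp over the first wavelength so vessels emerge
radially from the disc and meander only peripherally (radial emergence is
also what keeps the six primaries from crossing right at the origin).
Because the sinusoid completes integer periods, the chord coincides with
the ray and the arc/chord tortuosity is controlled analytically; the
recorded true value is a dense (8193-point) numeric arc-length evaluation.
Default tortuosities land around 1.02–1.05, within the range reported for
healthy retinal vessels.

**Calibres.** Artery diameters are drawn uniformly from 150–180 µm and
veins from 200–240 µm. The ranges are deliberately disjoint (the anatomical
rule that an artery is narrower than its accompanying vein is what the
classifier's width refinement exploits) and bracket commonly reported
first-order vessel calibres; their means give a true AVR near 0.75, inside
the normal 0.54–0.82 range.

**Rendering.** Default raster 512×512 at 16 µm/pixel (an 8.2 mm field), so
vessel widths span ~9–15 px — matched to the default filter-scale ladder
below. Background RGB means (120, 30, 8) reproduce the red:green ≈ 4 and
red:blue ≈ 16 ratios of trans-scleral illumination. Vessels are *darker*
than background in both red and green — as in real fundus images, where
blood absorbs — with artery (60, 20, 6) and vein (70, 14, 5), chosen so the
artery ODR (2.0) sits well below the vein ODR (4.0). Vessels are drawn
with anti-aliased edges (linear coverage over one pixel, via a Euclidean
distance transform of the densely resampled centerline); the ground-truth
mask marks pixels with ≥50% coverage so mask width equals true width.
Illumination inhomogeneity is a multiplicative cosine bump
`1 + a·cos(πu)cos(πv)` (default amplitude 0.2) and sensor noise is
additive Gaussian (default sd 2 on the 8-bit scale), clipped to range.
Everything is driven by explicit seeds; identical specs give bit-identical
images and truth.

**What the phantom does not emulate:** optic disc and macula texture,
choroidal vasculature, vessel branching hierarchies, central light reflex
on vessels, spatially correlated sensor noise. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration on
idealised vasculature, not clinical-grade performance.

## Segmentation chain

**Kernel bank.** `build_kernel_bank` constructs zero-mean line detectors:
Gaussian cross-profile `exp(-v²/2σ²)` truncated at 3σ, constant along a
support of length `6σ` (rounded to odd pixels), rotated to
`θ_i = i·180°/12`, mean-subtracted over the support. 12 orientations × 10
scales = 120 kernels. The σ ladder is geometric from 1.5 to 9.0 px,
spanning vessel widths of roughly 3–18 px — i.e. 50–290 µm at the default
pixel pitch; it should be rescaled (`sigmas=` argument) when the pitch
differs. Each kernel is normalised by its positive mass, which makes the
response read as a local average contrast: a vessel matched in scale and
orientation responds with approximately its own contrast, keeping the
maximum projection comparable across scales.

**Polarity.** Vessels are dark in the green channel, so the channel is
negated before filtering; with zero-mean kernels, negation is exactly
equivalent to inversion about any constant level.

**Convolution.** Reflective boundary handling; FFT-based convolution for
images larger than 64 px a side, direct spatial convolution below (and on
request) — the two agree to rounding error, which the test suite checks
against a brute-force nested-loop oracle.

**Illumination correction.** White top-hat with a disc of radius 27 px
(≈3× the largest σ): response minus its morphological opening, guaranteed
non-negative, removing any background structure wider than the disc.

**Thresholding and width refinement.** A global Otsu threshold (or a fixed
value, recorded in provenance either way) detects vessels reliably, but a
single global cut sits at a different fraction of each vessel's response
crest, clipping weak-contrast vessels narrower than strong ones. The mask
is therefore re-cut at half the local response crest (the maximum within a
31 px window — full width at half maximum), keeping only half-crest pixels
connected to the detection mask via binary reconstruction so nothing
appears away from detected vessels. Components below 64 px are removed and
pinholes below 64 px filled (a hole would punch a loop into the skeleton).
The refinement is switchable (`refine_extent=False` recovers the plain
global-threshold mask, which still meets the Dice target on default
scenes).

## Artery/vein classification

ODR = (R − G)/max(G, g_floor) on vessel pixels, with `g_floor = 1`
intensity unit as a division guard. The mask is skeletonised; dangling
skeleton twigs shorter than 15 px are pruned (boundary bumps otherwise
split one vessel at a spurious junction); branch points (≥3 skeleton
neighbours) are deleted; remaining connected paths of arc length ≥ 30 px
become segments with ordered centerlines.

Classification is per segment (whole vessels are uniformly coloured in
clinical practice): the threshold over segment-mean ODRs is an exact
small-sample 2-class Otsu (exhaustive split maximising between-class
variance — histogram Otsu needs more samples than a scene yields), or a
fixed value. Below threshold → artery, above → vein. Degenerate inputs
(<2 segments, identical means) leave labels "unknown" with a warning. The
optional refinement pass relabels spatially adjacent (<40 px), roughly
parallel (<30°) same-label pairs whose means lie within 0.15 of the
threshold by the width rule: narrower → artery, wider → vein. "Accompanying"
is operationalised as this adjacency + parallelism test; no other pairing
definition is standard.

## Metrics

**Diameter.** Euclidean distance transform of the vessel mask sampled
along the centerline. Each sample is snapped to the distance-transform
ridge (maximum within a 5 px window) because a skeleton centerline can sit
a pixel off the true axis, and the end-cap taper (≈1 vessel radius per
tip) is trimmed when the segment affords it. Local width is `2·EDT − 1` px
(pixel-centre correction, exact on an odd-width bar) times the pixel
pitch. This measures the *mask*, so its accuracy is bounded by
segmentation width fidelity; published diameters are treated as a worked
example of the AVR arithmetic, not of this estimator.

**Tortuosity.** Arc/chord of the centerline, ≥1 by the triangle
inequality. Raw 8-connected pixel chains systematically overestimate arc
length (staircase effect), so the metric is evaluated on a smoothed copy:
7-px moving-average of coordinates, subsampled every 3rd point, endpoints
kept so the chord is unchanged. The smoothing window is far below any
plausible meander wavelength at this scale.

**AVR.** Unweighted per-class means of segment diameters (length-weighted
means are a config option), ratio artery/vein, reported additionally at
the conventional 1-decimal precision. Requires at least one segment of
each class; otherwise an error names the missing class.

## Light safety

All quantities are *pre-weighted* by the standard photochemical/thermal
hazard spectral functions — the weighting tables themselves are not
implemented; inputs are taken exactly as a safety analysis reports them.
Defaults: 0.5 mW weighted power, scleral transmission 30% (the
conservative top of the 10–30% literature range, kept as metadata),
13 mm² illuminated area, 10 J/cm² photochemical limit, 700 mW/cm² thermal
limit, 9 mm² retinal area for the accidental trans-pupillary path.
`photochemical_tmax` = limit / (power × transmission / area) with explicit
mW→W and mm²→cm² conversions (defaults give 2.4 h); `pupil_tmax` drops the
transmission factor and is monotone increasing in area, so the 9 mm² lower
bound certifies a 30-minute lower bound. The thermal check returns
pass/fail plus the margin ratio. The printed 230 mW/cm² scleral intensity
is treated as a direct input, never recomputed from other quantities. The
eye/external FOV angle ratio (1.5) is calibrated from published printed
pairs (45°→67.5°, 60°→90°), not asserted as anatomy.

## Pipeline, configuration, reproducibility

`PipelineConfig` holds every stage parameter and round-trips losslessly
through YAML; `analyze` records all thresholds actually used (including
the data-driven Otsu values) in the report provenance, making every output
number traceable. Runs are deterministic for a fixed image and config.
A featureless input (constant image) yields a graceful "no-vessels" report
rather than an error. `end_to_end_selftest` simulates a default scene,
analyses it and asserts: Dice ≥ 0.7, label accuracy ≥ 95%, class-mean
diameter recovery within ±10%, tortuosity within ±5%, AVR within ±0.08.
On one CPU the selftest takes a few seconds at the default 512×512 size.

## Known limitations

- Width fidelity inherits the half-crest cut's assumptions; vessels much
  wider than twice the largest σ would be clipped (rescale `sigmas` with
  the pixel pitch).
- Tortuosity values near 1 make *relative* recovery tolerances easy; the
  phantom's meanders (≤1.06) do not probe pathological tortuosity.
- The classifier uses only ODR and width; no optic-disc-rooted graph
  propagation, so label errors on short ambiguous fragments are possible.
- The angle conversion is a fixed-ratio convention; real eye-angle/
  external-angle mappings are weakly nonlinear across instruments.
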