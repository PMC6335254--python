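# Methods

## Measurement model

The package measures **planform area**: the area of an animal's top-view
outline projected onto a horizontal plane. The imaging model is an ideal
pinhole camera at height *D* = 245 cm pointing straight down, principal
axis through the image center, no lens distortion. A plane at height *h*
above the floor is magnified linearly by

    m(h) = D / (D − h),      0 ≤ h < D,

so its projected area scales by m(h)². Area conversion uses a reference
surface of known area *A*ref (default 0.420 m²) photographed at a reference
height; segmenting it yields `pixels_per_m2 = count / A_ref`. Because a
subject whose body plane sits at the same height as the reference shares
the same magnification, the factor cancels and
`area = pixel_count / pixels_per_m2` returns the planform area directly.
A subject at a different height is biased by
`((D − h_ref)/(D − h_obj))²`; the measurement layer treats a
posture/calibration height mismatch as an error in strict mode and a logged
warning otherwise.

A pig's back is of course not a plane. Following the calibration logic of
planimetric practice, each posture class is assigned one representative
height: 69 cm for the ten standing postures, 29 cm for the three lying
postures. The same approximation is used by the synthetic generator, so the
bias it hides is exactly the bias the real method hides; the perspective
tests expose what happens when heights are mismatched rather than
pretending the approximation away.

## Segmentation

Images are reduced to luminance, contrast-stretched linearly so the 1st and
99th intensity percentiles map to the intensity extremes (monotone, hence
rank-preserving), then thresholded. The default threshold is automatic —
Otsu's inter-class-variance maximization — with a fixed-threshold override
for reproducibility studies. After optional removal of excluded pixels
(deterministic masks supplied as images, replacing interactive retouching),
the largest 8-connected component is kept together with any component at
least `min_component_fraction` (default 0.5) of its size, and enclosed
holes are filled (default on: a pig seen from above is simply connected).
Pixels are counted as foreground iff their center lies inside the
segmented region; the synthetic ground-truth rasterizer uses the identical
pixel-center rule, so oracle comparisons are convention-free.

## Synthetic scenes

The generator emulates the study conditions: a high-contrast planimetry
box (bright subject on dark floor), one animal or reference board per
frame, lens at 245 cm, reference board 0.420 m², subject weights spanning
75–133 kg. Silhouettes are parametric simple polygons — a body ellipse
plus posture-dependent head, shoulder-curve and limb extensions, with mild
seeded shape jitter — uniformly scaled so the shoelace area equals

    a = k_g · W^0.66 · (1 + ε),

where `k_g = area_mean_g / weight_mean_g^0.66` is fitted per posture group
from the packaged summary tables, and ε is zero-mean Gaussian with SD
`shape_noise`, truncated at ±3 SD to keep areas positive. A noiseless
silhouette at the group mean weight therefore reproduces the group mean
area *by construction*: the study's measured means are calibration inputs
to the generator, never outputs the pipeline gets credit for recovering.
What the pipeline *is* scored on is recovering each polygon's exact area
from rendered pixels (≤ 1% at ≥ 500 px/m floor sampling), the projection
law, the allometric exponent from noisy cohorts, and the ordering and
separation of posture classes.

Seed protocol: one master seed; per-animal seeds derive from it through a
counter (`master·100003 + i`), so cohorts are reproducible animal-by-animal
and any single animal can be regenerated in isolation.

What the generator does not emulate: fur texture, UV-fluorescence spectra,
lens distortion of a real zoom lens, multi-animal occlusion, or genuinely
3-D body shape. Passing tests therefore demonstrate correctness of the
measurement chain and the comparison arithmetic under the stated imaging
model, not robustness to real-world image degradation beyond the modelled
shadows/contamination blobs.

### Dispersion realism and its floor

Cohort weights default to uniform on [75, 133] kg, the study's span. That
choice has a knowable consequence: uniform weights have CV(W) ≈ 0.161, so
the weight term alone contributes an area CV of about 0.66 × 0.161 ≈ 0.107,
which exceeds the observed area CV of every posture group (0.075–0.102).
`tune_shape_noise` inverts the variance decomposition
`CV(a)² ≈ (0.66·CV(W))² + shape_noise²` and floors at zero, so under
uniform weights the tuned noise is zero and generated per-posture SDs sit
at the weight-driven floor — within 30% of the study SDs for nine of the
thirteen postures, and above by up to ~43% for the tightest groups (AS, CS,
LBC, LL). The study cohort's own within-group weight SDs (~10–12 kg) are
well below uniform's 16.7 kg, which is the entire source of the overshoot.
The property test asserts the 30% band where it is attainable and the
exact floor relation everywhere; narrower weight distributions recover the
band for all postures.

## Comparison layer

`comparison_table` evaluates, at each posture group's mean live weight as
printed (2 dp), the posture-specific allometric model (k = 0.019 for A–ES
and LBC, 0.025 for LSL, 0.047 for LL; exponent fixed at 0.66) and the
legal minimum `(W/235)·(1+surcharge)` with surcharge default 0 (the
without-addition case; a flag enables up to 0.20). Sign conventions:
`allometric_deviation = allometric − measured` and
`free_space = legal − measured`, so positive values mean the model allots
more than the body covers and negative free space means the legal floor is
smaller than the animal. All values are carried unrounded and rounded only
at the reporting layer, half-up, 3 dp for areas (2 dp where the published
numbers use 2).

### Known inconsistencies in the published prose

Recomputing every quantity from the printed group means reproduces the
published comparison numbers except for four prose figures, which the
package deliberately reports as recomputed rather than as printed:

| quantity | prose | recomputed |
|---|---|---|
| free space, posture E | 0.012 m² | 0.127 m² |
| legal shortfall, posture LL | 0.028 m² | 0.029 m² |
| free space, sternal lying | 0.033 m² | 0.032 m² (LBC) |
| semirecumbent allometric deviation | 0.103 m² | 0.104 m² (LSL) |

(The 0.012 figure is likely a transposition of 0.127's digits; the others
are sub-millimetre rounding slips.) Additionally the prose labels 0.089 m²
(posture ES) the *minimum* standing deviation, while recomputation puts
posture E marginally lower (0.0882 vs 0.0890); both values themselves
reproduce exactly. The prose also once writes "LCL" for the semilateral
code and once pairs the sternal description with "(LSL)"; the catalog
follows the definition table throughout: LBC sternal, LSL semilateral,
LL fully lateral.

## Statistics

- **Descriptives**: mean, SD (n−1), min, max.
- **Spearman correlation** of weight vs area within a posture: average
  ranks for ties, p-value from the t-approximation on n−2 df (the common
  statistical-software default at these group sizes); exact behaviour is
  cross-checked against a brute-force rank oracle on small tied samples.
- **Mean comparisons**: Welch's t with Welch–Satterthwaite df, computable
  from raw samples or directly from published summary statistics. Welch is
  the default because group sizes range from 30 to 201; it reduces to the
  pooled test when variances and sizes are equal.
- **Group-weight comparisons**: one-way fixed-effects layout with
  Tukey–Kramer adjustment — studentized-range distribution with the Kramer
  correction for unbalanced n — which for a single factor is equivalent to
  comparing least-square means with the Tukey method. Compact significance
  letters use insert-and-absorb with ties broken by catalog order A…LL. On
  samples moment-matched to the published group weights, exactly one pair
  separates at α = 0.05: E (106.26 kg) vs CS (111.22 kg), matching the
  published finding.

## Numerical choices

- Image coordinates: origin top-left, row-major; world coordinates: meters
  on the floor plane, origin under the lens. Pixel-center inclusion decides
  polygon rasterization.
- Rounding: half-up via decimal arithmetic, applied only when reporting.
- Degenerate inputs fail loudly: constant images (no contrast), empty
  segmentations, object heights ≥ lens height, negative weights or noise,
  surcharges outside [0, 0.20], summary tables violating their own
  invariants (counts, orderings, the 1,583-image total).
- Fixture precision: weights stored at 2 dp, areas at 3 dp, exactly as
  printed; load/save round-trips are lossless at that precision.

## Problem sizes

Default test and example runs use scenes of 1600×1100 px at 500 px/m
(oracle-equivalence checks use 26 scenes spanning all 13 postures),
analytic cohorts of 200 animals per posture for exponent recovery, and a
232-animal cohort for dispersion realism — sizes at which the stochastic
checks are stable while the whole suite stays fast.

## Limitations

- Single-animal scenes only; no occlusion, huddling, or group packing.
- The 3-D body is a planar outline at one height per posture class.
- No lens-distortion model; real wide-angle frames would need undistortion
  before calibration.
- Gender is carried descriptively in the tables but not modelled.
- Table 3's per-posture correlation p-values are published only as
  "p < 0.05" and are not reproduced beyond that bound.
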