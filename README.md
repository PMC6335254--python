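# pigplanim

Top-view planimetry of finishing pigs: how much floor does a pig's body
actually cover, posture by posture, and do space-allowance formulas and EU
transport law allot enough of it?

`pigplanim` is a Python library for researchers in livestock welfare and
transport who work with **static space** — the floor area physically covered
by an animal's body outline, measured from calibrated top-view images. It
implements the full measurement chain (contrast-based silhouette
segmentation, reference-surface calibration, pixel-to-m² conversion under a
pinhole camera), the two comparison analyses that give the measurements
meaning, and the statistics used to report them. Because live-animal
photography cannot ship in a package, a synthetic scene generator with
analytic ground truth stands in for the camera: every stage of the pipeline
can be scored against exact polygon areas.

## The science in brief

A pig photographed from directly above covers a planform area *a* that
depends on its live weight *W* and posture. Two reference models exist:

- **Allometric space allowance**: *a* = *k*·*W*^0.66 m² with
  *k* = 0.019 for standing and sternal-lying postures, *k* = 0.025 for
  semilateral lying, and *k* = 0.047 for fully recumbent lying.
- **Legal loading density** (Council Regulation (EC) No 1/2005, road
  transport of ~100 kg pigs): at most 235 kg live weight per m², i.e. a
  minimum floor area of *W*/235 m² per animal, extendable by up to 20%.

The planimetric measurements distinguish 13 postures — ten standing codes
(A, AS, B, BS, C, CS, D, DS, E, ES, varying head height and sideways body
curvature) and three lying codes (LBC sternal, LSL semilateral, LL fully
lateral). The package ships the per-posture summary tables of a 232-pig,
1,583-image study cohort (weights 75–133 kg) as fixtures, and the
comparison layer recomputes from them the deviations between measured,
allometric, and legal areas.

Measurement geometry: the camera lens sits *D* = 245 cm above the floor. A
plane at height *h* is magnified by *D*/(*D*−*h*), so calibration uses a
0.420 m² reference board mounted at the typical body-plane height — 69 cm
for standing pigs, 29 cm for lying pigs — making the perspective factor
cancel between reference and subject.

## Worked example

```bash
python examples/01_reproduce_published_comparisons.py
```

prints, among the 13 rows:

```
 posture   W (kg)  measured allometric deviation legal min    free
       A   109.09     0.288      0.420    +0.132     0.464  +0.176
       E   106.26     0.325      0.413    +0.088     0.452  +0.127
     LBC   108.21     0.428      0.418    -0.010     0.460  +0.032
      LL   107.50     0.486      1.030    +0.544     0.457  -0.029

standing allometric deviations: mean 0.107 ± 0.017 m², max 0.132 (A), min 0.088 (E)
```

Reading: a standing pig (posture A) covers 0.288 m² while the standing
allometric formula predicts 0.420 m² — an over-prediction of 0.132 m². For
a fully recumbent pig (LL) the formula over-predicts by 0.544 m², while the
legal minimum of 0.457 m² is 0.029 m² *smaller* than the 0.486 m² the
animal's body actually covers: the legal floor allotment cannot hold all
pigs lying fully recumbent at once without overlap.

The other examples render a synthetic pig and measure it to within
rasterization tolerance of its exact polygon area
(`02_measure_synthetic_pig.py`), demonstrate the
((*D*−*h*<sub>ref</sub>)/(*D*−*h*<sub>obj</sub>))² perspective bias of
mismatched calibration heights (`03_perspective_bias.py`), and run the
simulate → calibrate → measure → compare → stats chain on a seeded cohort
(`04_cohort_statistics.py`).

A thin CLI wraps the same stages:

```bash
pigplanim reproduce                 # recompute + check the published numbers
pigplanim simulate --seed 7 --out scenes/
pigplanim end-to-end --seed 7 --out run/
```

## Layout

- `src/pigplanim/postures.py` — 13-posture taxonomy, packaged study tables
- `src/pigplanim/scene.py` — synthetic scenes: pinhole projection,
  allometric silhouettes, analytic ground truth
- `src/pigplanim/planimetry.py` — contrast enhancement, segmentation,
  calibration, area measurement
- `src/pigplanim/space.py` — allometric and legal space models, comparisons
- `src/pigplanim/stats.py` — descriptives, Spearman, Welch, Tukey–Kramer
- `src/pigplanim/pipeline.py`, `cli.py` — stage chaining and the CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
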