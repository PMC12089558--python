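# stenokit

Automated detection and grading of vascular stenosis in 2-D angiography-like
images, built for researchers working on peripheral arterial disease imaging
(abdominal aorta and iliac arteries in digital subtraction angiography) and
for anyone who needs a fully synthetic, ground-truth-controlled test bed for
vessel morphometry.

The pipeline has five stages:

1. **Prompt-point selection + segmentation.** A promptable segmenter is
   driven by iteratively chosen positive points: threshold the vessel
   probability map, sample 100 spatially spread candidate pixels, take the
   locally densest candidate as a positive point, then repeatedly predict a
   mask from the points found so far and pick the densest candidate outside
   it — five positive points by default. Any promptable model can be plugged
   in behind a two-method contract; a deterministic, weight-free classical
   backend (smoothed inverted-intensity probability map, geodesic
   prompt-conditioned prediction) ships in the box.
2. **Topological skeleton.** The mask's skeleton is decomposed into a branch
   graph (endpoints, junctions, ordered pixel paths) and terminal spurs
   shorter than a length threshold are pruned iteratively, preserving
   connectivity.
3. **Diameter profiles.** The local vessel diameter along each centerline
   branch is estimated from the Euclidean distance transform (EDT):
   `d(s) = 2·max3×3(EDT) − 1` px (ridge re-centering plus half-pixel boundary
   correction).
4. **Anomaly detection and quantification.** Per-branch diameter extrema are
   anomaly candidates; a candidate is confirmed when its relative diameter
   change against the median of two flanking reference windows reaches a
   threshold (default 0.25). Confirmed narrowings are quantified as
   `percent = 1 − d_anom/d_ref` and graded on the 5-point clinical scale
   (1: 0–24 %, 2: 25–50 %, 3: 51–75 %, 4: 76–99 %, 5: occlusion). Occlusions
   themselves are structurally undetectable — a fully occluded stretch has no
   lumen pixels, hence no skeleton — and every report says so explicitly.
5. **Agreement statistics.** Weighted Cohen's kappa (linear or quadratic)
   with the standard interpretation bands, Spearman rank correlation with
   strength bands, sensitivity/specificity/PPV/NPV for the high-grade {4,5}
   vs {1,2,3} dichotomy, and the Wilcoxon matched-pairs signed-rank test.

A synthetic **phantom generator** renders DSA-like vessels (single tubes,
Y-forks, aorto-iliac trees) with exactly known centerlines, radii and imposed
lesion severities, so every stage can be validated against ground truth.

## Worked example

Generate a phantom with an imposed 60 % stenosis and run the full pipeline:

```bash
$ stenokit phantom single --severity 0.6 --radius 8 --out demo --seed 3
wrote phantom to demo
$ stenokit assess demo/phantom.png -o demo/out
INFO stenokit: segmented 6625 vessel pixels
INFO stenokit: 1 branches, 1 confirmed findings
grade 3 (max stenosis 53.3%)
```

The report (`demo/out/report.json`) contains one confirmed stenosis at
53.3 % — the imposed 60 % lesion measured through rendering noise,
segmentation and pixel-level diameter estimation — which maps to grade 3
(moderate, 51–75 %), matching the phantom's ground-truth grade. The output
directory also holds `mask.png`, `skeleton.png`, `skeleton.json` and
`profile.csv` (per-centerline-pixel diameters), mirroring each pipeline
stage.

Rating tables are evaluated the same way:

```bash
$ stenokit evaluate ratings.csv
segment        n   kappa       band      r       p  sens  spec
CIA_right      8    0.83  excellent   0.93   0.500  0.50  1.00
pooled         8    0.83  excellent   0.93   0.500  0.50  1.00
```

Here `kappa` is the linear-weighted Cohen's kappa between the two rating
columns (0.83 → excellent agreement band), `r` the Spearman correlation,
`p` the Wilcoxon matched-pairs p-value, and sens/spec the dichotomized
(grade ≥ 4) confusion rates.

## Library use

```python
from stenokit import RunConfig, assess_vessel, make_backend, segment, select_positive_points
from stenokit.phantoms import PhantomSpec, Anomaly, make_phantom

cfg = RunConfig()
img, truth = make_phantom(PhantomSpec(
    anomalies=[Anomaly("tube", 0.5, "stenosis", 0.6, 25.0)], seed=3))
backend = make_backend(cfg)
points = select_positive_points(img, backend, cfg.n_points, cfg).points
report = assess_vessel(segment(img, backend, points), cfg)
print(report.grade, report.max_stenosis_percent)
```

## Scope notes

- All geometry is in pixels; stenosis percentages are unitless ratios, so no
  mm calibration is needed.
- Dilations (aneurysm-like bulges) are detected and quantified as percent
  increase but are not graded on a clinical scale.
- 3-D imaging, DICOM ingestion and anatomical vessel naming are out of
  scope; segment labels (AAI/CIA/EIA) are user-supplied metadata.
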