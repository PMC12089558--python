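# Methods

This note documents the models, estimators and numerical choices behind
stenokit, in the order the pipeline runs them, together with what the
synthetic phantoms do and do not establish about real angiograms.

## Promptable segmentation and point selection

The point-selection algorithm assumes only a minimal segmenter contract:
`probability_map(image)` and a deterministic `predict(image, points) ->
(mask, probability_map)`. Selection proceeds in rounds:

1. Pixels with probability below `probability_threshold` (default 0.5) are
   discarded. An empty survivor set raises `NoVesselSignal` — it is a
   distinct outcome, not an empty prompt list.
2. From the surviving pixels, `n_candidates` (default 100) spread candidates
   are drawn by greedy thinning over a seeded random permutation, enforcing
   a pairwise separation of `min_separation` (default 3 px). The first
   positive point is the candidate with the smallest mean distance to its
   `k = 10` nearest fellow candidates (the "densest" candidate — dense
   candidate neighborhoods track wide, well-attested vessel regions). Ties
   break by higher probability, then row-major order. The second point is
   chosen the same way among candidates at least `min_separation` from the
   first.
3. Each further point (three rounds by default, five points total) re-samples
   100 spread candidates and takes the densest one *outside* the mask
   predicted from all points so far. If the predicted mask swallows every
   remaining pixel the selection returns early with an `exhausted` flag.

All randomness flows from a single config seed; two runs with the same seed
are bit-identical.

### The classical backend

The bundled backend is deliberately weight-free so the pipeline is testable
without any neural network:

- **Probability map**: Gaussian-smooth the image (σ = 1 px), then map
  intensity linearly from the 99th percentile (background) to the 1st
  percentile (vessel core) and clip to [0, 1] — vessels are dark on a light
  DSA-like background. If the percentile spread is below `min_contrast`
  (0.08) the image is declared vessel-free (all-zero map).
- **Prediction**: threshold the map at 0.5 and keep foreground within a
  geodesic radius `reach` (default 60 px, measured inside the foreground) of
  the prompt points. This mimics the partial masks of a promptable
  segmenter — more spread points grow the mask — which is what makes the
  iterative "next point outside the mask" refinement meaningful. Two
  post-processing rules repair coverage artifacts: uncovered foreground
  pockets smaller than one inscribed-disc area that touch the covered region
  are filled (lens-shaped bites where two prompt regions meet), and
  uncovered stretches adjacent to two distinct covered regions are filled
  regardless of size (a narrow stenosis throat attracts no prompts — density
  favors wide regions — and must not be left as a gap). One-sided uncovered
  tails stay out so refinement still has targets.

Alternatives considered: a Sato/Frangi vesselness map (needs scale tuning
per vessel caliber; rejected for the default), and hysteresis thresholding
for thin-throat continuity (rejected: the weak-threshold halo widens every
vessel by ~1 px and biases severities low by up to 10 points).

## Skeleton graph and pruning

Skeletonization uses morphological thinning (fewer spurs than the medial
axis; the medial axis remains available via `method="medial_axis"`). The
1-px skeleton is decomposed with 8-connectivity: endpoints have one skeleton
neighbor, junction pixels three or more; 8-adjacent junction pixels merge
into one junction node. Branch length is geometric (diagonal steps √2).
Pure cycles are stored as one closed edge cut at the lexicographically
smallest pixel.

Pruning removes terminal branches shorter than `min_branch_length`
(default 10 px) and runs to a fixpoint, because dissolving a junction whose
degree drops to 2 merges its two surviving branches and can expose new
spurs. Internal branches (junction-to-junction) are never pruned, and a
component is never erased — its last edge survives regardless of length, so
component count is conserved.

## Diameter estimation

The Euclidean distance transform gives, at each centerline pixel, the radius
of the largest inscribed disc. Two discretization errors are corrected:

- the staircase skeleton of an oblique tube sits up to ~1 px off the true
  medial ridge, where the EDT reads low → each sample takes the maximum EDT
  over its 3×3 neighborhood (ridge re-centering);
- the EDT measures to the *center* of the nearest background pixel and so
  overestimates the lumen radius by about half a pixel → subtract after
  doubling: `d = 2·max3×3(EDT) − 1`.

With both corrections the median estimated diameter of rasterized
constant-radius tubes (r = 3–12 px, any orientation) stays within ±1 px of
the true value, which fixes the scale error budget of every percentage
downstream.

Profiles are smoothed with a centered moving average (`smooth_window = 5`
px) for robust extremum localization; the *raw* profile is kept alongside
and used for all magnitude arithmetic, since smoothing dilutes the depth of
a sharp lesion.

Samples within one local vessel radius of any segment end are flagged
invalid for anomaly search: near a junction the inscribed disc leaks into
the merging vessel and the EDT is inflated; near a free end — a rounded cap
or a mask truncated by partial segmentation coverage — the EDT tapers off.
Both zones extend about one radius and contain no usable diameter signal.
The margin is `max(⌊w/2⌋, ⌈median_diam/2⌉ + 2)` px, enlarged at junction
ends to `⌈EDT(end)⌉ + 2` when that is larger. The cost is a known blind
spot: lesions closer than one vessel radius to a bifurcation or to the
field-of-view edge are not assessed.

## Anomaly detection and stenosis percentage

Candidates per branch are the interior global minimum (stenosis), interior
global maximum (dilation), and local extrema with diameter prominence ≥
`prominence` (0.5 px). For each candidate a reference diameter `d_ref` is
the median raw diameter over two flanking windows of `window = 15` px,
separated from the extremum by a gap sized from the lesion's own extent
(walk outward until the profile recovers to within 10 % of a provisional
far-flank median; gap capped at `window`) so the lesion never contaminates
its own reference. At a segment end the surviving flank is used alone.

A candidate is confirmed when the relative change in the direction of its
kind, `(d_ref − d_raw)/d_ref` for narrowings, reaches `change_threshold`.
The default 0.25 aligns the confirmation boundary with the ≥ 25 % band
where stenosis becomes clinically relevant (grade ≥ 2). The reported
magnitude re-queries the distance transform in the 3×3 neighborhood of the
extremum (`d_anom = 2·maxEDT − 1`) so it is not diluted by smoothing, and

    stenosis percent = 1 − d_anom / d_ref
    dilation percent = d_anom / d_ref − 1.

Estimator selection was done on noiseless phantoms: min-pooling the EDT
along the path double-counts off-ridge error (bias ≈ +5 points); the 3×3
ridge max at the extremum has bias ≈ +0.1 points and MAE ≈ 2 points over
severities 30–90 %.

A segment's grade is the clinical band of its maximum confirmed stenosis
percent (no confirmed finding → grade 1). Percent values are mapped to
grades by rounding to an integer percent (half-to-even after snapping float
noise, so 24.5 % reads as grade 1) and banding 0–24/25–50/51–75/76–99/100.

**Occlusions are out of reach by construction**: a fully occluded stretch
has no lumen pixels, no skeleton, and simply splits the vessel into
components. Reports carry `occlusion_flag = "indeterminate"`, note the
component count, and can never emit percent = 1.0 (d_anom ≥ 1 px). Grade 5
is therefore never produced by the pipeline; rating-table comparisons can
exclude grade-5 reference cases (`exclude_grade5`).

## Agreement statistics

Weighted Cohen's kappa uses linear disagreement weights by default
(quadratic available; the weighting is always echoed in the output since the
two can differ materially). Bands: ≤ 0.40 poor, 0.41–0.60 moderate,
0.61–0.80 good, 0.81–1.00 excellent, applied after rounding kappa to two
decimals. Spearman uses midranks for ties; bands at |r| 0.1/0.3/0.5.
The Wilcoxon matched-pairs test drops zero differences, uses the exact null
for n ≤ 25 without tied ranks and a continuity-corrected normal
approximation otherwise; all-zero differences return p = 1 with a flag
rather than an error. Degenerate statistics (single grade used by both
raters, zero variance, empty confusion rows) return flagged results, never
NaN. When two human raters form the reference, their half-integer average
grade is rounded half-up to an integer category (floor/ceil configurable).

## The phantom generator

A phantom is an analytic centerline (quadratic Bézier per branch, resampled
at 0.35 px arclength steps) with a per-arclength radius function. Lesions
multiply the radius by `1 ∓ severity·bump(s)` with a cosine-tapered unit
bump over a finite extent (a rectangular bump is available for worst-case
tests). Masks are rasterized as the union of inscribed discs along the
centerline; renderings place the dark vessel (sigmoid soft edge, 0.7 px) on
a light background with a smooth texture field and i.i.d. Gaussian noise,
both scaled by the `noise` parameter, so a noiseless rendering thresholds
back to the exact mask. Everything derives from the spec (including its
seed): a JSON spec dump replays a phantom bit for bit.

Default study conditions, chosen once as representative of aorto-iliac DSA
crops: canvas 448×386 px (the smaller clinical crop size; 818×946 supported),
base radius U[6, 10] px, lesion extent U[20, 30] px placed in the middle of
the vessel, rendering noise σ = 0.03 of the intensity range. Cohorts sample
a grade per phantom from a configurable mix whose default reflects the
prevalence in an unselected clinical population, renormalized over grades
1–4 — {1: 0.792, 2: 0.092, 3: 0.050, 4: 0.066} — because a grade-5 phantom
(occlusion) has no lumen to rasterize and no skeleton to analyze; grade-4
severities stop at 0.92 so the rasterized throat keeps ≥ 1 px of lumen.
Severities are drawn uniformly within each grade's percent band, inset by
0.005 so rounding can never flip the ground-truth grade.

What the phantoms do **not** emulate: subtraction artifacts and bone/soft
tissue residue, contrast-flow inhomogeneity, overlapping or tortuous
out-of-plane vessels, catheters, and calcified plaque appearance. Passing
the synthetic studies therefore establishes the geometric correctness of
the morphometry and the internal consistency of the grading stack, not
clinical performance; the segmentation backend in particular faces far
richer failure modes on real DSA.

## Problem sizes and tolerances in the validation studies

- Diameter oracle: 20 tubes, r = 3–12 px, random orientation, ±1 px on the
  median.
- Severity recovery: 50 single-lesion phantoms, severities U[30, 90] %,
  assessed from ground-truth masks; MAE ≤ 7.5 points and zero missed severe
  (> 75 %) lesions.
- Null specificity: 50 healthy phantoms (tubes and aorto-iliac trees), ≤ 5 %
  with any confirmed finding.
- Statistics oracles: brute-force double-sum kappa, Pearson-of-midranks
  Spearman, and full sign-pattern enumeration of the signed-rank null
  (n ≤ 8), agreement to 1e-12.
- End-to-end study: 100-phantom cohort at the default grade mix, full
  image → grade pipeline vs ground truth, linear-weighted kappa required to
  land in the good/excellent band. This is a property of the pipeline on
  synthetic data, not a clinical claim.

## Known limitations

- Lesions within one vessel radius of a junction or image border are not
  assessed (excluded margins).
- Diameters below ~2 px are at the rasterization floor; severities above
  ~92 % are reported but saturate toward the floor value.
- Sub-pixel accuracy (edge fitting) and mm calibration are out of scope;
  percentages are ratios of pixel-scale diameters.
- The classical backend assumes dark vessels on a brighter background with
  monotone contrast; it is a reference implementation, not a clinical
  segmenter.
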