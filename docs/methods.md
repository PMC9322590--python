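# Methods

## Coordinate and morphology conventions

Volumes are indexed `[x, y, z]` with x = left-right, y =
anterior-posterior (posterior = +y, toward the pedicles), z =
inferior-superior; voxel `i` along an axis of spacing `s` has its centre at
`(i + 0.5)·s` mm.  All morphological distances are physical millimetres,
realised on the grid through the voxel spacing:

* *erode/dilate by d mm*: threshold of the Euclidean distance transform at
  `d` (a metric ball; anisotropic spacing handled by the EDT sampling).
  Erosion keeps voxels strictly farther than `d` from background;
  outside-grid is treated as background.
* *dilate along an axis by d mm*: 1-D segment of half-length d, i.e.
  `floor(d / spacing)` voxels.
* *body re-dilation*: a per-axis **box** of half-extent
  `body_dilation_mm`, truncated posteriorly at
  `body_dilation_posterior_mm`.  A box rather than a ball is deliberate:
  the step exists to recover the whole vertebral body from its eroded
  core, and a ball of radius 12 mm cannot reach the body corners (which
  lie ~`10·√3` mm from the core), whereas reaching 12 mm along each axis
  independently recovers a box-like body exactly.
* *geodesic dilation of a seed within M*: iterated one-voxel
  (26-neighbourhood) dilation clipped to `M ∪ seed`, with
  `ceil(d / min(spacing))` iterations, finally intersected with `M`.  The
  seed may lie outside `M` — the facet contact area lives in the
  background gap between two vertebrae and is grown *into* the bone —
  but growth cannot crawl across background belonging to neither.

Connected components use 26-connectivity by default; "largest component"
ties break by voxel count, then inferior-most centroid, then component id,
so extraction is fully deterministic.

## VOI recipes and their parameters

`MorphParams` defaults (all configurable, mm): body erosion 10, body
re-dilation 12 (posterior cap 10), facet contact dilation 5 (cranio-caudal),
facet geodesic refinement 3, centerline exclusion 5, lowest-facet slab 10,
disc dilation 10 (cranio-caudal), disc forbidden-rim dilation 3 (in-plane).
The erosion/dilation pair for the body is fixed by the method's design
("slightly larger" re-dilation, posterior cap equal to the erosion
distance); the remaining distances are method parameters chosen to produce
plausible VOIs on the default phantom and are surfaced rather than
hard-coded.

Design choices where the method is genuinely open:

* The cranio-caudal axis is used for the facet-contact and disc-overlap
  dilations: overlap between vertically adjacent structures is impossible
  under a purely lateral dilation.  The disc forbidden regions are
  in-plane (axial, slice-wise) dilations of each body minus that body's
  own axial footprint column.  Note that under the strict cranio-caudal
  overlap the initial disc estimate is confined to the intersection of the
  two bodies' footprint columns, so the forbidden rims are provably inert
  for this dilation choice; the step is retained because it becomes active
  whenever the overlap dilation has any in-plane component.
* Posterior elements are defined as vertebra minus extracted body; the
  spinous process is not explicitly segmented — spurious midline contacts
  are removed by the centerline rule (component centroid within 5 mm of
  the sagittal midline, the median left-right coordinate of the two
  bodies' union).
* The L5-S1 facets always use the inferior-slab seed on L5; when a sacrum
  label is present it only widens the region the refinement may grow into.
* There is no interactive mask editing; anomalies (empty contact, a single
  surviving facet component) are logged as warnings and yield empty masks
  rather than failures.

A note on the body recipe at junctions: because the erosion is metric,
interior voxels directly behind a thick posterior attachment can exceed the
erosion distance from all background, so the re-dilation may recapture a
one-voxel layer of the attachment root.  This is inherent to the
erode/re-dilate design (the posterior cap equals the erosion distance) and
is bounded by one or two voxel layers in practice.

## Quantification

For a VOI: max, arithmetic mean and total = mean × volume (mL) of the voxel
values; volume = voxel count × voxel volume (no partial-volume weighting).
Means are accumulated in float64 so that voxel-pooled region summaries
(volume-weighted mean, max of maxes, summed totals) coincide with metrics
computed directly on the union mask to ~1e-12 relative.  Region pooling
across levels is voxel-pooled by default — the magnitude of published
per-region totals (e.g. bodies' SUVtotal ≈ mean × ~200 mL across five
bodies) indicates summing over levels — with per-VOI averaging available
behind `pooling="per_voi"`.  `suv_from_activity` implements the standard
body-weight SUV, concentration / (dose / weight).

## Statistics

Within-pair differences (case − control) gate the test choice through
Shapiro–Wilk at α = 0.05 (the normality test is a package choice; it is the
standard small-n test).  Paired *t* when normal; otherwise the two-sided
Wilcoxon signed-rank test with exact null distribution when n ≤ 25 with no
zero or tied differences, else the normal approximation with continuity
correction (zeros dropped).  The mean difference and its *t*-based 95% CI
are reported for every row, including Wilcoxon rows, matching the usual
tabular presentation; a Hodges–Lehmann interval was considered and not
adopted for that reason.

Holm–Bonferroni: the k-th smallest p is compared with α/(m−k+1), stopping
at the first failure (rejections are a prefix of the ascending order).  A
`literal_fixed` variant compares every ordered p against α/m, mirroring
descriptions that reuse the first-step level throughout; the two variants
coincide whenever the procedure stops at step one.

## The synthetic phantom

The phantom emulates exactly what the VOI algorithm consumes: per-vertebra
binary masks with the right physical dimensions and adjacencies.  Each
vertebra is a 34 × 30 × 28 mm body box, bilateral pedicles, bilateral
articular columns overhanging the 8 mm disc gap (leaving a 4 mm
cranio-caudal gap between adjacent columns, within facet-contact range),
laminae and a midline spinous process; an optional 40 × 30 × 30 mm sacrum
sits below L5.  Default grid 128 × 128 × 192 voxels at 1.5 mm isotropic.
Each vertebra is verified to be a single 26-connected component.

Intensities are i.i.d. Gaussian per voxel per tissue class
(vertebral body, posterior elements, disc, sacrum, background), means and
SDs defaulting to published control-group region summaries (NaF / FDG SUV
and HU); SUV channels are clipped at 0.  One child random stream per
channel (and per subject in the pipeline) is derived from the master seed,
so adding a channel or subject never perturbs the others.  Optional
Gaussian smoothing emulates PET resolution; it is off by default because no
per-voxel noise model is available to calibrate against.

What the phantom does **not** model: anatomical vertebra shapes, partial
volume and reconstruction effects, intra-tissue heterogeneity, spatial
noise correlation.  The per-voxel noise SDs are borrowed from
*between-subject* spreads, which conflates variance sources; consequently
passing tests demonstrate correctness of the mask algebra, the metric
definitions and the statistical machinery on known ground truth — not
segmentation performance on clinical images.

The cohort generator draws per-subject region metrics directly from
case/control Gaussians per (channel, region, metric) cell; cells whose
published summary is a median (min–max) use the median as centre and
(max − min)/4 as an SD proxy.  Demographics satisfy the matching design:
within-pair age difference ≤ 3 years, identical sex, a 7:5 male:female
cycle per 12 pairs.

## Pipeline

Phantom mode generates the geometry once, segments it, then draws one
intensity volume set per subject.  Subject tissue means are the group means
plus a between-subject Gaussian effect (SD again the published group SDs):
without this effect, region means over thousands of voxels would have
negligible between-subject variance and 12-pair tests would be degenerate.
Because the geometry (hence every VOI volume) is identical across subjects,
`total = mean × constant`, so mean and total rows of a region carry
identical p values in phantom mode.  Reruns with the same configuration and
seed are byte-identical; a provenance JSON records the config hash, seed,
all morphological parameters in effect, per-VOI voxel counts and collected
warnings.

## Problem sizes used in validation

The test-suite simulations use: 5000 null replicates at n = 12 pairs for
the type-I error of the gated paired test, 1000 replicates for 95% CI
coverage under a true difference at the published disc-SUVmax group SDs,
500 replicates of 27-test null families for the Holm family-wise error,
2⁶-fold sign enumeration at n = 6 for the exact Wilcoxon oracle, and
2000–5000 pairs for cohort-mean recovery.  Resolution-equivariance is
checked at 1.5 mm vs 0.75 mm spacing on two-vertebra toys whose
coordinates are multiples of 3 mm, so both grids realise the same physical
structures; agreement of VOI volumes is required to within 10%
(discretisation tolerance).  Full-resolution (1.5 mm) phantom runs back the
structural checks (5 bodies, 4 discs, 10 facet VOIs; 27 comparison rows).

## Known limitations

* The phantom's block geometry cannot probe failure modes caused by curved
  or pathological vertebra shapes (the centerline rule and largest-
  component heuristics are exercised only on stylised inputs).
* Facet VOIs on the default phantom are small (~0.2–0.9 mL); their metric
  values are correspondingly noisy at realistic voxel SDs.
* The forbidden-region step of the disc recipe is inert under the strict
  cranio-caudal overlap (see above).
* No partial-volume or decay correction; SUV inputs are assumed already
  decay-corrected, as PET/CT scanners provide.
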