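# Methods

## The analysis model

The pipeline treats a developing hermaphroditic fern prothallus as a set of
point nuclei in the 2D projection plane, observed at 6-h intervals.  Every
quantity it reports is derived from three primitives:

- a **per-frame detection**: nucleus centroids (μm) with unique per-frame ids;
- a **link table**: rows `(t_from, id_from, t_to, id_to)` connecting
  consecutive frames, where a parent with two rows is one division event;
- a **lineage forest**: the transitive closure of the link table, rooted at
  the progenitor cells of the first frame.

A division at step t→t+1 is timestamped at the step-start hour.  Analysis
windows are half-open `[start, end)` in hours, so the developmental phases
(initiation 0–24 h, transition 24–54 h, maturation 54–108 h) partition the
events exactly and window counts are additive.  The division activity of a
cell alive at a reference frame is the number of division events in its own
subtree whose timestamps fall in the window; per-lineage activity sums the
per-cell values over cells sharing a root.

### Segmentation

Nuclei in a maximum-intensity projection are bright, roughly isotropic
blobs.  Each frame is Gaussian-smoothed (`smooth_sigma`, default 1 px),
thresholded (Otsu by default; a fixed threshold for binary or calibrated
input), and the foreground mask is split by a marker-controlled watershed of
the negated Euclidean distance transform.  Markers are the h-maxima of the
distance map at depth `h_maxima_depth · max(distance)` (default 0.3): this
merges the shallow multiple maxima of a single slightly lumpy nucleus while
keeping the two deep maxima of touching nuclei, which plain connected
components would fuse.  Regions smaller than `min_area` (default 4 px²) are
dropped.  Labels are reassigned 1..N in raster-scan order of each region's
first pixel, so identical input yields identical output.  Scripted edits
(delete, merge under the lower id, split by re-running the watershed from
two seed pixels) reproduce a manual curation pass; edits are applied in
script order and the map is relabelled afterwards.

### Tracking

Pass 1 solves the rectangular assignment problem minimising total squared
displacement over candidate pairs within `max_displacement` (default
15 μm/step, comfortably above observed motion); out-of-range pairs carry a
cost large enough that the solver only uses them when no valid pair exists,
and such assignments are discarded.  Pass 2 attaches each remaining new
nucleus, in ascending id order, as a second daughter to the nearest old
nucleus within `division_radius` (default 12 μm ≈ one cell diameter) that
has fewer than two children.  Leftover new nuclei are an error unless
orphans are explicitly allowed (ablation re-analysis); childless old nuclei
are flagged terminated, never silently dropped.  Ties break toward the
lowest ids.

This automatic linker is provably exact when (a) every continuing nucleus
moves less than half the minimum same-frame nearest-neighbor distance and
(b) every daughter lies nearer its own parent than any rival; the test suite
asserts 100 % recovery, divisions included, on simulated data satisfying
those conditions, and checks the pass-1 optimum against exhaustive
enumeration on small frames.  At realistic nuclear densities simultaneous
adjacent divisions are genuinely ambiguous from coordinates alone — a
daughter can land almost equidistant between two dividing parents — which is
why curated link files remain first-class inputs and override automatic
links wherever present.  Downstream statistics in the validation suites are
therefore computed on curated (ground-truth) links, with automatic linking
validated separately under its guarantee conditions.

### Marginal vs inner meristem cells

"Marginal" means the tissue's outermost cell layer.  The classifier builds
the alpha-shape boundary of all nucleus positions in the frame (Delaunay
triangulation, triangles kept when their circumradius is below `alpha`,
boundary = edges on exactly one kept triangle).  `alpha` defaults to 2.5×
the median nearest-neighbor distance — large enough to bridge normal
inter-nucleus gaps, small enough to follow the concave notch region.  Cells
inside the meristem ROI within ε = 0.5 μm of the boundary polyline are
marginal; other ROI cells are inner; everything else is outside.  The ROI is
normally drawn (a polygon; the validation suites use the simulator's own
meristem disk), or derived automatically as the largest connected set of
recently divided cells.  Degenerate inputs: fewer than 3 ROI cells is an
error; a collinear configuration classifies everything marginal with a
warning.

### Statistics

Group comparisons use Student's two-tailed t-test with pooled variance
(Welch's correction available behind a flag).  Zero pooled variance with
equal means returns p = 1 by convention; with unequal means it is an error.
The implementation is checked against the textbook formula to 1e-10.

### Archegonium geometry

Distances are Euclidean in the 2D projection plane, in μm.  An archegonium's
center is the unweighted centroid of its member nuclei unless a manual
center annotation is supplied (annotations win).  A distance series starts
at 0 h since initiation, one entry per frame; initiation summaries report
per-archegonium initiation hour and distance and cross-sample mean ±
standard error (sd/√n).

## The synthetic prothallus

The generator is an agent-based model whose purpose is to produce data with
the statistical structure the analysis assumes, plus exact ground truth.
Cells are points; each step every cell divides with a probability set by its
zone and the current phase, daughters are placed at ±`daughter_offset`
(default 4 μm) along a random axis, and a repulsive relaxation (pairwise
spring pushes toward a target 2 % above `min_spacing`, iterated until no
violation remains) restores the minimum nucleus spacing of 7 μm.  Tissue
growth is therefore entirely division-driven: inserting cells pushes
neighbors outward.

The meristem is a persistent disk anchored at the advancing margin on one
lateral side; the anchor tracks the most advanced nearby cell along the
meristem axis, and the disk radius ramps linearly from 20 to 90 μm over the
run, reflecting the several-fold expansion of the actively dividing region
during maturation.  Zone labels are recomputed every step with the same
tissue-boundary test the analysis side uses: meristem cells on the alpha
boundary are `meristem_marginal`, enclosed meristem cells `meristem_inner`,
the rest `outside`.

Per-step division probabilities (initiation, transition, maturation):

| zone              | defaults            | rationale |
|-------------------|---------------------|-----------|
| meristem marginal | 0.20, 0.30, 0.33    | maturation value calibrated (see below) |
| meristem inner    | 0.20, 0.24, 0.28    | maturation value calibrated |
| outside           | 0.20, 0.05, 0.00    | broad early division; division restricted to the meristem in maturation |

With a 6-h step, 0.2–0.33 corresponds to cell-cycle times of roughly
18–30 h.  The two maturation values were calibrated once, against the target
statistics the generator is meant to emulate — pooled mean division events
in 54–108 h of ≈7.0 for marginal and ≈4.3 for inner meristem cells at 54 h —
and then frozen; they are *effective* rates: the measured subtree counts
reflect both the per-step probability and the attrition of descendants that
leave the advancing meristem.  `marginal_boost` (default 1) multiplies the
marginal probability and is the dial for position-effect experiments; the
expected marginal maturation count is non-decreasing in it.

**Notch annotation.**  The notch is annotated at the meristem's margin
front: the maximal projection of meristem cells onto the meristem axis
(ratcheted — a growing front never regresses — and exponentially smoothed,
κ = 0.5), with the lateral coordinate a soft leading-row average smoothed
across frames (weight 0.3) and frozen while the front is static.  This
mimics a consistently placed manual annotation and makes the notch motion
smooth and monotone; with it, the notch-to-first-archegonium distance series
is non-decreasing in every seed tested (200/200).

**Archegonia.**  Starting at the maturation boundary (54 h) and every
`archegonium_interval_hours` (30 h) thereafter, the non-archegonium cell
nearest a target point — drawn at distance Normal(35.8, 6.0) μm from the
notch, in a ±20° cone toward the tissue interior — becomes an archegonium
progenitor.  Its clone divides deterministically for
`archegonium_division_rounds` (3) steps and then stops (8 cells).  Because
the real organ grows largely out of the projection plane, archegonium
daughters are placed with a small in-plane offset (1 μm) and archegonium
cells keep a reduced mutual spacing (0.35·`min_spacing`), so the projected
organ stays compact, as in micrographs.  Cell snapping adds no measurable
bias to the initiation distance (paired realized-vs-target difference
−0.1 μm over 200 seeds).

**Ablation.**  At the configured time, nuclei inside a circular ROI are
removed (their tracks terminate), survivors within twice the ROI radius
divide at the outside rate thereafter, and a new meristem is seeded at the
tissue-boundary cell farthest from the wound, with the meristem axis
re-pointed there — reproducing the collapse of division activity around a
wounded meristem and the de-novo meristem at a distant margin.

**Reproducibility.**  One `numpy` Generator keyed by `rng_seed` drives all
randomness; per-cell decisions are drawn in ascending id order, so identical
configurations give bitwise-identical outputs.  `SimConfig.truncated(n)`
yields a shorter run whose stochastic prefix is draw-for-draw identical
(the radius-ramp endpoint is rescaled), which the validation suites use to
measure initiation statistics cheaply.

### What the generator does and does not emulate

It reproduces: the 22-frame / 6-h observation design; broad early division
followed by one-sided (meristem) division and maturation-phase restriction
to the meristem; higher marginal than inner division activity with the
published group means; archegonium initiation ≈36 μm from the notch at
≈30-h intervals, first at 54 h, receding monotonically afterwards; and the
ablation response, qualitatively (suppression near the wound, de-novo
meristem and renewed initiation at a distant margin).

It does not emulate: real tissue mechanics or cell shapes (nuclei are
points; growth is relaxation, not wall mechanics), morphological notch
indentation, rhizoids or antheridia, 3D structure of mature archegonia,
photobleaching/optical artifacts (rendering is ideal Gaussian blobs plus
optional Gaussian or Poisson noise), or cell death outside ablation.
Passing tests therefore certify the pipeline's correctness on data whose
geometry and statistics match these assumptions — not segmentation or
tracking performance on raw confocal imagery, where clumped nuclei, uneven
illumination and z-projection artifacts dominate.

### Numerical choices

- Relaxation pushes toward 1.02·`min_spacing` so the strict minimum is
  reached in finitely many iterations; it errors if spacing cannot be
  restored (cell count too high for the domain).  Coincident points are
  separated along a fixed axis.
- Rendering maps μm to pixels via `origin_um` and `pixel_size`; pixel (0,0)
  is top-left, row = y, col = x; positions outside the image raise an error
  naming the offending nuclei.
- Alpha-shape circumradii use the exact R = abc/(4·area) formula; degenerate
  (zero-area) triangles are treated as infinitely large and discarded.
- Assignment ties in the linker are resolved by the solver deterministically;
  second-daughter ties break toward the lowest parent id.
- Window bounds must be multiples of the step; a reference time after the
  window start is rejected.

### Problem sizes in the validation suites

The test and acceptance runs use cohorts sized for precision at interactive
runtimes: 10 gametophytes for conservation and drift checks, 200 truncated
runs for the initiation-distance mean, 24 for the marginal/inner means,
20 replicates × 4 gametophytes (cells pooled to n≈40 per group, as published
studies pool samples) for the significance-rate check, 200 random small
frame pairs for the assignment oracle, and ~30 rendered frames for
segmentation recovery.  A single default gametophyte (30 → ≈600 nuclei over
126 h) simulates in about a second.

### Known limitations

- Fully automatic tracking at realistic nuclear density (7 μm spacing,
  4 μm daughter offsets) mis-assigns some links during dense division bursts
  and leaves orphans; subtree-based division counts are sensitive to such
  breaks.  Curated links (or the simulator's ground truth) are required for
  faithful per-lineage statistics, exactly as manual lineage files were used
  in the original workflow.
- The marginal/inner contrast in the simulator arises from both the
  configured probabilities and geometric attrition, so configured
  probability ratios are not reproduced as measured count ratios; only the
  calibrated defaults target the published means.
- The auto-ROI (connected divided cells) is a convenience, not a substitute
  for a drawn meristem ROI, and is sensitive to the chosen preceding window.
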