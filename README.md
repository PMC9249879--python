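# fernlineage

Quantitative live-imaging analysis of fern gametophyte development.

Hermaphroditic gametophytes of the fern *Ceratopteris richardii* grow a flat
prothallus from a multicellular notch meristem, and differentiate
egg-producing archegonia next to the meristem notch.  Long-term time-lapse
confocal imaging of a nuclear reporter (one 2D maximum-intensity projection
every 6 h) makes it possible to follow every single cell: where it is, which
progenitor it descends from, when it divides, and how far the organs it
builds sit from the meristem.  `fernlineage` implements that analysis as a
reusable, tested pipeline:

1. **Nucleus segmentation** — marker-controlled watershed on the Euclidean
   distance transform of the thresholded projection, with h-maxima seeding,
   deterministic labelling, and scripted manual corrections
   (delete / merge / split).
2. **Lineage tracking** — optimal one-to-one assignment between consecutive
   frames (minimum total squared displacement, `scipy`'s Hungarian solver)
   plus a second-daughter pass that captures division events; manual link
   files override automatic links.  Links assemble into a lineage forest
   rooted at the progenitor cells of the first frame; clonal sectors get
   random per-lineage colors.
3. **Division quantification** — division events per cell and per lineage in
   half-open time windows (the developmental phases 0–24, 24–54 and
   54–108 h), divided/not-divided maps, blue→red division-activity maps,
   marginal-vs-inner classification of meristem cells (alpha-shape boundary
   of the tissue), and Student's two-tailed *t*-test between the groups.
4. **Archegonium geometry** — distance from the meristem notch to each
   archegonium center over time, initiation times, distances, and
   inter-initiation intervals.
5. **Synthetic prothallus** — an agent-based generator of growing
   gametophytes (point nuclei in the plane, phase- and position-dependent
   division, advancing meristem, archegonium initiation near the notch,
   optional in-silico ablation) that renders image stacks and exports full
   ground truth, so every stage of the pipeline can be validated against a
   known answer.

Because archegonia initiate at a characteristic distance from the notch
(≈36 μm) and at ≈30-h intervals, and marginal meristem cells divide more
often than inner ones (≈7 vs ≈4.3 events during the 54–108 h maturation
phase), the simulator's defaults are calibrated to reproduce exactly those
statistics — making the pipeline's quantitative output directly comparable
to published measurements.

## Worked example

```python
import numpy as np
from shapely.geometry import Point
from fernlineage import (SimConfig, simulate_prothallus, count_divisions, TimeWindow,
                         classify_zone, compare_marginal_inner, tracks_from_truth,
                         notches_from_truth, distance_series)

truth = simulate_prothallus(SimConfig(rng_seed=1))
print("frames:", truth.n_timepoints, "| progenitors:", len(truth.records_at(0)),
      "| final nuclei:", len(truth.records_at(21)), "| division events:",
      truth.division_event_count())

# maturation-phase division events of every cell alive at 54 h
forest = truth.true_forest()
counts = count_divisions(forest, reference_time=9, window=TimeWindow(54, 108))

# marginal vs inner meristem cells, from the drawn meristem ROI
row = truth.notches[truth.notches.t_index == 9].iloc[0]
roi = Point(row.meristem_x_um, row.meristem_y_um).buffer(row.meristem_radius_um)
zones = classify_zone(truth.records_at(9), meristem_roi=roi)
result, summary = compare_marginal_inner(counts, zones)
print(summary.to_string(index=False))
print(f"t = {result.t_statistic:.2f}, df = {result.degrees_of_freedom}, "
      f"p = {result.p_value:.2e}")

# the first archegonium recedes from the notch as the meristem advances
ds = distance_series(tracks_from_truth(truth)[0], notches_from_truth(truth))
print("first archegonium, distance to notch (um):",
      np.round(ds.distances()[:6], 1).tolist())
```

Output:

```
frames: 22 | progenitors: 30 | final nuclei: 562 | division events: 532
    zone  n_cells  mean_events  sd_events
marginal       11     7.636364   7.419875
   inner       44     4.659091   5.693502
t = 1.46, df = 53, p = 1.51e-01
first archegonium, distance to notch (um): [29.9, 37.1, 42.3, 48.2, 56.3, 65.9]
```

One simulated gametophyte grows from 30 progenitor cells to 562 nuclei over
126 h; the difference (532) equals the number of division events — every
division adds exactly one cell.  At 54 h its meristem holds 11 marginal and
44 inner cells whose clones average 7.6 and 4.7 division events during
maturation (a single gametophyte is underpowered for significance, which is
why studies pool cells across several samples).  The first archegonium
initiates ≈30 μm from the notch and recedes monotonically as the meristem
front advances.

## Command line

Each pipeline stage is also a subcommand of the `fernlineage` script
(`simulate`, `render`, `segment`, `track`, `quantify`, `zones`,
`distances`, `report`), reading and writing plain CSV/JSON/TIFF with schema
headers.  For example:

```sh
fernlineage simulate --out run/truth --seed 1
fernlineage render   --truth run/truth --out run/stack.tif
fernlineage segment  --stack run/stack.tif --out run/seg
fernlineage track    --nuclei run/seg/nuclei.csv --out run/links.csv
fernlineage quantify --nuclei run/seg/nuclei.csv --links run/links.csv \
                     --windows 0-24,24-54,54-108 --out run/quant
fernlineage report   --truth run/truth --out run/report
```

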