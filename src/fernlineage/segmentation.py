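"""Nucleus detection by watershed on the distance transform.

Each maximum-intensity-projection frame is smoothed, thresholded into a
foreground mask, and split into nuclei by a marker-controlled watershed of
the negated Euclidean distance transform, seeded at the h-maxima of the
distance map.  Labels are re-assigned consecutively in raster-scan order of
each region's top-left pixel so that identical input always yields identical
output.  Scripted manual corrections (delete / merge / split) reproduce the
hand-editing step of a curation workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegParams:
    """Watershed segmentation parameters.

    smooth_sigma
        Gaussian pre-smoothing in px (0 disables).
    threshold_method
        "otsu" or "fixed" (then ``fixed_threshold`` is used).
    h_maxima_depth
        Seed depth as a fraction of the maximum distance-transform value,
        in (0, 1); deeper (larger) values merge close seeds.
    min_area / max_area
        Area filter in px² applied after the watershed.
    """

    smooth_sigma: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    h_maxima_depth: float = 0.3
    min_area: int = 4
    max_area: int | None = None

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")
        if not 0.0 < self.h_maxima_depth < 1.0:
            raise ValueError("h_maxima_depth must be in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass
class LabelMap:
    """Consecutively labelled nuclei of one frame (background 0)."""

    labels: np.ndarray
    t_index: int = 0

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def region_pixels(self, label: int) -> np.ndarray:
        return np.argwhere(self.labels == label)


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus: centroid in px and μm, area in px²."""

    t_index: int
    id: int
    row: float
    col: float
    x_um: float
    y_um: float
    area: int


def max_project(stack3d: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (z) axis.

    2D input passes through unchanged; an empty stack is an error.
    """
    arr = np.asarray(stack3d)
    if arr.size == 0:
        raise ValueError("empty image stack")
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D image or 3D stack, got {arr.ndim}D")
    return arr.max(axis=0)


def _relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel regions 1..N in raster-scan order of each region's top-left
    pixel (first pixel encountered scanning rows then columns)."""
    out = np.zeros_like(labels, dtype=np.int32)
    old = np.unique(labels)
    old = old[old > 0]
    if len(old) == 0:
        return out
    # first linear index of each label = raster position of its top-left pixel
    flat = labels.ravel()
    first = {}
    for lin in np.flatnonzero(flat):
        lab = flat[lin]
        if lab not in first:
            first[lab] = lin
            if len(first) == len(old):
                break
    order = sorted(old, key=lambda lab: first[int(lab)])
    for new, lab in enumerate(order, start=1):
        out[labels == lab] = new
    return out


def segment_nuclei(image: np.ndarray, params: SegParams = SegParams()) -> LabelMap:
    """Segment all nuclei of one 2D frame.

    Pipeline: Gaussian smoothing → foreground threshold (Otsu or fixed) →
    Euclidean distance transform → h-maxima seeds at depth
    ``h_maxima_depth · max(distance)`` → watershed of the negated distance
    map within the mask → area filter → deterministic consecutive
    relabelling.  An all-background result is a valid empty LabelMap.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel 2D image")
    if params.smooth_sigma > 0:
        img = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)

    if params.threshold_method == "otsu":
        if np.allclose(img.min(), img.max()):
            return LabelMap(labels=np.zeros(img.shape, dtype=np.int32))
        thr = threshold_otsu(img)
    else:
        thr = params.fixed_threshold
    mask = img > thr
    if not mask.any():
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32))

    distance = ndi.distance_transform_edt(mask)
    depth = params.h_maxima_depth * float(distance.max())
    seeds = h_maxima(distance, depth)
    markers, n_seeds = ndi.label(seeds, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_seeds == 0:
        return LabelMap(labels=np.zeros(img.shape, dtype=np.int32))
    labels = watershed(-distance, markers=markers, mask=mask, connectivity=1)

    # Area filter.
    areas = np.bincount(labels.ravel())
    drop = np.zeros(len(areas), dtype=bool)
    drop[1:] = areas[1:] < params.min_area
    if params.max_area is not None:
        drop[1:] |= areas[1:] > params.max_area
    if drop.any():
        labels = np.where(drop[labels], 0, labels)
    return LabelMap(labels=_relabel_raster_order(labels))


def detect_centroids(lm: LabelMap, pixel_size: float = 1.0) -> list[NucleusRecord]:
    """One record per label: unweighted pixel-centroid, area, μm coordinates
    (x = col · pixel_size, y = row · pixel_size); ids equal labels."""
    records: list[NucleusRecord] = []
    labels = lm.labels
    if labels.max() == 0:
        return records
    idx = np.arange(1, labels.max() + 1)
    com = ndi.center_of_mass(np.ones_like(labels), labels, idx)
    areas = ndi.sum_labels(np.ones_like(labels), labels, idx)
    for lab, (r, c), a in zip(idx, com, areas):
        records.append(
            NucleusRecord(
                t_index=lm.t_index,
                id=int(lab),
                row=float(r),
                col=float(c),
                x_um=float(c) * pixel_size,
                y_um=float(r) * pixel_size,
                area=int(a),
            )
        )
    return records


def records_to_frame(records: Sequence[NucleusRecord]):
    """Tabular view (t_index, id, x_um, y_um, area) of detection records."""
    import pandas as pd

    return pd.DataFrame(
        [(r.t_index, r.id, r.x_um, r.y_um, r.area) for r in records],
        columns=["t_index", "id", "x_um", "y_um", "area"],
    )


# ---------------------------------------------------------------------------
# Scripted manual corrections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditDirective:
    """delete(t,id) | merge(t,id_a,id_b) | split(t,id,seed_1,seed_2)."""

    op: str
    t_index: int
    ids: tuple[int, ...]
    seeds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.op not in ("delete", "merge", "split"):
            raise ValueError(f"unknown edit op {self.op!r}")


@dataclass
class EditScript:
    """Ordered segmentation corrections, applied in script order."""

    directives: list[EditDirective] = field(default_factory=list)

    @classmethod
    def from_obj(cls, items: Sequence[dict]) -> "EditScript":
        ds = []
        for d in items:
            ds.append(
                EditDirective(
                    op=d["op"],
                    t_index=int(d.get("t", d.get("t_index", 0))),
                    ids=tuple(int(i) for i in (d["ids"] if "ids" in d else [d["id"]])),
                    seeds=tuple(tuple(int(v) for v in s) for s in d.get("seeds", [])),
                )
            )
        return cls(directives=ds)


def apply_edits(lm: LabelMap, script: EditScript) -> LabelMap:
    """Apply delete / merge / split corrections and relabel consecutively.

    Deletion zeroes a region; merge unions two regions under the lower id;
    split re-runs the watershed inside one region from two given seed
    pixels.  A directive naming a missing (t, id) raises with the directive
    index.
    """
    labels = lm.labels.copy()
    for k, d in enumerate(script.directives):
        if d.t_index != lm.t_index:
            raise ValueError(f"directive {k} targets t={d.t_index}, map is t={lm.t_index}")
        present = set(np.unique(labels).tolist())
        for i in d.ids:
            if i not in present:
                raise ValueError(f"directive {k} ({d.op}) references missing label {i}")
        if d.op == "delete":
            labels[labels == d.ids[0]] = 0
        elif d.op == "merge":
            a, b = sorted(d.ids[:2])
            labels[labels == b] = a
        elif d.op == "split":
            region = labels == d.ids[0]
            if len(d.seeds) != 2:
                raise ValueError(f"directive {k}: split needs exactly 2 seed points")
            markers = np.zeros_like(labels)
            for m, (r, c) in enumerate(d.seeds, start=1):
                if not region[r, c]:
                    raise ValueError(f"directive {k}: seed {(r, c)} outside region {d.ids[0]}")
                markers[r, c] = m
            distance = ndi.distance_transform_edt(region)
            sub = watershed(-distance, markers=markers, mask=region, connectivity=1)
            nxt = labels.max() + 1
            labels[sub == 1] = nxt
            labels[sub == 2] = nxt + 1
    return LabelMap(labels=_relabel_raster_order(labels), t_index=lm.t_index)
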