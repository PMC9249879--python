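"""Division-event quantification and position analysis.

Counts division events per cell and per lineage within half-open time
windows, renders divided/not-divided and division-activity maps, classifies
meristem cells as marginal (on the tissue boundary of the meristem region) or
inner, and compares the two groups with Student's two-tailed t-test.

A division at step t→t+1 is timestamped at the step-start hour, so the
developmental phase windows 0–24, 24–54 and 54–108 h partition the events
cleanly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiLineString, Polygon

from .tracking import LineageForest

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["t_index", "id", "root_id", "window_start_h", "window_end_h", "n_events"]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window [start_h, end_h) in hours."""

    start_h: float
    end_h: float

    def __post_init__(self) -> None:
        if not self.start_h < self.end_h:
            raise ValueError("start_h must be < end_h")

    def contains(self, hour: float) -> bool:
        return self.start_h <= hour < self.end_h

    def validate_step(self, step_hours: float) -> None:
        for v in (self.start_h, self.end_h):
            if abs(v / step_hours - round(v / step_hours)) > 1e-9:
                raise ValueError(f"window bound {v} h is not a multiple of {step_hours} h")


def count_divisions(
    forest: LineageForest, reference_time: int, window: TimeWindow
) -> pd.DataFrame:
    """Division events of each cell alive at ``reference_time``.

    For every cell alive at the reference frame, counts the division events
    (nodes with two children) in its own subtree whose step-start hour lies
    in the window.  Per-lineage totals are sums over cells sharing a root
    (see :func:`lineage_totals`).
    """
    if forest.hours(reference_time) > window.start_h:
        raise ValueError("reference_time must not be later than the window start")
    window.validate_step(forest.step_hours)
    rows = []
    for node in sorted(forest.alive_at(reference_time), key=lambda n: n.id):
        n_events = forest.subtree_division_count(node.key, window.start_h, window.end_h)
        rows.append((node.t_index, node.id, node.root_id, window.start_h, window.end_h, n_events))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def lineage_totals(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum division counts over cells sharing a progenitor (root)."""
    return (
        counts.groupby(["root_id", "window_start_h", "window_end_h"], as_index=False)["n_events"]
        .sum()
        .sort_values("root_id")
        .reset_index(drop=True)
    )


def divided_map(forest: LineageForest, window: TimeWindow) -> pd.DataFrame:
    """Boolean divided/not-divided layer at the window-start frame.

    A cell is flagged divided iff its subtree contains at least one division
    event inside the window; rendering shows divided cells magenta and the
    rest green at their window-start positions.
    """
    t_start = int(round(window.start_h / forest.step_hours))
    counts = count_divisions(forest, t_start, window)
    out = counts[["t_index", "id"]].copy()
    out["divided"] = counts["n_events"] > 0
    pos = {n.id: (n.x_um, n.y_um) for n in forest.alive_at(t_start)}
    out["x_um"] = [pos[i][0] for i in out["id"]]
    out["y_um"] = [pos[i][1] for i in out["id"]]
    return out


# ---------------------------------------------------------------------------
# Color scale and map rendering
# ---------------------------------------------------------------------------

_BLUE = np.array([0.0, 0.0, 1.0])
_RED = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class ColorScale:
    """Linear blue→red scale from 0 to ``max_value`` division events."""

    max_value: int

    def __post_init__(self) -> None:
        if self.max_value < 1:
            raise ValueError("max_value must be >= 1")

    @property
    def min_value(self) -> int:
        return 0

    def color(self, count: float) -> tuple[float, float, float]:
        f = min(max(count / self.max_value, 0.0), 1.0)
        return tuple((1.0 - f) * _BLUE + f * _RED)


def render_division_map(
    counts: pd.DataFrame,
    positions: Mapping[int, tuple[float, float]],
    scale: ColorScale,
    ax=None,
    dot_size: float = 30.0,
):
    """Dot map of division activity: one dot per cell at its window-start
    position, colored along the blue→red scale; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    missing = [int(i) for i in counts["id"] if int(i) not in positions]
    if missing:
        raise KeyError(f"no position for counted cell id(s) {missing}")
    if ax is None:
        _, ax = plt.subplots()
    xy = np.array([positions[int(i)] for i in counts["id"]], dtype=float)
    colors = [scale.color(c) for c in counts["n_events"]]
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=dot_size)
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    sm = plt.cm.ScalarMappable(
        cmap=plt.matplotlib.colors.LinearSegmentedColormap.from_list("div", [_BLUE, _RED]),
        norm=plt.matplotlib.colors.Normalize(vmin=0, vmax=scale.max_value),
    )
    ax.figure.colorbar(sm, ax=ax, label="division events")
    return ax


def render_divided_map(layer: pd.DataFrame, ax=None, dot_size: float = 30.0):
    """Magenta (divided) / green (not divided) dot map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    col = np.where(layer["divided"], "magenta", "green")
    ax.scatter(layer["x_um"], layer["y_um"], c=col, s=dot_size)
    ax.set_aspect("equal")
    return ax


# ---------------------------------------------------------------------------
# Marginal / inner classification (alpha-shape boundary)
# ---------------------------------------------------------------------------


def alpha_boundary_mask(points: np.ndarray, alpha: float, eps: float = 0.5) -> np.ndarray:
    """Boolean mask of points on the alpha-shape boundary of a 2D point set.

    The alpha shape keeps Delaunay triangles with circumradius < alpha; its
    boundary consists of edges belonging to exactly one kept triangle.  A
    point is boundary (marginal) if it lies within ``eps`` μm of the boundary
    polyline or belongs to no kept triangle.  With fewer than 3 points, or a
    degenerate collinear configuration, every point is boundary.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        return np.ones(n, dtype=bool)
    try:
        tri = Delaunay(points)
    except Exception:  # degenerate (collinear) input
        warnings.warn("degenerate point configuration: all points marked marginal")
        return np.ones(n, dtype=bool)

    simplices = tri.simplices
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    # Circumradius R = abc / (4 * area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area > 0, la * lb * lc / (4.0 * area), np.inf)
    kept = simplices[circumradius < alpha]

    mask = np.ones(n, dtype=bool)
    if len(kept) == 0:
        return mask

    edge_count: dict[tuple[int, int], int] = {}
    for s in kept:
        for i, j in ((0, 1), (1, 2), (0, 2)):
            e = (min(s[i], s[j]), max(s[i], s[j]))
            edge_count[e] = edge_count.get(e, 0) + 1
    boundary_edges = [e for e, cnt in edge_count.items() if cnt == 1]
    in_kept = np.zeros(n, dtype=bool)
    in_kept[np.unique(kept)] = True

    boundary = MultiLineString([(tuple(points[i]), tuple(points[j])) for i, j in boundary_edges])
    dist = shapely.distance(boundary, shapely.points(points))
    mask = (~in_kept) | (dist <= eps)
    return mask


@dataclass
class ZoneAssignment:
    """Per-cell marginal/inner/outside labels for one frame."""

    zones: dict[int, str]  # id -> marginal | inner | outside
    t_index: int
    provenance: str  # "manual" | "auto"
    alpha: float
    roi: Polygon | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.t_index, i, z) for i, z in sorted(self.zones.items())],
            columns=["t_index", "id", "zone"],
        )


def _median_nn_distance(points: np.ndarray) -> float:
    if len(points) < 2:
        return 1.0
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))


def classify_zone(
    records: pd.DataFrame,
    meristem_roi: Polygon | Sequence[tuple[float, float]] | None = None,
    alpha: float | None = None,
    *,
    eps: float = 0.5,
    divided: Mapping[int, bool] | None = None,
) -> ZoneAssignment:
    """Classify each cell of one frame as marginal, inner or outside.

    Cells outside the meristem ROI are ``outside``.  ROI cells lying on the
    tissue's outermost layer — within ``eps`` μm of the alpha-shape boundary
    of the whole frame's cell positions — are ``marginal``; the remaining
    (submarginal, enclosed) ROI cells are ``inner``.  ``alpha`` defaults to
    2.5× the median nearest-neighbor distance of the frame.

    If no ROI is given, an automatic ROI is built as the connected set of
    cells that divided in the preceding window (``divided`` mapping
    required), and provenance is recorded as "auto".
    """
    t_index = int(records["t_index"].iloc[0]) if "t_index" in records.columns and len(records) else 0
    ids = records["id"].to_numpy()
    pts = records[["x_um", "y_um"]].to_numpy(dtype=float)

    provenance = "manual"
    if meristem_roi is None:
        if divided is None:
            raise ValueError("an ROI polygon or a divided-cell mapping is required")
        provenance = "auto"
        meristem_roi = _auto_roi(ids, pts, divided)
    elif not isinstance(meristem_roi, Polygon):
        meristem_roi = Polygon(meristem_roi)

    inside = shapely.covers(meristem_roi, shapely.points(pts))
    if int(inside.sum()) < 3:
        raise ValueError("need at least 3 meristem cells to classify marginal vs inner")

    if alpha is None:
        alpha = 2.5 * _median_nn_distance(pts)
    boundary = alpha_boundary_mask(pts, alpha=alpha, eps=eps)

    zones: dict[int, str] = {}
    for i, ins, on_margin in zip(ids, inside, boundary):
        if not ins:
            zones[int(i)] = "outside"
        else:
            zones[int(i)] = "marginal" if on_margin else "inner"
    return ZoneAssignment(zones=zones, t_index=t_index, provenance=provenance, alpha=float(alpha), roi=meristem_roi)


def _auto_roi(ids: np.ndarray, pts: np.ndarray, divided: Mapping[int, bool]) -> Polygon:
    """ROI from the largest connected component of recently divided cells."""
    sel = np.array([bool(divided.get(int(i), False)) for i in ids])
    if sel.sum() < 3:
        raise ValueError("fewer than 3 divided cells; cannot build an automatic ROI")
    dpts = pts[sel]
    link = 2.5 * _median_nn_distance(dpts)
    tree = cKDTree(dpts)
    pairs = tree.query_pairs(link)
    # union-find over divided cells
    parent = list(range(len(dpts)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(len(dpts)):
        comps.setdefault(find(i), []).append(i)
    largest = max(comps.values(), key=len)
    hull = shapely.convex_hull(shapely.multipoints(dpts[largest]))
    return hull.buffer(1e-6) if hull.geom_type != "Polygon" else hull


# ---------------------------------------------------------------------------
# Student's t-test and the marginal vs inner comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def ttest_two_tailed(
    group_a: Sequence[float], group_b: Sequence[float], *, welch: bool = False
) -> TTestResult:
    """Student's two-tailed t-test (pooled variance; Welch behind a flag).

    With zero pooled variance, equal means give p = 1 by convention; unequal
    means are an error (the statistic is undefined).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TTestResult(0.0, df, 1.0, a.mean(), b.mean(), len(a), len(b))
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df_out = int(df) if not welch else int(np.floor(res.df))
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=df_out,
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
    )


def compare_marginal_inner(
    counts: pd.DataFrame, zones: ZoneAssignment | Mapping[int, str], *, welch: bool = False
) -> tuple[TTestResult, pd.DataFrame]:
    """Compare division counts of marginal vs inner meristem cells.

    Partitions the per-cell counts by zone label and returns the two-tailed
    t-test (marginal as group A) plus a per-group summary table.
    """
    zmap = zones.zones if isinstance(zones, ZoneAssignment) else dict(zones)
    lab = counts["id"].map(lambda i: zmap.get(int(i), "outside"))
    marginal = counts.loc[lab == "marginal", "n_events"].to_numpy(dtype=float)
    inner = counts.loc[lab == "inner", "n_events"].to_numpy(dtype=float)
    for name, grp in (("marginal", marginal), ("inner", inner)):
        if len(grp) == 0:
            raise ValueError(f"no cells in the {name} group")
    result = ttest_two_tailed(marginal, inner, welch=welch)
    summary = pd.DataFrame(
        {
            "zone": ["marginal", "inner"],
            "n_cells": [len(marginal), len(inner)],
            "mean_events": [marginal.mean(), inner.mean()],
            "sd_events": [np.std(marginal, ddof=1), np.std(inner, ddof=1)],
        }
    )
    return result, summary
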