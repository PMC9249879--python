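"""Archegonium geometry: initiation relative to the meristem notch.

The egg-producing archegonia initiate next to the meristem notch; this
module quantifies that relation from annotations (notch point per frame,
archegonium tracks) or directly from simulator ground truth: the distance
series of each archegonium center from the notch, initiation times and
distances, and inter-initiation intervals.  All distances are Euclidean in
the 2D projection plane, in μm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NotchAnnotation:
    """Notch point (x, y) μm per frame — the notch, or where it will form."""

    points: dict[int, tuple[float, float]]

    def at(self, t_index: int) -> tuple[float, float]:
        if t_index not in self.points:
            raise KeyError(f"no notch annotation for frame t={t_index}")
        return self.points[t_index]


@dataclass
class ArchegoniumTrack:
    """One archegonium: initiation frame and per-frame center point."""

    arch_id: int
    initiation_t: int
    centers: dict[int, tuple[float, float]]  # t_index -> (x, y) μm
    member_ids: dict[int, list[int]] = field(default_factory=dict)


@dataclass
class DistanceSeries:
    """Notch-to-archegonium distances over consecutive frames.

    Entries are (hours since initiation, distance μm); the first entry is at
    0 h since initiation.
    """

    arch_id: int
    entries: list[tuple[float, float]]

    def hours(self) -> np.ndarray:
        return np.array([h for h, _ in self.entries])

    def distances(self) -> np.ndarray:
        return np.array([d for _, d in self.entries])


def archegonium_center(members: pd.DataFrame | Sequence) -> tuple[float, float]:
    """Unweighted centroid of member-nucleus positions (manual annotations
    override this upstream where present)."""
    if isinstance(members, pd.DataFrame):
        if len(members) == 0:
            raise ValueError("empty archegonium member set")
        return (float(members["x_um"].mean()), float(members["y_um"].mean()))
    pts = np.asarray([(m[0], m[1]) if not hasattr(m, "x_um") else (m.x_um, m.y_um)
                      for m in members], dtype=float)
    if len(pts) == 0:
        raise ValueError("empty archegonium member set")
    return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def notch_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Euclidean distance (μm) between notch point a and archegonium
    center b, both in the same calibrated coordinate frame."""
    return float(np.hypot(b[0] - a[0], b[1] - a[1]))


def distance_series(track: ArchegoniumTrack, notches: NotchAnnotation,
                    step_hours: float = 6.0) -> DistanceSeries:
    """Distance per frame from initiation onward; requires a notch point for
    every covered frame."""
    entries = []
    for t in sorted(track.centers):
        if t < track.initiation_t:
            continue
        a = notches.at(t)
        d = notch_distance(a, track.centers[t])
        entries.append((step_hours * (t - track.initiation_t), d))
    return DistanceSeries(arch_id=track.arch_id, entries=entries)


def initiation_summary(
    tracks: Sequence[ArchegoniumTrack],
    notches: NotchAnnotation | Mapping[int, NotchAnnotation],
    step_hours: float = 6.0,
    sample_of: Mapping[int, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-archegonium initiation hour and distance, plus cross-sample
    means ± standard error (SE = sd/√n).

    ``notches`` may be one annotation set or a per-sample mapping (then
    ``sample_of`` maps arch_id → sample).  Returns (per-archegonium table,
    summary table).  Inter-initiation intervals are computed within each
    sample in order of initiation.
    """
    if not tracks:
        raise ValueError("at least one archegonium track is required")
    rows = []
    for tr in tracks:
        sample = sample_of.get(tr.arch_id, 0) if sample_of else 0
        ann = notches[sample] if isinstance(notches, Mapping) else notches
        d0 = notch_distance(ann.at(tr.initiation_t), tr.centers[tr.initiation_t])
        rows.append(
            {
                "sample": sample,
                "arch_id": tr.arch_id,
                "initiation_h": step_hours * tr.initiation_t,
                "initiation_distance_um": d0,
            }
        )
    per_arch = pd.DataFrame(rows).sort_values(["sample", "initiation_h"]).reset_index(drop=True)
    per_arch["order"] = per_arch.groupby("sample").cumcount() + 1
    per_arch["interval_h"] = per_arch.groupby("sample")["initiation_h"].diff()

    def mean_se(x: pd.Series) -> tuple[float, float, int]:
        x = x.dropna()
        n = len(x)
        se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(x.mean()), se, n

    summary_rows = []
    for order, grp in per_arch.groupby("order"):
        m, se, n = mean_se(grp["initiation_distance_um"])
        mh, seh, _ = mean_se(grp["initiation_h"])
        summary_rows.append(
            {
                "order": order,
                "n": n,
                "mean_initiation_h": mh,
                "se_initiation_h": seh,
                "mean_initiation_distance_um": m,
                "se_initiation_distance_um": se,
            }
        )
    mi, sei, ni = mean_se(per_arch["interval_h"])
    summary = pd.DataFrame(summary_rows)
    summary.attrs["mean_interval_h"] = mi
    summary.attrs["se_interval_h"] = sei
    summary.attrs["n_intervals"] = ni
    return per_arch, summary


# ---------------------------------------------------------------------------
# Extraction from simulator ground truth
# ---------------------------------------------------------------------------


def notches_from_truth(truth) -> NotchAnnotation:
    """Per-frame notch annotation from a GroundTruth notch series."""
    return NotchAnnotation(
        points={
            int(r.t_index): (float(r.x_um), float(r.y_um))
            for r in truth.notches.itertuples(index=False)
        }
    )


def tracks_from_truth(truth) -> list[ArchegoniumTrack]:
    """Archegonium tracks rebuilt from the simulator event log and forest.

    Members of each archegonium are the initiating cell and all its
    descendants; the center per frame is their unweighted centroid.
    """
    inits = [e for e in truth.events if e["type"] == "archegonium_initiation"]
    if not inits:
        return []
    forest = truth.true_forest()
    tracks = []
    for ev in inits:
        t0, cid = int(ev["t_index"]), int(ev["cell_id"])
        members_by_t: dict[int, list[int]] = {}
        for node in forest.iter_subtree((t0, cid)):
            members_by_t.setdefault(node.t_index, []).append(node.id)
        centers = {}
        for t, ids in members_by_t.items():
            recs = truth.records_at(t)
            sel = recs[recs["id"].isin(ids)]
            centers[t] = archegonium_center(sel)
        tracks.append(
            ArchegoniumTrack(
                arch_id=int(ev["arch_id"]),
                initiation_t=t0,
                centers=centers,
                member_ids=members_by_t,
            )
        )
    return tracks
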