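"""Cell lineage tracking across time-lapse frames.

Links nuclei between consecutive frames (optimal one-to-one assignment plus a
second-daughter pass for division capture), assembles the links into a lineage
forest rooted at the progenitor cells of the first frame, and assigns clonal
colors for lineage maps.

Coordinates are in microns throughout; frames are indexed by integer
``t_index`` with ``hours = step_hours * t_index``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

#: cost placed on forbidden (out-of-range) assignments; any total cost that
#: includes it exceeds any feasible all-valid matching.
_FORBIDDEN = 1.0e12

LINK_COLUMNS = ["t_from", "id_from", "t_to", "id_to"]


@dataclass(frozen=True)
class LinkParams:
    """Parameters of frame-to-frame linking.

    max_displacement
        Largest allowed nucleus displacement per step (μm).  Candidate pairs
        further apart are treated as unassignable.
    division_radius
        Radius (μm) within which an otherwise unmatched nucleus at t+1 may be
        attached as a second daughter of a nucleus at t; roughly one cell
        diameter.
    allow_unmatched_new
        If True, t+1 nuclei with no parent candidate become orphans (new
        roots) instead of raising; used when re-analysing ablated samples.
    """

    max_displacement: float = 15.0
    division_radius: float = 12.0
    allow_unmatched_new: bool = False

    def __post_init__(self) -> None:
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.division_radius <= 0:
            raise ValueError("division_radius must be > 0")


@dataclass
class LinkResult:
    """Links for one consecutive frame pair plus bookkeeping flags."""

    links: pd.DataFrame  # columns LINK_COLUMNS
    divisions: list[int] = field(default_factory=list)  # id_from with 2 children
    orphans: list[int] = field(default_factory=list)  # id_to with no parent
    terminated: list[int] = field(default_factory=list)  # id_from with no child


def _as_points(records) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with id/x_um/y_um columns or a sequence of records
    exposing .id and .x_um/.y_um; return (ids, positions)."""
    if isinstance(records, pd.DataFrame):
        ids = records["id"].to_numpy()
        pos = records[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        recs = list(records)
        ids = np.array([r.id for r in recs])
        pos = np.array([[r.x_um, r.y_um] for r in recs], dtype=float)
        if len(recs) == 0:
            pos = pos.reshape(0, 2)
    if len(ids) != len(set(ids.tolist())):
        raise ValueError("duplicate nucleus ids within one frame")
    return ids, pos


def link_frames(records_t, records_t1, params: LinkParams = LinkParams()) -> LinkResult:
    """Link nuclei of frame t to frame t+1.

    Pass 1 computes the one-to-one assignment minimising total squared
    displacement over pairs within ``max_displacement`` (pairs beyond it carry
    effectively infinite cost and are dropped from the solution).  Pass 2
    attaches every remaining t+1 nucleus, in ascending id order, as a second
    daughter to the nearest t nucleus within ``division_radius`` that has
    fewer than two children; a t nucleus with two children is one division
    event.  Leftover t+1 nuclei are orphans (error unless
    ``allow_unmatched_new``); childless t nuclei are flagged terminated.
    """
    ids0, pos0 = _as_points(records_t)
    ids1, pos1 = _as_points(records_t1)
    t_from = _frame_index(records_t, default=0)
    t_to = _frame_index(records_t1, default=t_from + 1)
    if t_to != t_from + 1:
        raise ValueError(f"frames are not consecutive: t={t_from} and t={t_to}")

    n0, n1 = len(ids0), len(ids1)
    children: dict[int, list[int]] = {int(i): [] for i in ids0}
    parent_of: dict[int, int] = {}

    if n0 and n1:
        diff = pos0[:, None, :] - pos1[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        cost = np.where(d2 <= params.max_displacement**2, d2, _FORBIDDEN)
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if cost[r, c] < _FORBIDDEN:
                children[int(ids0[r])].append(int(ids1[c]))
                parent_of[int(ids1[c])] = int(ids0[r])

    # Pass 2: second daughters.
    orphans: list[int] = []
    unmatched1 = sorted(int(i) for i in ids1 if int(i) not in parent_of)
    if unmatched1 and n0:
        idx0 = {int(i): k for k, i in enumerate(ids0)}
        pos1_by_id = {int(i): pos1[k] for k, i in enumerate(ids1)}
        for cid in unmatched1:
            p = pos1_by_id[cid]
            best = None
            for pid, kids in children.items():
                if len(kids) >= 2:
                    continue
                d = float(np.hypot(*(pos0[idx0[pid]] - p)))
                if d <= params.division_radius:
                    key = (d, pid)
                    if best is None or key < best[0]:
                        best = (key, pid)
            if best is None:
                orphans.append(cid)
            else:
                children[best[1]].append(cid)
                parent_of[cid] = best[1]
    elif unmatched1:
        orphans.extend(unmatched1)

    if orphans and not params.allow_unmatched_new:
        raise ValueError(
            f"unmatched new nuclei at t={t_to}: ids {orphans} "
            "(set allow_unmatched_new to accept them as new roots)"
        )

    rows_out = [
        (t_from, pid, t_to, cid)
        for pid in sorted(children)
        for cid in sorted(children[pid])
    ]
    links = pd.DataFrame(rows_out, columns=LINK_COLUMNS, dtype=int)
    divisions = sorted(pid for pid, kids in children.items() if len(kids) == 2)
    terminated = sorted(pid for pid, kids in children.items() if not kids)
    if terminated:
        logger.warning("t=%d: %d track(s) terminated: %s", t_from, len(terminated), terminated)
    return LinkResult(links=links, divisions=divisions, orphans=orphans, terminated=terminated)


def _frame_index(records, default: int) -> int:
    if isinstance(records, pd.DataFrame) and "t_index" in records.columns and len(records):
        vals = records["t_index"].unique()
        if len(vals) != 1:
            raise ValueError("records of one frame must share a single t_index")
        return int(vals[0])
    if not isinstance(records, pd.DataFrame):
        recs = list(records)
        if recs and hasattr(recs[0], "t_index"):
            vals = {r.t_index for r in recs}
            if len(vals) != 1:
                raise ValueError("records of one frame must share a single t_index")
            return int(vals.pop())
    return default


def merge_links(auto: pd.DataFrame, manual: pd.DataFrame) -> pd.DataFrame:
    """Overlay manually curated links on automatic ones.

    Every (t_to, id_to) present in the manual table replaces the automatic
    link for that nucleus; all other automatic links are kept.
    """
    manual = manual[LINK_COLUMNS].astype(int)
    keys = set(zip(manual["t_to"], manual["id_to"]))
    keep = ~auto.apply(lambda r: (r["t_to"], r["id_to"]) in keys, axis=1)
    merged = pd.concat([auto[keep], manual], ignore_index=True)
    return merged.sort_values(LINK_COLUMNS).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Lineage forest
# ---------------------------------------------------------------------------


@dataclass
class ForestNode:
    t_index: int
    id: int
    x_um: float
    y_um: float
    parent: tuple[int, int] | None = None
    children: list[tuple[int, int]] = field(default_factory=list)
    root_id: int = -1

    @property
    def key(self) -> tuple[int, int]:
        return (self.t_index, self.id)

    @property
    def is_division(self) -> bool:
        return len(self.children) == 2


class LineageForest:
    """Parent/child structure over all (t_index, id) nodes.

    Roots are the nuclei of the first frame plus any accepted orphans.  Every
    non-root node has exactly one parent at the previous t_index, and carries
    the ``root_id`` of its progenitor.
    """

    def __init__(self, step_hours: float = 6.0):
        self.step_hours = float(step_hours)
        self.nodes: dict[tuple[int, int], ForestNode] = {}
        self.roots: list[tuple[int, int]] = []

    # -- queries ------------------------------------------------------------

    def hours(self, t_index: int) -> float:
        return self.step_hours * t_index

    @property
    def t_max(self) -> int:
        return max(t for t, _ in self.nodes)

    def alive_at(self, t_index: int) -> list[ForestNode]:
        return [n for n in self.nodes.values() if n.t_index == t_index]

    def iter_subtree(self, key: tuple[int, int]) -> Iterable[ForestNode]:
        stack = [key]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(node.children)

    def subtree_division_count(self, key: tuple[int, int], start_h: float, end_h: float) -> int:
        """Number of division events in the subtree of ``key`` whose step-start
        hour falls in the half-open window [start_h, end_h)."""
        n = 0
        for node in self.iter_subtree(key):
            if node.is_division and start_h <= self.hours(node.t_index) < end_h:
                n += 1
        return n

    def division_events(self) -> list[ForestNode]:
        return [n for n in self.nodes.values() if n.is_division]

    # -- export -------------------------------------------------------------

    def to_json_obj(self) -> dict:
        return {
            "step_hours": self.step_hours,
            "nodes": [
                {
                    "t_index": n.t_index,
                    "id": n.id,
                    "x_um": n.x_um,
                    "y_um": n.y_um,
                    "parent": list(n.parent) if n.parent else None,
                    "root_id": n.root_id,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.key)
            ],
        }

    def to_newick(self, root_key: tuple[int, int]) -> str:
        """Newick string of one lineage tree; branch length = steps."""

        def fmt(key: tuple[int, int]) -> str:
            node = self.nodes[key]
            label = f"n{node.t_index}_{node.id}"
            if not node.children:
                return label
            inner = ",".join(fmt(c) + f":{c[0] - node.t_index}" for c in node.children)
            return f"({inner}){label}"

        return fmt(root_key) + ";"


def build_forest(
    links: pd.DataFrame,
    records_by_t: Mapping[int, pd.DataFrame],
    step_hours: float = 6.0,
) -> LineageForest:
    """Assemble the lineage forest from per-pair link rows and per-frame
    nucleus records (DataFrames with id/x_um/y_um columns)."""
    forest = LineageForest(step_hours=step_hours)
    for t, recs in sorted(records_by_t.items()):
        for row in recs.itertuples(index=False):
            key = (int(t), int(row.id))
            forest.nodes[key] = ForestNode(int(t), int(row.id), float(row.x_um), float(row.y_um))

    seen_child: set[tuple[int, int]] = set()
    for row in links.itertuples(index=False):
        pk = (int(row.t_from), int(row.id_from))
        ck = (int(row.t_to), int(row.id_to))
        if ck[0] != pk[0] + 1:
            raise ValueError(f"link {pk}->{ck} does not span consecutive frames")
        if pk not in forest.nodes or ck not in forest.nodes:
            missing = pk if pk not in forest.nodes else ck
            raise ValueError(f"link references missing record {missing}")
        if ck in seen_child:
            raise ValueError(f"nucleus {ck} has two parents")
        seen_child.add(ck)
        forest.nodes[ck].parent = pk
        forest.nodes[pk].children.append(ck)

    t0 = min(t for t, _ in forest.nodes)
    for key, node in sorted(forest.nodes.items()):
        if node.parent is None:
            forest.roots.append(key)
            node.root_id = node.id
            if node.t_index != t0:
                logger.warning("orphan nucleus %s treated as new root", key)
    # Propagate root ids depth-first from each root.
    for rk in forest.roots:
        rid = forest.nodes[rk].root_id
        for n in forest.iter_subtree(rk):
            n.root_id = rid
    return forest


# ---------------------------------------------------------------------------
# Clonal colors
# ---------------------------------------------------------------------------


@dataclass
class ColorAssignment:
    """Random, per-lineage distinct RGB colors (floats in [0, 1])."""

    colors: dict[int, tuple[float, float, float]]
    rng_seed: int

    def color_of_node(self, forest: LineageForest, key: tuple[int, int]):
        return self.colors[forest.nodes[key].root_id]


def assign_colors(forest: LineageForest, rng_seed: int = 0) -> ColorAssignment:
    """One distinct color per lineage root, drawn deterministically."""
    rng = np.random.default_rng(rng_seed)
    colors: dict[int, tuple[float, float, float]] = {}
    used: set[tuple[float, float, float]] = set()
    for rk in sorted(forest.roots):
        rid = forest.nodes[rk].root_id
        while True:
            c = tuple(np.round(rng.uniform(0.05, 0.95, size=3), 4))
            if c not in used:
                used.add(c)
                colors[rid] = c
                break
    return ColorAssignment(colors=colors, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Family trees (per-progenitor division genealogies)
# ---------------------------------------------------------------------------


def family_tree(
    forest: LineageForest,
    root_id: int,
    window: "tuple[float, float]",
    later_window: "tuple[float, float] | None" = None,
    zones: Mapping[tuple[int, int], str] | None = None,
) -> dict:
    """Genealogy of one progenitor restricted to a time window.

    Returns a nested dict tree (keys: node, children, and for nodes at the
    window-end frame an ``n_later_divisions`` annotation counting division
    events of that cell's own subtree within ``later_window``; a ``zone``
    annotation is attached wherever ``zones`` provides one).
    """
    root_key = None
    for rk in forest.roots:
        if forest.nodes[rk].root_id == root_id:
            root_key = rk
            break
    if root_key is None:
        raise KeyError(f"unknown root_id {root_id}")
    start_h, end_h = window
    t_end = int(round(end_h / forest.step_hours))

    def build(key: tuple[int, int]) -> dict:
        node = forest.nodes[key]
        out: dict = {"node": key, "children": []}
        if zones is not None and key in zones:
            out["zone"] = zones[key]
        if node.t_index == t_end:
            if later_window is not None:
                out["n_later_divisions"] = forest.subtree_division_count(
                    key, later_window[0], later_window[1]
                )
            else:
                out["n_later_divisions"] = 0
            return out
        for ck in node.children:
            if forest.hours(ck[0]) <= end_h:
                out["children"].append(build(ck))
        if not node.children and later_window is not None:
            out["n_later_divisions"] = forest.subtree_division_count(
                key, later_window[0], later_window[1]
            )
        elif not node.children:
            out["n_later_divisions"] = 0
        return out

    return build(root_key)
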