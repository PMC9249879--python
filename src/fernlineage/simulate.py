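"""Agent-based synthetic prothallus: ground-truth trajectories and rendered
nuclear-marker frames.

The generator emulates the statistical structure of a growing hermaphroditic
fern gametophyte imaged every 6 h: an initiation phase in which most cells
divide a few times, a transition phase in which division concentrates on one
lateral side (the forming meristem), and a maturation phase in which division
is restricted to the meristem, marginal meristem cells divide more often than
inner ones, archegonia initiate near the meristem notch at a characteristic
distance and interval, and an optional ablation removes cells and triggers
meristem re-initiation elsewhere.

Cells are point nuclei in the plane (μm).  Each step, every cell divides
with a probability set by its zone and the current phase; daughters are
placed at ±``daughter_offset`` along a random axis and a short repulsive
relaxation restores the minimum nucleus spacing.  The meristem is a
persistent circular sector anchored at the advancing margin on one lateral
side; its boundary cells (by the same alpha-shape test the analysis side
uses) are the marginal zone.  The notch is the inward-most point of the
meristem boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.spatial import cKDTree

from .division import _median_nn_distance, alpha_boundary_mask

logger = logging.getLogger(__name__)

NUCLEI_COLUMNS = ["t_index", "id", "x_um", "y_um", "parent_id", "root_id", "zone", "cell_type"]
LINK_COLUMNS = ["t_from", "id_from", "t_to", "id_to"]

#: sentinel for "no parent" in the nuclei table
NO_PARENT = -1


class RelaxationError(RuntimeError):
    """Raised when cell spacing cannot be restored (cell count too high)."""


class DomainOverflowError(ValueError):
    """Raised when simulated positions fall outside the rendering image."""


@dataclass(frozen=True)
class AblationSpec:
    """In-silico micro-needle ablation: a circular ROI removed at one time."""

    time_h: float
    center: tuple[float, float]
    radius_um: float


@dataclass
class SimConfig:
    """Parameters of the synthetic prothallus.

    Division probabilities are per-step values in [0, 1], one per
    developmental phase (initiation, transition, maturation); phase
    boundaries default to 24 h and 54 h.  The meristem radius ramps linearly
    in time from ``meristem_radius_start`` to ``meristem_radius_end`` as the
    meristem proliferates.  Distances in μm, times in hours.
    """

    step_hours: float = 6.0
    n_timepoints: int = 22
    phase_boundaries: tuple[float, float] = (24.0, 54.0)
    p_div_meristem_marginal: tuple[float, float, float] = (0.20, 0.30, 0.33)
    p_div_meristem_inner: tuple[float, float, float] = (0.20, 0.24, 0.28)
    p_div_outside: tuple[float, float, float] = (0.20, 0.05, 0.0)
    marginal_boost: float = 1.0
    min_spacing: float = 7.0
    daughter_offset: float = 4.0
    n_initial: int = 30
    initial_spacing: float = 12.0
    meristem_radius_start: float = 20.0
    meristem_radius_end: float = 90.0
    archegonium_init_distance_mean: float = 35.8
    archegonium_init_distance_sd: float = 6.0
    archegonium_interval_hours: float = 30.0
    archegonium_division_rounds: int = 3
    max_archegonia: int | None = None  # cap on initiations (0 disables)
    ablation: AblationSpec | None = None
    rng_seed: int = 0
    relax_iterations: int = 10

    def __post_init__(self) -> None:
        for name in ("p_div_meristem_marginal", "p_div_meristem_inner", "p_div_outside"):
            probs = tuple(float(p) for p in getattr(self, name))
            if len(probs) != 3 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"{name} must be three per-phase probabilities in [0, 1]")
            object.__setattr__(self, name, probs)
        pb = tuple(float(b) for b in self.phase_boundaries)
        total = self.step_hours * (self.n_timepoints - 1)
        if not (pb[0] < pb[1] < total):
            raise ValueError("phase_boundaries must be strictly increasing and < total duration")
        object.__setattr__(self, "phase_boundaries", pb)
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be > 0")
        if self.marginal_boost < 1.0:
            raise ValueError("marginal_boost must be >= 1")
        if isinstance(self.ablation, dict):
            object.__setattr__(self, "ablation", AblationSpec(**self.ablation))

    def phase_of(self, hour: float) -> int:
        if hour < self.phase_boundaries[0]:
            return 0
        if hour < self.phase_boundaries[1]:
            return 1
        return 2

    def meristem_radius_at(self, t_index: int) -> float:
        frac = t_index / max(self.n_timepoints - 1, 1)
        return self.meristem_radius_start + frac * (
            self.meristem_radius_end - self.meristem_radius_start
        )

    def truncated(self, n_timepoints: int) -> "SimConfig":
        """Config generating exactly the first ``n_timepoints`` frames of
        this run (the radius-ramp endpoint is rescaled so the per-frame
        radius, and hence the whole stochastic process, is unchanged over
        the shared frames)."""
        if not 2 <= n_timepoints <= self.n_timepoints:
            raise ValueError("truncation must keep 2..n_timepoints frames")
        frac = (n_timepoints - 1) / (self.n_timepoints - 1)
        end = self.meristem_radius_start + frac * (
            self.meristem_radius_end - self.meristem_radius_start
        )
        return dataclasses.replace(
            self, n_timepoints=n_timepoints, meristem_radius_end=end
        )


@dataclass
class GroundTruth:
    """Full simulator output: per-frame nuclei, links, event log, notch
    series and the configuration that produced them."""

    nuclei: pd.DataFrame
    links: pd.DataFrame
    events: list[dict]
    notches: pd.DataFrame  # t_index, x_um, y_um, meristem_x_um, meristem_y_um, meristem_radius_um
    config: SimConfig

    def records_at(self, t_index: int) -> pd.DataFrame:
        return self.nuclei[self.nuclei["t_index"] == t_index].reset_index(drop=True)

    def records_by_t(self) -> dict[int, pd.DataFrame]:
        return {int(t): g.reset_index(drop=True) for t, g in self.nuclei.groupby("t_index")}

    @property
    def n_timepoints(self) -> int:
        if len(self.nuclei) == 0:
            return self.config.n_timepoints
        return int(self.nuclei["t_index"].max()) + 1

    def division_event_count(self) -> int:
        return sum(1 for e in self.events if e["type"] == "division")

    def true_forest(self):
        from .tracking import build_forest

        return build_forest(self.links, self.records_by_t(), step_hours=self.config.step_hours)

    def true_zones_at(self, t_index: int) -> dict[int, str]:
        recs = self.records_at(t_index)
        out = {}
        for row in recs.itertuples(index=False):
            z = {"meristem_marginal": "marginal", "meristem_inner": "inner"}.get(row.zone, "outside")
            out[int(row.id)] = z
        return out


@dataclass
class _Cell:
    id: int
    pos: np.ndarray  # (2,) μm
    root_id: int
    parent_id: int  # NO_PARENT for progenitors and continuations
    arch_id: int = -1  # archegonium membership (-1: none)
    arch_gen: int = 0  # rounds of division since archegonium initiation


def _hex_layout(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Roughly circular patch of n points on a jittered hexagonal grid."""
    pts = []
    m = int(np.ceil(np.sqrt(n))) + 3
    for r in range(-m, m + 1):
        for c in range(-m, m + 1):
            x = spacing * (c + 0.5 * (r % 2))
            y = spacing * (np.sqrt(3) / 2.0) * r
            pts.append((x, y))
    pts = np.array(pts)
    order = np.argsort(np.hypot(pts[:, 0], pts[:, 1]), kind="stable")
    sel = pts[order[:n]]
    return sel + rng.normal(0.0, 0.4, size=sel.shape)


#: mutual-spacing factor for cells of the same archegonium: the organ grows
#: as a compact, partly out-of-plane structure, so its nuclei cluster far
#: more densely in 2D projection than prothallus nuclei
ARCH_SPACING_FACTOR = 0.35

#: in-plane placement offset (μm) for archegonium daughters, much smaller
#: than for prothallus cells (archegonium divisions are largely out-of-plane)
ARCH_DAUGHTER_OFFSET = 1.0


def _relax(
    positions: np.ndarray,
    min_spacing: float,
    iterations: int,
    groups: np.ndarray | None = None,
    max_extra: int = 4990,
) -> np.ndarray:
    """Pairwise spring pushes restoring the minimum nucleus spacing.

    Pairs within the same group (same archegonium) use a reduced minimum,
    ``ARCH_SPACING_FACTOR``·min_spacing.  Each iteration pushes every
    too-close pair apart toward a target 2% above its minimum (so the strict
    minimum is reached in finitely many steps rather than asymptotically).
    Runs the configured number of iterations and keeps going (up to a hard
    cap) while violations persist; raises RelaxationError if spacing cannot
    be restored.
    """
    pos = positions.copy()
    n = len(pos)
    if n < 2:
        return pos
    for _ in range(iterations + max_extra):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(1.02 * min_spacing, output_type="ndarray")
        if len(pairs) == 0:
            return pos
        if groups is not None:
            same = (groups[pairs[:, 0]] == groups[pairs[:, 1]]) & (groups[pairs[:, 0]] >= 0)
            s_pair = np.where(same, ARCH_SPACING_FACTOR * min_spacing, min_spacing)
        else:
            s_pair = np.full(len(pairs), min_spacing)
        delta = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dist = np.linalg.norm(delta, axis=1)
        if not (dist < s_pair).any():
            return pos
        zero = dist < 1e-12
        if zero.any():
            # coincident points: push along a deterministic axis
            delta[zero] = np.array([1.0, 0.0])
            dist[zero] = 1e-12
        target = 1.02 * s_pair
        push = np.where(dist < target, 0.5 * (target - dist), 0.0)
        vec = delta / dist[:, None] * push[:, None]
        move = np.zeros_like(pos)
        np.add.at(move, pairs[:, 0], vec)
        np.add.at(move, pairs[:, 1], -vec)
        pos += move
    raise RelaxationError(
        "could not restore minimum nucleus spacing; cell count too high for the domain"
    )


def simulate_prothallus(config: SimConfig) -> GroundTruth:
    """Run the agent-based growth model and return full ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    cells: list[_Cell] = []
    pts = _hex_layout(config.n_initial, config.initial_spacing, rng)
    for i, p in enumerate(pts):
        cells.append(_Cell(id=i, pos=np.asarray(p, dtype=float), root_id=i, parent_id=NO_PARENT))
    next_id = config.n_initial
    next_arch_id = 0

    # Meristem anchored at the +x margin; after ablation the axis is re-seeded.
    axis = np.array([1.0, 0.0])
    anchor = max(cells, key=lambda c: float(c.pos @ axis)).pos.copy()

    nuclei_rows: list[tuple] = []
    link_rows: list[tuple] = []
    events: list[dict] = []
    notch_rows: list[tuple] = []

    next_init_h = config.phase_boundaries[1]
    ablated = False
    abl = config.ablation
    prev_notch_fl: tuple[float, float] | None = None  # (front, lateral) smoothing state

    for t in range(config.n_timepoints):
        hours = config.step_hours * t

        positions = np.array([c.pos for c in cells])
        # Track the advancing margin: anchor follows the furthest cell along
        # the meristem axis among cells near the previous anchor.
        radius = config.meristem_radius_at(t)
        near = [
            c
            for c in cells
            if c.arch_id < 0 and float(np.hypot(*(c.pos - anchor))) <= radius
        ]
        if near:
            anchor = max(near, key=lambda c: float(c.pos @ axis)).pos.copy()
        meristem = [
            c for c in cells if c.arch_id < 0 and float(np.hypot(*(c.pos - anchor))) <= radius
        ]
        meristem_ids = {c.id for c in meristem}

        # Notch: the meristem's margin front — the most advanced meristem
        # cell along the meristem axis.  The front advances monotonically as
        # the meristem proliferates, so archegonia left behind in the tissue
        # recede from it, as observed in vivo.
        centroid = positions.mean(axis=0)
        notch = anchor.copy()
        marginal_ids: set[int] = set()
        # Marginal = meristem cells on the tissue's outermost layer (alpha
        # boundary of the whole cell set); enclosed meristem cells are inner.
        tissue_boundary = alpha_boundary_mask(
            positions, alpha=2.5 * _median_nn_distance(positions)
        )
        on_margin = {c.id for c, b in zip(cells, tissue_boundary) if b}
        if len(meristem) >= 3:
            mpts = np.array([c.pos for c in meristem])
            marginal_ids = meristem_ids & on_margin
            # Front position along the axis (ratcheted: the front of a
            # growing meristem never regresses), lateral position as a soft
            # leading-row average smoothed across frames — a stable notch
            # annotation robust to single-cell rearrangements.
            proj = mpts @ axis
            front = float(proj.max())
            w = np.exp((proj - front) / 5.0)
            lateral = axis[::-1] * np.array([-1.0, 1.0])  # 90° ccw normal
            lat_mean = float((mpts @ lateral * w).sum() / w.sum())
            if prev_notch_fl is not None:
                pf, pl = prev_notch_fl
                if front <= pf + 1e-9:
                    # static front: the notch annotation does not move
                    front, lat_mean = pf, pl
                else:
                    # exponential smoothing turns bursty per-step growth into
                    # a steady, strictly advancing annotation
                    front = pf + 0.5 * (front - pf)
                    lat_mean = 0.7 * pl + 0.3 * lat_mean
            prev_notch_fl = (front, lat_mean)
            notch = front * axis + lat_mean * lateral
        elif meristem:
            marginal_ids = meristem_ids

        # Archegonium initiation: starting in the maturation phase, one new
        # archegonium per interval, at the non-archegonium cell nearest a
        # target point drawn around the configured distance from the notch.
        while (
            hours >= next_init_h
            and next_init_h <= config.step_hours * (config.n_timepoints - 1)
            and (config.max_archegonia is None or next_arch_id < config.max_archegonia)
        ):
            d = max(0.0, rng.normal(config.archegonium_init_distance_mean,
                                    config.archegonium_init_distance_sd))
            inward = centroid - notch
            norm = np.linalg.norm(inward)
            inward = inward / norm if norm > 0 else -axis
            theta = rng.uniform(-np.pi / 9.0, np.pi / 9.0)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            target = notch + d * (rot @ inward)
            candidates = [c for c in cells if c.arch_id < 0]
            if not candidates:
                break
            chosen = min(candidates, key=lambda c: float(np.hypot(*(c.pos - target))))
            chosen.arch_id = next_arch_id
            chosen.arch_gen = 0
            meristem_ids.discard(chosen.id)
            marginal_ids.discard(chosen.id)
            realized = float(np.hypot(*(chosen.pos - notch)))
            events.append(
                {
                    "type": "archegonium_initiation",
                    "t_index": t,
                    "hours": float(hours),
                    "arch_id": int(next_arch_id),
                    "cell_id": int(chosen.id),
                    "notch_um": [float(notch[0]), float(notch[1])],
                    "target_distance_um": float(d),
                    "distance_um": realized,
                }
            )
            next_arch_id += 1
            next_init_h += config.archegonium_interval_hours

        notch_rows.append(
            (t, float(notch[0]), float(notch[1]), float(anchor[0]), float(anchor[1]), float(radius))
        )

        # Record this frame.
        for c in sorted(cells, key=lambda c: c.id):
            if c.arch_id >= 0:
                zone, ctype = "outside", "archegonium"
            elif c.id in meristem_ids:
                zone = "meristem_marginal" if c.id in marginal_ids else "meristem_inner"
                ctype = "meristem"
            else:
                zone, ctype = "outside", "prothallus"
            nuclei_rows.append(
                (t, c.id, float(c.pos[0]), float(c.pos[1]), c.parent_id, c.root_id, zone, ctype)
            )

        if t == config.n_timepoints - 1:
            break

        # Ablation: remove the ROI, suppress its surroundings, re-seed the
        # meristem at the margin cell farthest from the wound.
        if abl is not None and not ablated and hours >= abl.time_h:
            ablated = True
            center = np.asarray(abl.center, dtype=float)
            removed = [c for c in cells if float(np.hypot(*(c.pos - center))) <= abl.radius_um]
            cells = [c for c in cells if c not in removed]
            if not cells:
                raise ValueError("ablation removed every cell")
            events.append(
                {
                    "type": "ablation",
                    "t_index": t,
                    "hours": float(hours),
                    "center_um": [float(center[0]), float(center[1])],
                    "radius_um": float(abl.radius_um),
                    "removed": [int(c.id) for c in removed],
                }
            )
            surv = np.array([c.pos for c in cells])
            bmask = alpha_boundary_mask(surv, alpha=2.5 * _median_nn_distance(surv))
            bidx = np.flatnonzero(bmask)
            far = bidx[np.argmax(np.linalg.norm(surv[bidx] - center, axis=1))]
            anchor = cells[int(far)].pos.copy()
            tissue_centroid = surv.mean(axis=0)
            newaxis = anchor - tissue_centroid
            nn = np.linalg.norm(newaxis)
            axis = newaxis / nn if nn > 0 else axis
            prev_notch_fl = None  # notch smoothing restarts along the new axis
            meristem_ids = {
                c.id
                for c in cells
                if c.arch_id < 0 and float(np.hypot(*(c.pos - anchor))) <= radius
            }
            surv_margin = {c.id for c, b in zip(cells, bmask) if b}
            marginal_ids = meristem_ids & surv_margin or set(meristem_ids)

        # Divisions, ascending id for reproducibility.
        phase = config.phase_of(hours)
        new_cells: list[_Cell] = []
        for c in sorted(cells, key=lambda c: c.id):
            if c.arch_id >= 0:
                p = 1.0 if c.arch_gen < config.archegonium_division_rounds else 0.0
            elif ablated and abl is not None and float(
                np.hypot(*(c.pos - np.asarray(abl.center)))
            ) <= 2.0 * abl.radius_um:
                p = config.p_div_outside[phase]
            elif c.id in meristem_ids:
                if c.id in marginal_ids:
                    p = min(1.0, config.p_div_meristem_marginal[phase] * config.marginal_boost)
                else:
                    p = config.p_div_meristem_inner[phase]
            else:
                p = config.p_div_outside[phase]

            if rng.uniform() < p:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                u = np.array([np.cos(theta), np.sin(theta)])
                offset = ARCH_DAUGHTER_OFFSET if c.arch_id >= 0 else config.daughter_offset
                d1 = _Cell(
                    id=next_id,
                    pos=c.pos + offset * u,
                    root_id=c.root_id,
                    parent_id=c.id,
                    arch_id=c.arch_id,
                    arch_gen=c.arch_gen + 1 if c.arch_id >= 0 else 0,
                )
                d2 = _Cell(
                    id=next_id + 1,
                    pos=c.pos - offset * u,
                    root_id=c.root_id,
                    parent_id=c.id,
                    arch_id=c.arch_id,
                    arch_gen=c.arch_gen + 1 if c.arch_id >= 0 else 0,
                )
                next_id += 2
                new_cells.extend([d1, d2])
                link_rows.append((t, c.id, t + 1, d1.id))
                link_rows.append((t, c.id, t + 1, d2.id))
                events.append(
                    {
                        "type": "division",
                        "t_index": t,
                        "hours": float(hours),
                        "parent": int(c.id),
                        "children": [int(d1.id), int(d2.id)],
                    }
                )
            else:
                cont = _Cell(
                    id=c.id, pos=c.pos.copy(), root_id=c.root_id, parent_id=NO_PARENT,
                    arch_id=c.arch_id, arch_gen=c.arch_gen,
                )
                new_cells.append(cont)
                link_rows.append((t, c.id, t + 1, c.id))

        pos = np.array([c.pos for c in new_cells])
        grp = np.array([c.arch_id for c in new_cells])
        pos = _relax(pos, config.min_spacing, config.relax_iterations, groups=grp)
        for c, p in zip(new_cells, pos):
            c.pos = p
        cells = new_cells

    nuclei = pd.DataFrame(nuclei_rows, columns=NUCLEI_COLUMNS)
    links = pd.DataFrame(link_rows, columns=LINK_COLUMNS, dtype=int)
    notches = pd.DataFrame(
        notch_rows,
        columns=["t_index", "x_um", "y_um", "meristem_x_um", "meristem_y_um", "meristem_radius_um"],
    )
    logger.info(
        "simulated %d frames, %d final nuclei, %d division events (seed %d)",
        config.n_timepoints,
        int((nuclei["t_index"] == config.n_timepoints - 1).sum()),
        sum(1 for e in events if e["type"] == "division"),
        config.rng_seed,
    )
    return GroundTruth(nuclei=nuclei, links=links, events=events, notches=notches, config=config)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


@dataclass
class RenderConfig:
    """How nuclei are drawn: isotropic Gaussian blobs on a background.

    Pixel (0, 0) is top-left; row = y, col = x, both 0-based:
    col = (x_um - origin_x) / pixel_size, row = (y_um - origin_y) / pixel_size.
    """

    pixel_size: float = 1.0  # μm / px
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    blob_sigma: float = 2.0  # px
    peak_intensity: float = 1000.0
    background_level: float = 100.0
    noise_model: str = "none"  # none | gaussian | poisson
    noise_scale: float = 0.0
    origin_um: tuple[float, float] = (0.0, 0.0)  # maps to pixel (0, 0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.blob_sigma <= 0:
            raise ValueError("pixel_size and blob_sigma must be > 0")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none, gaussian or poisson")


def auto_render_config(truth: GroundTruth, pixel_size: float = 1.0, margin_um: float = 20.0,
                       **kwargs) -> RenderConfig:
    """RenderConfig whose origin and shape cover every simulated position."""
    x = truth.nuclei["x_um"]
    y = truth.nuclei["y_um"]
    ox = float(x.min() - margin_um)
    oy = float(y.min() - margin_um)
    cols = int(np.ceil((x.max() + margin_um - ox) / pixel_size)) + 1
    rows = int(np.ceil((y.max() + margin_um - oy) / pixel_size)) + 1
    return RenderConfig(pixel_size=pixel_size, image_shape=(rows, cols),
                        origin_um=(ox, oy), **kwargs)


def render_frames(truth: GroundTruth, rc: RenderConfig) -> np.ndarray:
    """Render one 16-bit frame per time point; returns (T, rows, cols)."""
    rows, cols = rc.image_shape
    rng = np.random.default_rng(rc.rng_seed)
    stack = np.zeros((truth.n_timepoints, rows, cols), dtype=np.float64)
    half = int(np.ceil(4.0 * rc.blob_sigma))
    rr_patch, cc_patch = np.mgrid[-half : half + 1, -half : half + 1]

    offenders = []
    for row in truth.nuclei.itertuples(index=False):
        c = (row.x_um - rc.origin_um[0]) / rc.pixel_size
        r = (row.y_um - rc.origin_um[1]) / rc.pixel_size
        if not (0 <= r < rows and 0 <= c < cols):
            offenders.append((int(row.t_index), int(row.id), float(row.x_um), float(row.y_um)))
            continue
        r0, c0 = int(round(r)), int(round(c))
        blob = rc.peak_intensity * np.exp(
            -(((rr_patch + r0 - r) ** 2) + ((cc_patch + c0 - c) ** 2)) / (2.0 * rc.blob_sigma**2)
        )
        rlo, rhi = max(0, r0 - half), min(rows, r0 + half + 1)
        clo, chi = max(0, c0 - half), min(cols, c0 + half + 1)
        stack[int(row.t_index), rlo:rhi, clo:chi] += blob[
            rlo - (r0 - half) : rhi - (r0 - half), clo - (c0 - half) : chi - (c0 - half)
        ]
    if offenders:
        raise DomainOverflowError(
            f"{len(offenders)} nucleus position(s) fall outside the image "
            f"(first few: {offenders[:5]}); use a larger image_shape or adjust origin_um"
        )
    stack += rc.background_level
    if rc.noise_model == "gaussian":
        stack = stack + rng.normal(0.0, rc.noise_scale, size=stack.shape)
    elif rc.noise_model == "poisson":
        gain = rc.noise_scale if rc.noise_scale > 0 else 1.0
        stack = rng.poisson(np.clip(stack, 0, None) * gain).astype(np.float64) / gain
    return np.clip(stack, 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# Ground-truth export / import
# ---------------------------------------------------------------------------


def export_ground_truth(truth: GroundTruth, directory: str | Path) -> dict[str, Path]:
    """Write nuclei.csv, links.csv, events.json and simconfig.yaml."""
    from . import io as flio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "nuclei": directory / "nuclei.csv",
        "links": directory / "links.csv",
        "events": directory / "events.json",
        "config": directory / "simconfig.yaml",
    }
    flio.write_table(truth.nuclei, paths["nuclei"], schema="nuclei")
    flio.write_table(truth.links, paths["links"], schema="links")
    payload = {
        "schema": "fernlineage/events v1",
        "events": truth.events,
        "notches": truth.notches.to_dict(orient="records"),
    }
    paths["events"].write_text(json.dumps(payload, indent=1))
    cfg = dataclasses.asdict(truth.config)
    if cfg.get("ablation") is not None:
        cfg["ablation"] = dataclasses.asdict(truth.config.ablation)
    paths["config"].write_text(yaml.safe_dump({"schema": "fernlineage/simconfig v1", **_listify(cfg)}))
    return paths


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj


def read_ground_truth(directory: str | Path) -> GroundTruth:
    """Read back a ground-truth directory written by export_ground_truth."""
    from . import io as flio

    directory = Path(directory)
    nuclei = flio.read_table(directory / "nuclei.csv")
    links = flio.read_table(directory / "links.csv").astype(int)
    payload = json.loads((directory / "events.json").read_text())
    notches = pd.DataFrame(payload["notches"])
    cfg = yaml.safe_load((directory / "simconfig.yaml").read_text())
    cfg.pop("schema", None)
    for key in ("phase_boundaries", "p_div_meristem_marginal", "p_div_meristem_inner",
                "p_div_outside"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    if cfg.get("ablation") is not None:
        ab = cfg["ablation"]
        ab["center"] = tuple(ab["center"])
        cfg["ablation"] = AblationSpec(**ab)
    config = SimConfig(**cfg)
    nuclei = nuclei.astype(
        {"t_index": int, "id": int, "parent_id": int, "root_id": int,
         "x_um": float, "y_um": float, "zone": str, "cell_type": str}
    )
    return GroundTruth(nuclei=nuclei, links=links, events=payload["events"], notches=notches,
                       config=config)


def write_frames(stack: np.ndarray, path: str | Path) -> Path:
    """Write a rendered stack as a multi-page 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, stack)
    return path
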