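import logging

import numpy as np
import pandas as pd
import pytest

from fernlineage import SimConfig, simulate_prothallus
from fernlineage.tracking import build_forest

logging.getLogger("fernlineage").setLevel(logging.ERROR)


def sparse_config(seed: int, n_timepoints: int = 8) -> SimConfig:
    """Well-separated, slowly dividing tissue: nuclei stay >= 10 μm apart and
    per-step motion is small, so detection and linking are unambiguous."""
    return SimConfig(
        rng_seed=seed,
        n_initial=25,
        initial_spacing=20.0,
        min_spacing=10.0,
        daughter_offset=3.0,
        n_timepoints=n_timepoints,
        archegonium_division_rounds=0,
        p_div_meristem_marginal=(0.12, 0.12, 0.12),
        p_div_meristem_inner=(0.12, 0.12, 0.12),
        p_div_outside=(0.12, 0.12, 0.12),
        phase_boundaries=(12.0, 24.0),
    )


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition simulated gametophyte (22 frames, 6-h steps)."""
    return simulate_prothallus(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_forest(default_truth):
    return default_truth.true_forest()


def forest_from_rows(node_rows, link_rows, step_hours=6.0):
    """Build a LineageForest from (t, id, x, y) node tuples and
    (t_from, id_from, t_to, id_to) link tuples."""
    records = {}
    for t, i, x, y in node_rows:
        records.setdefault(t, []).append((t, i, x, y))
    by_t = {
        t: pd.DataFrame(rows, columns=["t_index", "id", "x_um", "y_um"])
        for t, rows in records.items()
    }
    links = pd.DataFrame(link_rows, columns=["t_from", "id_from", "t_to", "id_to"])
    return build_forest(links, by_t, step_hours=step_hours)


@pytest.fixture
def two_division_forest():
    """Root 1 continues once, divides at the 6-h step; daughter 3 divides at
    the 12-h step.  Division timestamps: 6 h and 12 h."""
    nodes = [
        (0, 1, 0.0, 0.0),
        (1, 1, 0.0, 0.0),
        (2, 2, -2.0, 0.0),
        (2, 3, 2.0, 0.0),
        (3, 2, -2.0, 0.0),
        (3, 4, 1.0, 0.0),
        (3, 5, 3.0, 0.0),
    ]
    links = [
        (0, 1, 1, 1),
        (1, 1, 2, 2),
        (1, 1, 2, 3),
        (2, 2, 3, 2),
        (2, 3, 3, 4),
        (2, 3, 3, 5),
    ]
    return forest_from_rows(nodes, links)


@pytest.fixture
def doubling_forest():
    """Every cell divides every step for 2 steps: 1 -> 2,3 -> 4..7."""
    nodes = [(0, 1, 0.0, 0.0)]
    links = []
    nodes += [(1, 2, -4.0, 0.0), (1, 3, 4.0, 0.0)]
    links += [(0, 1, 1, 2), (0, 1, 1, 3)]
    child = 4
    for parent, px in ((2, -4.0), (3, 4.0)):
        for dx in (-2.0, 2.0):
            nodes.append((2, child, px + dx, 0.0))
            links.append((1, parent, 2, child))
            child += 1
    return forest_from_rows(nodes, links)
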