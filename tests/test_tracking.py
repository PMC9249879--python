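"""Frame linking and lineage forest: assignment oracles, division capture,
forest construction, clonal colors, and family trees."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fernlineage import (
    LinkParams,
    assign_colors,
    build_forest,
    family_tree,
    link_frames,
    merge_links,
    simulate_prothallus,
)
from fernlineage.tracking import LINK_COLUMNS

from conftest import forest_from_rows, sparse_config


def frame(t, pts):
    return pd.DataFrame(
        [(t, i, x, y) for i, (x, y) in enumerate(pts)],
        columns=["t_index", "id", "x_um", "y_um"],
    )


# -- link_frames ------------------------------------------------------------


def test_identity_point_sets_identity_links():
    pts = [(0.0, 0.0), (10.0, 0.0), (0.0, 10.0)]
    res = link_frames(frame(0, pts), frame(1, pts))
    assert res.divisions == [] and res.orphans == [] and res.terminated == []
    assert sorted(zip(res.links.id_from, res.links.id_to)) == [(0, 0), (1, 1), (2, 2)]


def test_division_capture_two_daughters():
    res = link_frames(
        frame(0, [(0.0, 0.0)]),
        frame(1, [(2.0, 0.0), (-2.0, 0.0)]),
        LinkParams(division_radius=5.0),
    )
    assert res.divisions == [0]
    assert sorted(zip(res.links.id_from, res.links.id_to)) == [(0, 0), (0, 1)]


def test_assignment_prefers_low_total_cost_over_swap():
    # A(0,0),B(10,0) -> A'(1,0),B'(9,0): direct links cost 2, swap costs 162
    res = link_frames(frame(0, [(0.0, 0.0), (10.0, 0.0)]), frame(1, [(1.0, 0.0), (9.0, 0.0)]))
    assert sorted(zip(res.links.id_from, res.links.id_to)) == [(0, 0), (1, 1)]


def test_duplicate_ids_rejected():
    bad = frame(0, [(0, 0), (5, 5)])
    bad.loc[1, "id"] = 0
    with pytest.raises(ValueError, match="duplicate"):
        link_frames(bad, frame(1, [(0, 0), (5, 5)]))


def test_orphan_raises_without_flag():
    with pytest.raises(ValueError, match="unmatched"):
        link_frames(frame(0, [(0.0, 0.0)]), frame(1, [(0.0, 0.0), (100.0, 100.0)]))
    res = link_frames(
        frame(0, [(0.0, 0.0)]),
        frame(1, [(0.0, 0.0), (100.0, 100.0)]),
        LinkParams(allow_unmatched_new=True),
    )
    assert res.orphans == [1]


def brute_force_matching(p0, p1, max_d):
    """Maximum-cardinality, minimum-squared-cost matching by enumeration."""
    n0, n1 = len(p0), len(p1)
    edges = {
        (i, j): float(np.sum((p0[i] - p1[j]) ** 2))
        for i in range(n0)
        for j in range(n1)
        if np.hypot(*(p0[i] - p1[j])) <= max_d
    }
    for k in range(min(n0, n1), -1, -1):
        costs = []
        for rows in itertools.combinations(range(n0), k):
            for cols in itertools.permutations(range(n1), k):
                pairs = list(zip(rows, cols))
                if all(p in edges for p in pairs):
                    costs.append(sum(edges[p] for p in pairs))
        if costs or k == 0:
            return k, (min(costs) if costs else 0.0)


def test_pass1_cost_matches_exhaustive_enumeration():
    """Optimal-assignment cost equals brute-force minimum over 200 random
    small frame pairs."""
    rng = np.random.default_rng(42)
    params = LinkParams(max_displacement=8.0, division_radius=8.0, allow_unmatched_new=True)
    for _ in range(200):
        n0, n1 = rng.integers(1, 7), rng.integers(1, 7)
        p0 = rng.uniform(0, 30, size=(n0, 2))
        p1 = rng.uniform(0, 30, size=(n1, 2))
        want_k, want_cost = brute_force_matching(p0, p1, params.max_displacement)

        # re-run pass 1 only: division pass would add links, so measure the
        # one-to-one core through a fresh call with division radius tiny
        res = link_frames(
            frame(0, [tuple(p) for p in p0]),
            frame(1, [tuple(p) for p in p1]),
            LinkParams(max_displacement=8.0, division_radius=1e-9, allow_unmatched_new=True),
        )
        got_pairs = list(zip(res.links.id_from, res.links.id_to))
        got_cost = sum(float(np.sum((p0[i] - p1[j]) ** 2)) for i, j in got_pairs)
        assert len(got_pairs) == want_k
        assert got_cost == pytest.approx(want_cost, abs=1e-9)


def test_tracking_recovery_on_simulated_data():
    """With small per-step motion and unambiguous divisions, automatic
    linking reproduces the true links exactly, divisions included."""
    from scipy.spatial import cKDTree

    params = LinkParams()
    n_checked = 0
    n_eligible = 0
    for seed in range(12):
        truth = simulate_prothallus(sparse_config(seed))
        by_t = truth.records_by_t()
        for t in sorted(by_t)[:-1]:
            r0, r1 = by_t[t], by_t[t + 1]
            tl = truth.links[truth.links.t_from == t]
            pos0 = dict(zip(r0.id, zip(r0.x_um, r0.y_um)))
            pos1 = dict(zip(r1.id, zip(r1.x_um, r1.y_um)))
            p1 = r1[["x_um", "y_um"]].to_numpy()
            nn = cKDTree(p1).query(p1, k=2)[0][:, 1].min()
            # recoverability: continuation displacement < half NN spacing,
            # and every daughter nearer its parent than any rival parent
            cont = tl.groupby("id_from").filter(lambda g: len(g) == 1)
            dmax = max(
                (np.hypot(pos1[c][0] - pos0[p][0], pos1[c][1] - pos0[p][1])
                 for p, c in zip(cont.id_from, cont.id_to)),
                default=0.0,
            )
            ok = dmax < 0.5 * nn
            div = tl.groupby("id_from").filter(lambda g: len(g) == 2)
            for p, c in zip(div.id_from, div.id_to):
                d_true = np.hypot(pos1[c][0] - pos0[p][0], pos1[c][1] - pos0[p][1])
                d_rival = min(
                    np.hypot(pos1[c][0] - x, pos1[c][1] - y)
                    for q, (x, y) in pos0.items()
                    if q != p
                )
                ok &= d_true < d_rival
            n_checked += 1
            if not ok:
                continue
            n_eligible += 1
            res = link_frames(r0, r1, params)
            got = set(map(tuple, res.links[["id_from", "id_to"]].to_numpy()))
            want = set(map(tuple, tl[["id_from", "id_to"]].to_numpy()))
            assert got == want, f"seed {seed} t {t}"
    # the conditions must hold in the large majority of generated pairs
    assert n_eligible / n_checked >= 0.8


# -- build_forest -----------------------------------------------------------


def test_single_track_forest():
    forest = forest_from_rows(
        [(0, 1, 0, 0), (1, 1, 1, 0), (2, 1, 2, 0)],
        [(0, 1, 1, 1), (1, 1, 2, 1)],
    )
    assert forest.roots == [(0, 1)]
    assert len(forest.nodes) == 3
    assert len(forest.division_events()) == 0


def test_hand_built_division_tree(two_division_forest):
    f = two_division_forest
    assert len(f.roots) == 1
    assert len(f.division_events()) == 2
    leaves = [n for n in f.alive_at(3)]
    assert len(leaves) == 3
    assert all(n.root_id == 1 for n in f.nodes.values())


def test_forest_matches_simulator_truth():
    truth = simulate_prothallus(sparse_config(5))
    forest = build_forest(truth.links, truth.records_by_t())
    assert len(forest.nodes) == len(truth.nuclei)
    assert len(forest.roots) == len(truth.records_at(0))
    # root propagation agrees with the simulator's root_id column
    for row in truth.nuclei.itertuples(index=False):
        assert forest.nodes[(row.t_index, row.id)].root_id == row.root_id
    assert len(forest.division_events()) == truth.division_event_count()


def test_two_parents_rejected():
    with pytest.raises(ValueError, match="two parents"):
        forest_from_rows(
            [(0, 1, 0, 0), (0, 2, 5, 0), (1, 3, 2, 0)],
            [(0, 1, 1, 3), (0, 2, 1, 3)],
        )


def test_link_to_missing_record_rejected():
    with pytest.raises(ValueError, match="missing record"):
        forest_from_rows([(0, 1, 0, 0)], [(0, 1, 1, 9)])


# -- colors ----------------------------------------------------------------


def test_colors_distinct_deterministic_and_closed(default_forest):
    ca1 = assign_colors(default_forest, rng_seed=11)
    ca2 = assign_colors(default_forest, rng_seed=11)
    assert ca1.colors == ca2.colors
    assert len(set(ca1.colors.values())) == len(ca1.colors)
    # closure: every node maps to its root's color
    for key, node in default_forest.nodes.items():
        assert ca1.color_of_node(default_forest, key) == ca1.colors[node.root_id]
    assert assign_colors(default_forest, rng_seed=12).colors != ca1.colors


# -- family trees -----------------------------------------------------------


def test_family_tree_leaf_root(two_division_forest):
    f = forest_from_rows([(0, 1, 0, 0)], [])
    tree = family_tree(f, 1, window=(0.0, 0.0), later_window=(0.0, 108.0))
    assert tree["node"] == (0, 1)
    assert tree["children"] == []
    assert tree["n_later_divisions"] == 0


def test_family_tree_doubling_annotations(doubling_forest):
    tree = family_tree(doubling_forest, 1, window=(0.0, 12.0), later_window=(12.0, 108.0))

    def leaves(t):
        if not t["children"]:
            return [t]
        return [l for c in t["children"] for l in leaves(c)]

    ls = leaves(tree)
    assert len(ls) == 4
    assert all(l["n_later_divisions"] == 0 for l in ls)


def test_family_tree_zone_passthrough(two_division_forest):
    zones = {(2, 2): "marginal", (2, 3): "inner"}
    tree = family_tree(two_division_forest, 1, window=(0.0, 12.0), zones=zones)
    kids = tree["children"][0]["children"]
    got = {k["node"]: k.get("zone") for k in kids}
    assert got == {(2, 2): "marginal", (2, 3): "inner"}


def test_family_tree_unknown_root(two_division_forest):
    with pytest.raises(KeyError):
        family_tree(two_division_forest, 99, window=(0.0, 12.0))


# -- misc -------------------------------------------------------------------


def test_merge_links_overrides_by_child():
    auto = pd.DataFrame([(0, 1, 1, 1), (0, 2, 1, 2)], columns=LINK_COLUMNS)
    manual = pd.DataFrame([(0, 5, 1, 2)], columns=LINK_COLUMNS)
    merged = merge_links(auto, manual)
    assert len(merged) == 2
    pairs = set(zip(merged.id_from, merged.id_to))
    assert pairs == {(1, 1), (5, 2)}


def test_newick_export_parses(two_division_forest):
    import dendropy

    nwk = two_division_forest.to_newick((0, 1))
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert len(tree.leaf_nodes()) == 3


def test_conservation_identity(default_forest, default_truth):
    final_t = default_truth.n_timepoints - 1
    leaves = sum(
        1
        for n in default_forest.nodes.values()
        if n.t_index == final_t
    )
    assert leaves == len(default_truth.records_at(final_t))
    assert len(default_forest.division_events()) == leaves - len(default_forest.roots)
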