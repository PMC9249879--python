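"""Division counting, divided maps, color scales, marginal/inner
classification and Student's t-test."""

import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from fernlineage import (
    ColorScale,
    TimeWindow,
    ZoneAssignment,
    classify_zone,
    compare_marginal_inner,
    count_divisions,
    divided_map,
    lineage_totals,
    simulate_prothallus,
    ttest_two_tailed,
)
from fernlineage import SimConfig

from conftest import forest_from_rows


# -- windows and counting ---------------------------------------------------


def test_window_validation():
    with pytest.raises(ValueError):
        TimeWindow(24.0, 24.0)
    w = TimeWindow(0.0, 24.0)
    assert w.contains(0.0) and w.contains(23.9) and not w.contains(24.0)
    with pytest.raises(ValueError):
        w2 = TimeWindow(0.0, 13.0)
        w2.validate_step(6.0)


def test_count_no_branches_is_zero():
    f = forest_from_rows(
        [(0, 1, 0, 0), (1, 1, 0, 0), (2, 1, 0, 0)],
        [(0, 1, 1, 1), (1, 1, 2, 1)],
    )
    counts = count_divisions(f, 0, TimeWindow(0.0, 108.0))
    assert counts.n_events.tolist() == [0]


def test_count_timestamped_at_step_start(two_division_forest):
    f = two_division_forest  # divisions at 6 h and 12 h
    assert count_divisions(f, 0, TimeWindow(0.0, 108.0)).n_events.tolist() == [2]
    assert count_divisions(f, 2, TimeWindow(12.0, 108.0)).n_events.sum() == 1
    assert count_divisions(f, 1, TimeWindow(6.0, 12.0)).n_events.tolist() == [1]


def test_reference_after_window_start_rejected(two_division_forest):
    with pytest.raises(ValueError):
        count_divisions(two_division_forest, 2, TimeWindow(0.0, 108.0))


def test_per_lineage_conservation(default_forest, default_truth):
    span = TimeWindow(0.0, default_forest.step_hours * default_truth.n_timepoints)
    counts = count_divisions(default_forest, 0, span)
    final = default_truth.n_timepoints - 1
    assert counts.n_events.sum() == len(default_truth.records_at(final)) - len(
        default_truth.records_at(0)
    )


def test_window_additivity_per_lineage(default_forest):
    """Counts over the three developmental phases sum to the full span."""
    parts = [TimeWindow(0, 24), TimeWindow(24, 54), TimeWindow(54, 108)]
    tot_parts = None
    for w in parts:
        lt = lineage_totals(count_divisions(default_forest, 0, w))
        s = lt.set_index("root_id")["n_events"]
        tot_parts = s if tot_parts is None else tot_parts.add(s, fill_value=0)
    full = lineage_totals(count_divisions(default_forest, 0, TimeWindow(0, 108)))
    full_s = full.set_index("root_id")["n_events"]
    pd.testing.assert_series_equal(tot_parts.astype(int), full_s, check_names=False)


# -- divided map ------------------------------------------------------------


def test_divided_map_matches_counts(default_forest):
    w = TimeWindow(24.0, 54.0)
    layer = divided_map(default_forest, w)
    counts = count_divisions(default_forest, 4, w).set_index("id")["n_events"]
    for row in layer.itertuples(index=False):
        assert row.divided == (counts[row.id] > 0)


def test_divided_map_degenerate_forests(doubling_forest):
    all_magenta = divided_map(doubling_forest, TimeWindow(0.0, 12.0))
    assert all_magenta.divided.all()
    f = forest_from_rows([(0, 1, 0, 0), (1, 1, 0, 0)], [(0, 1, 1, 1)])
    all_green = divided_map(f, TimeWindow(0.0, 6.0))
    assert not all_green.divided.any()


# -- color scale ------------------------------------------------------------


def test_color_scale_endpoints_and_midpoint():
    scale = ColorScale(max_value=81)
    assert scale.color(0) == (0.0, 0.0, 1.0)
    assert scale.color(81) == (1.0, 0.0, 0.0)
    assert scale.color(200) == (1.0, 0.0, 0.0)  # clipped
    mid = ColorScale(max_value=12).color(6)
    assert mid == (0.5, 0.0, 0.5)
    with pytest.raises(ValueError):
        ColorScale(max_value=0)


def test_render_division_map_missing_position(two_division_forest):
    from fernlineage import render_division_map
    import matplotlib

    matplotlib.use("Agg")
    counts = count_divisions(two_division_forest, 0, TimeWindow(0, 108))
    with pytest.raises(KeyError):
        render_division_map(counts, positions={}, scale=ColorScale(2))
    ax = render_division_map(counts, positions={1: (0.0, 0.0)}, scale=ColorScale(2))
    assert ax is not None


# -- zones ------------------------------------------------------------------


def zframe(pts):
    return pd.DataFrame(
        [(0, i, x, y) for i, (x, y) in enumerate(pts)],
        columns=["t_index", "id", "x_um", "y_um"],
    )


def test_triangle_all_marginal():
    recs = zframe([(0, 0), (10, 0), (5, 8)])
    za = classify_zone(recs, meristem_roi=Polygon([(-5, -5), (15, -5), (15, 15), (-5, 15)]))
    assert all(z == "marginal" for z in za.zones.values())


def test_grid_center_is_inner():
    pts = [(i, j) for i in range(3) for j in range(3)]
    za = classify_zone(zframe(pts), meristem_roi=Polygon([(-1, -1), (3, -1), (3, 3), (-1, 3)]),
                       alpha=100.0)
    labels = [za.zones[i] for i, (x, y) in enumerate(pts)]
    assert labels.count("marginal") == 8
    assert za.zones[4] == "inner"  # the (1, 1) center cell


def test_outside_roi_is_outside():
    pts = [(0, 0), (10, 0), (5, 8), (50, 50)]
    za = classify_zone(zframe(pts), meristem_roi=Polygon([(-5, -5), (15, -5), (15, 15), (-5, 15)]))
    assert za.zones[3] == "outside"


def test_too_few_roi_cells_rejected():
    with pytest.raises(ValueError, match="3 meristem"):
        classify_zone(zframe([(0, 0), (1, 0), (50, 50)]),
                      meristem_roi=Polygon([(-1, -1), (2, -1), (2, 2), (-1, 2)]))


def test_collinear_configuration_all_marginal_with_warning():
    pts = [(float(i), 0.0) for i in range(5)]
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        za = classify_zone(zframe(pts), meristem_roi=Polygon([(-1, -1), (5, -1), (5, 1), (-1, 1)]))
    assert all(z == "marginal" for z in za.zones.values())
    assert any("degenerate" in str(w.message) for w in rec)


def test_zone_exhaustive_and_agreement_with_simulator():
    """On simulated frames, classification from the true meristem ROI agrees
    with the simulator's own zone labels for ≥95% of meristem cells."""
    for seed in range(10):
        truth = simulate_prothallus(SimConfig(rng_seed=seed))
        recs = truth.records_at(9)
        nrow = truth.notches[truth.notches.t_index == 9].iloc[0]
        roi = Point(nrow.meristem_x_um, nrow.meristem_y_um).buffer(
            nrow.meristem_radius_um, quad_segs=64
        )
        za = classify_zone(recs, meristem_roi=roi)
        assert set(za.zones) == set(recs.id.astype(int))  # exhaustive
        z_true = truth.true_zones_at(9)
        mer = [i for i, z in z_true.items() if z in ("marginal", "inner")]
        agree = np.mean([za.zones.get(i) == z_true[i] for i in mer])
        assert agree >= 0.95


def test_auto_roi_from_divided_cells():
    pts = [(i * 8.0, j * 8.0) for i in range(4) for j in range(4)]
    divided = {i: (i % 4 < 2) for i in range(16)}  # left half divided
    za = classify_zone(zframe(pts), meristem_roi=None, divided=divided)
    assert za.provenance == "auto"
    inside = [i for i, z in za.zones.items() if z != "outside"]
    assert set(inside) == {i for i in range(16) if divided[i]}


# -- t-test -----------------------------------------------------------------


def test_ttest_identical_groups():
    r = ttest_two_tailed([1, 2, 3], [1, 2, 3])
    assert r.t_statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)
    assert r.degrees_of_freedom == 4


def test_ttest_closed_form_example():
    r = ttest_two_tailed([2, 4, 6], [1, 2, 3])
    assert r.t_statistic == pytest.approx(2 / np.sqrt(2.5 * (2 / 3)))
    assert r.degrees_of_freedom == 4


def test_ttest_antisymmetry():
    a, b = [2.0, 4.0, 6.0, 5.0], [1.0, 2.0, 3.0]
    r1 = ttest_two_tailed(a, b)
    r2 = ttest_two_tailed(b, a)
    assert r1.t_statistic == pytest.approx(-r2.t_statistic)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_ttest_zero_variance_conventions():
    assert ttest_two_tailed([2, 2, 2], [2, 2]).p_value == 1.0
    with pytest.raises(ValueError, match="zero pooled variance"):
        ttest_two_tailed([2, 2, 2], [3, 3])
    with pytest.raises(ValueError):
        ttest_two_tailed([1], [1, 2])


def test_ttest_matches_textbook_formula_highprec():
    """Pooled-variance formula evaluated independently, 100 random draws."""
    from scipy.stats import t as tdist

    rng = np.random.default_rng(7)
    for _ in range(100):
        n1, n2 = rng.integers(2, 10), rng.integers(2, 10)
        a = rng.normal(0, 1, n1)
        b = rng.normal(0.5, 2, n2)
        r = ttest_two_tailed(a, b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_exp = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p_exp = 2 * tdist.sf(abs(t_exp), n1 + n2 - 2)
        assert abs(r.t_statistic - t_exp) < 1e-10
        assert abs(r.p_value - p_exp) < 1e-10


def test_welch_flag_changes_df():
    a = [1.0, 2.0, 3.0, 8.0]
    b = [1.1, 1.9, 3.2]
    student = ttest_two_tailed(a, b)
    welch = ttest_two_tailed(a, b, welch=True)
    assert student.degrees_of_freedom == 5
    assert welch.degrees_of_freedom <= student.degrees_of_freedom


# -- marginal vs inner ------------------------------------------------------


def make_counts(values):
    return pd.DataFrame(
        [(9, i, i, 54.0, 108.0, v) for i, v in enumerate(values)],
        columns=["t_index", "id", "root_id", "window_start_h", "window_end_h", "n_events"],
    )


def test_compare_identical_groups_p1():
    counts = make_counts([3, 3, 3, 3, 4, 4, 4, 4])
    zones = {i: ("marginal" if i < 4 else "inner") for i in range(8)}
    # make groups identical
    counts.loc[4:, "n_events"] = [3, 3, 4, 4]
    counts.loc[:3, "n_events"] = [3, 3, 4, 4]
    result, summary = compare_marginal_inner(counts, zones)
    assert result.p_value == pytest.approx(1.0)
    assert result.mean_a == result.mean_b


def test_compare_missing_group_raises():
    counts = make_counts([1, 2, 3])
    with pytest.raises(ValueError, match="inner"):
        compare_marginal_inner(counts, {0: "marginal", 1: "marginal", 2: "marginal"})


def test_compare_reports_group_sizes():
    counts = make_counts([7, 8, 6, 7, 4, 5, 3, 4])
    zones = {i: ("marginal" if i < 4 else "inner") for i in range(8)}
    result, summary = compare_marginal_inner(counts, zones)
    assert (result.n_a, result.n_b) == (4, 4)
    assert summary.loc[summary.zone == "marginal", "mean_events"].iloc[0] == 7.0
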