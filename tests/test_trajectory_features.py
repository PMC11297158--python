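"""Featurization, preprocessing, quality filtering, and responder calls."""

import numpy as np
import pytest

from combisig.trajectories import default_grid, make_toy_trajectory
from combisig.trajectory_features import (BASELINE_SD_FLOOR, CORE_FEATURES,
                                          call_responder, catalog_names,
                                          extract_features, feature_columns,
                                          interval_feature_names, preprocess,
                                          quality_filter, responder_fraction,
                                          responder_threshold)


def _features_of(traj, pathway="p38"):
    row = extract_features([traj]).iloc[0]
    return {name: row[f"{pathway}_{name}"] for name in catalog_names()}


def test_catalog_is_core_plus_sixteen_integrals():
    names = catalog_names()
    assert len(names) == len(CORE_FEATURES) + 16
    assert names[: len(CORE_FEATURES)] == list(CORE_FEATURES)
    assert interval_feature_names()[0] == "integral_0_0.5h"
    assert interval_feature_names()[-1] == "integral_7.5_8h"


def test_triangle_features_match_analytic_geometry():
    # rises linearly from 0 at t=0 to 2.0 at t=60, back to 0 at t=120
    traj = make_toy_trajectory("triangle", amplitude=2.0, t_peak=60, width=120)
    f = _features_of(traj)
    assert f["max_amplitude"] == pytest.approx(2.0)
    assert f["time_to_max"] == pytest.approx(60.0)
    assert f["time_to_half_max_activity"] == pytest.approx(30.0)
    assert f["max_derivative"] == pytest.approx(2.0 / 60.0, rel=1e-6)
    assert f["min_derivative"] == pytest.approx(-2.0 / 60.0, rel=1e-6)
    assert f["n_peaks"] == 1
    # total area = 1/2 * base * height = 120; integrals are trapezoid-exact
    # for a piecewise-linear signal sampled on the grid
    assert f["total_activity"] == pytest.approx(120.0)
    assert f["integral_0_0.5h"] == pytest.approx(0.5 * 30 * 1.0)
    assert f["integral_2_2.5h"] == pytest.approx(0.0)
    assert f["time_to_half_total_activity"] == pytest.approx(60.0, abs=2.5)
    # zero late-phase activity leaves the ratio undefined
    assert np.isnan(f["early_late_ratio"])
    # with late activity present, the ratio is early/late area
    osc = make_toy_trajectory("damped_oscillation", amplitude=1.0, period=480)
    fo = _features_of(osc)
    t = np.linspace(0, 480, 5000)
    y = np.exp(-t / (3 * 480)) * np.sin(np.pi * t / 480) ** 2
    expected = np.trapezoid(y[t <= 120], t[t <= 120]) / np.trapezoid(
        y[t >= 120], t[t >= 120])
    assert fo["early_late_ratio"] == pytest.approx(expected, rel=0.01)


def test_width_and_frequency_features():
    tri = make_toy_trajectory("triangle", amplitude=1.0, t_peak=120, width=120)
    f = _features_of(tri)
    # width at half prominence of a triangle is half the base
    assert f["first_peak_width_at_half_prominence"] == pytest.approx(60.0, rel=0.1)
    osc = make_toy_trajectory("damped_oscillation", amplitude=1.0, period=60)
    fo = _features_of(osc)
    # sin^2 has period 60 min -> dominant frequency 1/60 per min over 0-4 h
    assert fo["dominant_frequency"] == pytest.approx(1.0 / 60.0, rel=0.3)
    assert fo["n_peaks"] >= 3


def test_feature_nan_outside_grid_span():
    short_grid = default_grid(n_post=49)      # 0..240 min only
    traj = make_toy_trajectory("triangle", amplitude=1.0, t_peak=60, width=60,
                               grid=short_grid)
    f = _features_of(traj)
    assert np.isnan(f["integral_7.5_8h"])
    assert f["total_duration"] >= 0


def test_responder_calls():
    grid = default_grid()
    resp = make_toy_trajectory("step", amplitude=1.0, t_peak=10, width=60,
                               noise_sd=0.01, seed=1, grid=grid)
    non = make_toy_trajectory("flat", amplitude=0.0, noise_sd=0.01, seed=2,
                              grid=grid)
    assert call_responder(resp, "p38")
    assert not call_responder(non, "p38")
    late_only = make_toy_trajectory("step", amplitude=1.0, t_peak=120,
                                    width=60, noise_sd=0.01, seed=3)
    # activation outside the 60-min window does not count
    assert not call_responder(late_only, "p38", window_min=60.0)
    assert responder_fraction([resp, non], "p38") == pytest.approx(0.5)


def test_zero_baseline_sd_uses_floor():
    quiet = make_toy_trajectory("flat", amplitude=0.0)
    assert responder_threshold(quiet, "p38") == pytest.approx(3 * BASELINE_SD_FLOOR)


def test_preprocess_baseline_and_drift():
    grid = default_grid()
    raised = make_toy_trajectory("flat", amplitude=0.0, grid=grid)
    shifted = raised.with_channels(raised.p38 + 5.0, raised.nfkb + 5.0)
    out = preprocess([shifted])[0]
    assert np.allclose(out.p38, 0.0)
    # a common linear drift in the mocks is removed from real cells
    drift_curve = 0.01 * np.clip(grid, 0, None)
    mocks = [make_toy_trajectory("flat", amplitude=0.0, cell_id=f"m{i}")
             .with_channels(drift_curve, drift_curve) for i in range(8)]
    cell = make_toy_trajectory("step", amplitude=1.0, t_peak=60, width=60)
    drifting = cell.with_channels(cell.p38 + drift_curve, cell.nfkb + drift_curve)
    corrected = preprocess([drifting], mock_trajs=mocks)[0]
    resid = corrected.p38 - cell.p38
    assert np.abs(resid[np.abs(grid - 240) < 30]).max() < 0.05
    # too few mocks: drift step skipped with a warning
    with pytest.warns(UserWarning, match="mock"):
        preprocess([drifting], mock_trajs=mocks[:3])


def test_quality_filter_rules_and_report():
    good = make_toy_trajectory("flat", amplitude=0.1, cell_id="good")
    nan_cell = good.with_channels(
        np.where(good.time_min == 100, np.nan, good.p38), good.nfkb)
    nan_cell.cell_id = "nan"
    extreme = good.with_channels(good.p38 + 100.0, good.nfkb)
    extreme.cell_id = "extreme"
    kept, report = quality_filter([good, nan_cell, extreme])
    assert [t.cell_id for t in kept] == ["good"]
    assert report.removed_by_rule["full_duration"] == 1
    assert report.removed_by_rule["max_abs_activity"] == 1
    assert report.retained_fraction == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="every cell"):
        quality_filter([extreme])


def test_extract_features_table_shape_and_helpers():
    trajs = [make_toy_trajectory("triangle", amplitude=a, cell_id=f"c{i}")
             for i, a in enumerate((0.5, 1.0, 2.0))]
    table = extract_features(trajs)
    assert len(table) == 3
    for col in ("cell_id", "condition", "dose", "replicate"):
        assert col in table.columns
    p38_cols = feature_columns(table, "p38")
    assert len(p38_cols) == len(catalog_names())
    assert all(c.startswith("p38_") for c in p38_cols)
    both = feature_columns(table)
    assert len(both) == 2 * len(catalog_names())
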