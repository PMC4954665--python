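"""Occupancy matrices, Bray-Curtis day clustering and PCoA ordination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon, box

from reefrange.daytypology import (
    OccupancyMatrix,
    bray_curtis,
    classify_days,
    distance_to_hr,
    environmental_overlay,
    extraordinary_percentage,
    occupancy_matrix,
    pcoa,
)


# --------------------------------------------------------- distance to HR
def test_distance_inside_is_zero():
    hr = box(0, 0, 1000, 1000)
    assert distance_to_hr(500, 500, hr) == 0.0
    assert distance_to_hr(0, 0, hr) == 0.0  # boundary counts as inside


def test_distance_to_square_edge():
    hr = box(0, 0, 1000, 1000)
    assert distance_to_hr(1500, 500, hr) == pytest.approx(500.0)


def test_distance_matches_boundary_sampling_oracle():
    poly = Polygon([(0, 0), (800, 120), (950, 700), (400, 900), (-100, 500)])
    bnd = poly.exterior
    samples = [bnd.interpolate(f, normalized=True) for f in np.linspace(0, 1, 20000)]
    sx = np.array([p.x for p in samples])
    sy = np.array([p.y for p in samples])
    rng = np.random.default_rng(0)
    for _ in range(30):
        x, y = rng.uniform(-1500, 2500, 2)
        got = distance_to_hr(x, y, poly)
        from shapely.geometry import Point

        oracle = 0.0 if poly.covers(Point(x, y)) else float(
            np.min(np.hypot(sx - x, sy - y))
        )
        assert got == pytest.approx(oracle, abs=1.0)


# --------------------------------------------------------------- occupancy
def _tracks_for_days(track_factory, day_specs, hr_center=(0.0, 0.0)):
    """day_specs: {day_offset: [(fish, depth, (x, y)), ...]}"""
    t0 = pd.Timestamp("2008-06-01 12:00:00", tz="UTC")
    per_fish = {}
    for d, entries in day_specs.items():
        for fish, depth, xy in entries:
            per_fish.setdefault(fish, []).append((t0 + pd.Timedelta(days=d), depth, xy))
    tracks = []
    for fish, rows in per_fish.items():
        times, depths, xys = zip(*[(r[0], r[1], r[2]) for r in rows])
        tracks.append(track_factory(fish, times, ["S"] * len(times), depths, xys))
    return tracks


def test_occupancy_percentages_hand_count(track_factory):
    hr = box(-500, -500, 500, 500)
    specs = {0: [("a", 2.0, (0, 0)), ("b", 2.0, (0, 0)),
                 ("c", 25.0, (0, 0)), ("d", 25.0, (0, 0))]}
    tracks = _tracks_for_days(track_factory, specs)
    occ = occupancy_matrix(tracks, {t.tag_id: hr for t in tracks}, min_active_fish=3)
    assert occ.data.loc[:, "depth_25_26m"].iloc[0] == 50.0
    assert occ.data.loc[:, "depth_02_03m"].iloc[0] == 50.0


def test_occupancy_all_inside_hr_no_distance_features(track_factory):
    hr = box(-500, -500, 500, 500)
    specs = {0: [("a", 2.2, (0, 0)), ("b", 2.4, (10, 10)), ("c", 2.1, (-5, 3))]}
    tracks = _tracks_for_days(track_factory, specs)
    occ = occupancy_matrix(tracks, {t.tag_id: hr for t in tracks}, min_active_fish=3)
    assert occ.dist_cols == []
    row = occ.data.iloc[0]
    assert row["depth_02_03m"] == 100.0
    assert (row.drop("depth_02_03m") == 0.0).all()


def test_occupancy_distance_classes_and_denominator(track_factory):
    hr = box(-500, -500, 500, 500)
    specs = {
        0: [("a", 2.0, (0, 0)), ("b", 2.0, (1000, 0)), ("c", 2.0, (0, 0)),
            ("d", 2.0, (0, 0))],
    }
    tracks = _tracks_for_days(track_factory, specs)
    occ = occupancy_matrix(tracks, {t.tag_id: hr for t in tracks}, min_active_fish=3)
    # fish b sits 500 m beyond the edge: class (400, 600] m
    assert occ.data.loc[:, "dist_0400_0600m"].iloc[0] == 25.0


def test_occupancy_days_below_min_active_excluded(track_factory):
    specs = {0: [("a", 2.0, (0, 0)), ("b", 2.0, (0, 0)), ("c", 2.0, (0, 0))],
             1: [("a", 2.0, (0, 0))]}
    tracks = _tracks_for_days(track_factory, specs)
    hr = box(-500, -500, 500, 500)
    occ = occupancy_matrix(tracks, {t.tag_id: hr for t in tracks}, min_active_fish=3)
    assert len(occ.data) == 1


# ------------------------------------------------------------- bray-curtis
def test_bray_curtis_anchors_and_formula_oracle():
    m = pd.DataFrame([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 5.0]])
    d = bray_curtis(m)
    assert d.iloc[0, 1] == 0.0
    assert d.iloc[0, 2] == 1.0  # disjoint support

    rng = np.random.default_rng(1)
    x = rng.uniform(0, 10, (10, 5))
    d = bray_curtis(pd.DataFrame(x)).to_numpy()
    for j in range(10):
        for k in range(10):
            num = np.abs(x[j] - x[k]).sum()
            den = (x[j] + x[k]).sum()
            assert d[j, k] == pytest.approx(num / den, abs=1e-12)


def test_bray_curtis_rejects_negative_and_zero_rows():
    with pytest.raises(ValueError, match="negative"):
        bray_curtis(pd.DataFrame([[1.0, -0.1], [0.5, 0.2]]))
    with pytest.raises(ValueError, match="zero"):
        bray_curtis(pd.DataFrame([[1.0, 1.0], [0.0, 0.0]]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_bray_curtis_invariants(seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.01, 50, (6, 4))
    d = bray_curtis(pd.DataFrame(x)).to_numpy()
    assert (d >= 0).all() and (d <= 1 + 1e-12).all()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)


# ---------------------------------------------------------- classify_days
def _occ_from_frame(df, depth_cols, dist_cols):
    return OccupancyMatrix(
        data=df, depth_cols=depth_cols, dist_cols=dist_cols,
        active=pd.Series(10, index=df.index),
    )


def _synthetic_occupancy(n_base, n_extra, seed=0):
    rng = np.random.default_rng(seed)
    depth_cols = [f"depth_{k:02d}_{k + 1:02d}m" for k in range(30)]
    dist_cols = ["dist_0000_0200m"]
    rows = []
    for _ in range(n_base):
        # ordinary days share the same shallow occupancy profile, jittered
        r = np.zeros(31)
        r[1] = 60 + rng.uniform(-10, 10)
        r[2] = 50 + rng.uniform(-10, 10)
        r[3] = 30 + rng.uniform(-10, 10)
        rows.append(r)
    for _ in range(n_extra):
        r = np.zeros(31)
        r[1] = 30 + rng.uniform(-5, 5)
        r[rng.integers(22, 30)] = 60 + rng.uniform(-5, 5)  # deep excursion day
        r[30] = 35.0
        rows.append(r)
    days = pd.date_range("2008-06-01", periods=n_base + n_extra, freq="D").date
    df = pd.DataFrame(rows, index=days, columns=depth_cols + dist_cols)
    return _occ_from_frame(df, depth_cols, dist_cols)


def test_classify_days_separates_constructed_excursions():
    occ = _synthetic_occupancy(95, 5)
    ty = classify_days(occ)
    labels = ty.labels
    assert (labels.iloc[95:] == "extraordinary").all()
    assert (labels.iloc[:95] == "ordinary").all()
    # characterization: detected extraordinary days have >50% of fish deep
    assert (ty.deep_occupancy[labels == "extraordinary"] > 50).all()


def test_classify_days_row_order_invariance():
    occ = _synthetic_occupancy(40, 4)
    base = classify_days(occ).labels
    perm = np.random.default_rng(2).permutation(len(occ.data))
    shuffled = OccupancyMatrix(
        data=occ.data.iloc[perm], depth_cols=occ.depth_cols,
        dist_cols=occ.dist_cols, active=occ.active.iloc[perm],
    )
    got = classify_days(shuffled).labels
    for day in base.index:
        assert got.loc[day] == base.loc[day]


def test_classify_days_duplicated_days_get_same_label():
    occ = _synthetic_occupancy(20, 3)
    dup = occ.data.copy()
    dup2 = dup.copy()
    dup2.index = [d + pd.Timedelta(days=100) for d in pd.to_datetime(dup.index)]
    both = pd.concat([dup, dup2])
    occ2 = _occ_from_frame(both, occ.depth_cols, occ.dist_cols)
    labels = classify_days(occ2).labels
    n = len(dup)
    assert list(labels.iloc[:n]) == list(labels.iloc[n:])


def test_classify_days_identical_days_single_cluster_warns():
    df = pd.DataFrame(
        np.tile([50.0, 50.0, 0.0], (5, 1)),
        index=pd.date_range("2008-06-01", periods=5, freq="D").date,
        columns=["depth_00_01m", "depth_01_02m", "dist_0000_0200m"],
    )
    occ = _occ_from_frame(df, ["depth_00_01m", "depth_01_02m"], ["dist_0000_0200m"])
    with pytest.warns(UserWarning, match="identical"):
        ty = classify_days(occ)
    assert (ty.labels == "ordinary").all()


def test_extraordinary_percentage():
    assert extraordinary_percentage(551, 34) == pytest.approx(100 * 34 / 585)
    with pytest.raises(ValueError):
        extraordinary_percentage(0, 0)


# ------------------------------------------------------------------- pcoa
def test_pcoa_equilateral_for_equidistant_days():
    d = pd.DataFrame(1.0 - np.eye(3))
    coords, lost = pcoa(d, k=2)
    pts = coords.to_numpy()
    dists = [np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
    assert np.allclose(dists, dists[0], atol=1e-9)


def test_pcoa_euclidean_round_trip():
    rng = np.random.default_rng(3)
    pts = rng.normal(0, 1, (12, 2))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    coords, lost = pcoa(pd.DataFrame(d), k=2)
    rec = coords.to_numpy()
    d2 = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
    assert np.abs(d2 - d).max() <= 1e-8
    assert lost <= 1e-9


def test_pcoa_beats_random_projections():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, (15, 6))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    coords, _ = pcoa(pd.DataFrame(d), k=2)
    rec = coords.to_numpy()

    def strain(p):
        dd = np.linalg.norm(p[:, None] - p[None, :], axis=2)
        return ((dd - d) ** 2).sum()

    s0 = strain(rec)
    for _ in range(100):
        w = rng.normal(0, 1, (6, 2))
        q, _r = np.linalg.qr(w)
        assert s0 <= strain(x @ q) + 1e-9


# ------------------------------------------------------------ env overlay
def test_environmental_overlay_join_and_empty(track_factory):
    occ = _synthetic_occupancy(10, 2)
    ty = classify_days(occ)
    env = pd.DataFrame(
        {"date": [str(d) for d in list(occ.data.index)[:6]],
         "sst_c": np.arange(6.0), "wave_m": np.arange(6.0) / 10}
    )
    out = environmental_overlay(ty, env)
    assert set(out["label"]) <= {"ordinary", "extraordinary"}
    assert out["sst_c"].notna().sum() == 6  # unmatched days stay as gaps
    with pytest.warns(UserWarning, match="empty"):
        out2 = environmental_overlay(ty, pd.DataFrame())
    assert "label" in out2.columns
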