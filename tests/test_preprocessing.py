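"""Hourly standardization, outlier screening, rates, labels, distances."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import LineString, Point

from bearclock.preprocessing import (
    FeatureSet, assign_hour_index, assign_season, build_observations,
    compute_movement_rates, distance_to_features, screen_outliers,
    standardize_hourly,
)


def _fixes(rows):
    return pd.DataFrame(rows, columns=["animal_id", "sex", "timestamp", "x", "y"])


# ---------------------------------------------------------------------------
# hourly standardization
# ---------------------------------------------------------------------------


def test_standardize_keeps_fix_closest_to_top_of_hour():
    df = _fixes([
        ("a", "F", "2008-04-01 10:30:00", 0.0, 0.0),
        ("a", "F", "2008-04-01 10:00:00", 5.0, 5.0),
        ("a", "F", "2008-04-01 11:00:00", 9.0, 9.0),
    ])
    out = standardize_hourly(df)
    assert len(out) == 2
    assert list(out["x"]) == [5.0, 9.0]


def test_standardize_identity_on_hourly_series():
    ts = pd.date_range("2008-04-01 00:00", periods=48, freq="h")
    df = _fixes([("a", "F", t, float(i), 0.0) for i, t in enumerate(ts)])
    out = standardize_hourly(df)
    pd.testing.assert_frame_equal(out, df.assign(timestamp=pd.to_datetime(df["timestamp"])))


def test_standardize_surplus_row_count():
    """A 29,796-row table built with exactly 2,916 surplus same-hour rows
    reduces to 26,880 — the surplus count is verified by brute force."""
    rng = np.random.default_rng(42)
    n_animals, per_animal = 16, 1680          # 16 * 1680 = 26,880 unique hours
    base_rows = []
    for k in range(n_animals):
        start = pd.Timestamp("2008-03-01") + pd.Timedelta(days=int(rng.integers(0, 5)))
        ts = pd.date_range(start, periods=per_animal, freq="h")
        base_rows += [(f"b{k:02d}", "F", t, float(rng.normal()), float(rng.normal()))
                      for t in ts]
    base = _fixes(base_rows)
    dup = base.sample(n=2916, random_state=7).copy()
    dup["timestamp"] = dup["timestamp"] + pd.Timedelta(minutes=30)
    full = pd.concat([base, dup], ignore_index=True)
    assert len(full) == 29_796
    # brute-force surplus count: rows beyond the first per (animal, hour)
    hours = full.assign(h=pd.to_datetime(full["timestamp"]).dt.floor("h"))
    surplus = len(full) - hours.groupby(["animal_id", "h"]).ngroups
    assert surplus == 2_916
    assert len(standardize_hourly(full)) == 26_880


# ---------------------------------------------------------------------------
# outlier screening
# ---------------------------------------------------------------------------


def test_screen_removes_teleporting_fix():
    # neighbours 1 km apart; middle fix 50 km away forces >10 km/h both ways
    df = _fixes([
        ("a", "F", "2008-04-01 10:00", 0.0, 0.0),
        ("a", "F", "2008-04-01 11:00", 50_000.0, 0.0),
        ("a", "F", "2008-04-01 12:00", 1_000.0, 0.0),
    ])
    kept, removed = screen_outliers(df, max_speed_kmh=10.0)
    assert len(kept) == 2 and len(removed) == 1
    assert removed.iloc[0]["x"] == 50_000.0


def test_screen_identity_below_threshold():
    ts = pd.date_range("2008-04-01", periods=10, freq="h")
    df = _fixes([("a", "M", t, 100.0 * i, 0.0) for i, t in enumerate(ts)])
    kept, removed = screen_outliers(df, max_speed_kmh=10.0)
    assert len(kept) == 10 and len(removed) == 0


def test_screen_two_fix_series_is_identity():
    df = _fixes([
        ("a", "F", "2008-04-01 10:00", 0.0, 0.0),
        ("a", "F", "2008-04-01 11:00", 99_000.0, 0.0),
    ])
    kept, removed = screen_outliers(df, max_speed_kmh=10.0)
    assert len(kept) == 2 and len(removed) == 0


def test_screen_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        screen_outliers(_fixes([]), max_speed_kmh=0.0)


# ---------------------------------------------------------------------------
# movement rates
# ---------------------------------------------------------------------------


def test_rate_from_consecutive_fixes():
    df = _fixes([
        ("a", "F", "2008-04-01 10:00", 0.0, 0.0),
        ("a", "F", "2008-04-01 11:00", 300.0, 0.0),   # 300 m in 1 h
        ("a", "F", "2008-04-01 12:00", 300.0, 0.0),   # stationary
        ("a", "F", "2008-04-01 14:00", 900.0, 0.0),   # 2-h gap: no record
    ])
    out = compute_movement_rates(df)
    assert len(out) == 2
    assert out["rate_kmh"].tolist() == pytest.approx([0.3, 0.0])
    assert out["y"].iloc[0] == pytest.approx(math.sqrt(0.3))
    assert out["y"].iloc[1] == 0.0


def test_rate_count_matches_brute_force_pair_counter(rng):
    rows = []
    for k in range(4):
        t0 = pd.Timestamp("2008-05-01")
        hours = np.sort(rng.choice(200, size=80, replace=False))
        rows += [(f"b{k}", "F", t0 + pd.Timedelta(hours=int(h)),
                  float(rng.normal(0, 500)), float(rng.normal(0, 500))) for h in hours]
    df = _fixes(rows)
    out = compute_movement_rates(df)
    brute = 0
    for _, grp in df.groupby("animal_id"):
        t = sorted(pd.to_datetime(grp["timestamp"]))
        brute += sum((b - a) == pd.Timedelta(hours=1) for a, b in zip(t, t[1:]))
    assert len(out) == brute


# ---------------------------------------------------------------------------
# hour and season labels
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("ts,expected", [
    ("2008-04-01 00:00", 24),   # midnight is hour 24 on the circular clock
    ("2008-04-01 13:00", 13),
    ("2008-04-01 23:59", 23),
])
def test_hour_index(ts, expected):
    assert assign_hour_index(ts) == expected


def test_hour_index_24h_shift_is_identity():
    for h in range(24):
        t = pd.Timestamp("2008-04-01") + pd.Timedelta(hours=h)
        assert assign_hour_index(t) == assign_hour_index(t + pd.Timedelta(hours=24))


@pytest.mark.parametrize("date,expected", [
    ("2008-04-15", 1), ("2008-06-01", 2), ("2008-08-31", 3), ("2008-10-01", 4),
    ("2008-12-15", 4), ("2008-12-20", None), ("2008-12-16", None),
    ("2008-02-28", None), ("2008-03-01", 1),
])
def test_season_assignment(date, expected):
    assert assign_season(date) == expected


# ---------------------------------------------------------------------------
# distances to landscape features
# ---------------------------------------------------------------------------


def _toy_features():
    return FeatureSet({
        "primary_road": [LineString([(0, 0), (10_000, 0)])],
        "secondary_road": [LineString([(0, 5_000), (10_000, 5_000)])],
        "settlement": [Point(2_000, 2_000)],
    })


def test_distance_basics():
    f = _toy_features()
    assert distance_to_features((5_000, 0), f, "primary_road") == 0.0
    assert distance_to_features((2_000, 3_000), f, "settlement") == pytest.approx(1.0)
    with pytest.raises(ValueError):
        distance_to_features((0, 0), FeatureSet({"settlement": []}), "settlement")


def test_distance_matches_exhaustive_segment_minimum(rng):
    segs = [LineString([tuple(rng.uniform(0, 10_000, 2)), tuple(rng.uniform(0, 10_000, 2))])
            for _ in range(100)]
    f = FeatureSet({"secondary_road": segs})
    for _ in range(20):
        p = rng.uniform(0, 10_000, 2)
        got = distance_to_features(tuple(p), f, "secondary_road")
        brute = min(shapely.distance(Point(p), s) for s in segs) / 1000.0
        assert got == pytest.approx(brute)


def test_distance_rigid_motion_invariance(rng):
    segs = [LineString([tuple(rng.uniform(0, 5_000, 2)), tuple(rng.uniform(0, 5_000, 2))])
            for _ in range(10)]
    p = np.array([1_234.0, 567.0])
    d0 = distance_to_features(tuple(p), FeatureSet({"primary_road": segs}), "primary_road")
    theta, shift = 0.83, np.array([3_000.0, -2_000.0])
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    moved = [LineString((np.asarray(s.coords) @ R.T) + shift) for s in segs]
    d1 = distance_to_features(tuple(R @ p + shift), FeatureSet({"primary_road": moved}),
                              "primary_road")
    assert d1 == pytest.approx(d0)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_build_observations_schema_and_min_road_invariant(rng):
    ts = pd.date_range("2008-04-01", periods=72, freq="h")
    rows = []
    for k, sex in (("a", "F"), ("b", "M")):
        pos = np.cumsum(rng.normal(0, 200, size=(len(ts), 2)), axis=0) + 4_000
        rows += [(k, sex, t, float(x), float(y)) for t, (x, y) in zip(ts, pos)]
    obs = build_observations(_fixes(rows), features=_toy_features())
    assert len(obs) > 0
    assert np.allclose(obs["x1"], np.minimum(obs["x2"], obs["x3"]))
    assert (obs["season"] == 1).all() and obs["hour_index"].between(1, 24).all()
    assert np.allclose(obs["y"], np.sqrt(obs["rate_kmh"]))


def test_build_observations_from_covariate_table():
    ts = pd.date_range("2008-06-01", periods=5, freq="h")
    fixes = _fixes([("a", "F", t, 100.0 * i, 0.0) for i, t in enumerate(ts)])
    cov = pd.DataFrame({"animal_id": "a", "timestamp": ts,
                        "x2_km": 1.0, "x3_km": 0.5, "x4_km": 2.0})
    obs = build_observations(fixes, covariates=cov)
    assert (obs["x1"] == 0.5).all() and (obs["x2"] == 1.0).all()
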