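"""From raw GPS fixes to the model's observation table.

Steps: hourly standardization (one fix per animal per clock hour, the one
closest to the top of the hour), a symmetric speed filter for outliers,
hourly movement rates from consecutive-hour pairs, hour-of-day / dietary
season / sex labels, and distance covariates to roads and settlements.

Fix tables are pandas DataFrames with columns
``animal_id, sex, timestamp, x, y`` (timestamp ISO-8601, coordinates in
meters of a projected CRS).  Every step is deterministic.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .observations import OBS_COLUMNS

FIX_COLUMNS = ["animal_id", "sex", "timestamp", "x", "y"]
FEATURE_TYPES = ("primary_road", "secondary_road", "settlement")

# dietary seasons: spring Mar-May, early summer Jun-Jul, late summer Aug-Sep,
# fall Oct 1 - Dec 15; outside the active period -> no season
_SEASON_BY_MONTH = {3: 1, 4: 1, 5: 1, 6: 2, 7: 2, 8: 3, 9: 3, 10: 4, 11: 4}
FALL_CUTOFF_DAY = 15  # December 15, inclusive


def _as_fixes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table is missing columns: {missing}")
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    if not np.isfinite(out[["x", "y"]].to_numpy(float)).all():
        raise ValueError("fix coordinates must be finite")
    return out.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)


def standardize_hourly(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one fix per animal per clock hour.

    Within each (animal, calendar hour) bucket the fix closest to the top of
    the hour wins; ties go to the earlier fix.  Deterministic.
    """
    if len(fixes) == 0:
        return fixes.copy()
    df = _as_fixes(fixes)
    bucket = df["timestamp"].dt.floor("h")
    offset = (df["timestamp"] - bucket).dt.total_seconds()
    df = df.assign(_bucket=bucket, _offset=offset)
    keep = df.sort_values(["animal_id", "_bucket", "_offset", "timestamp"], kind="stable") \
             .groupby(["animal_id", "_bucket"], sort=False).head(1)
    return keep.sort_values(["animal_id", "timestamp"], kind="stable") \
               .drop(columns=["_bucket", "_offset"]).reset_index(drop=True)


def screen_outliers(fixes: pd.DataFrame, max_speed_kmh: float = 10.0):
    """Remove fixes whose implied speed to BOTH temporal neighbors is excessive.

    A teleporting location forces high speeds on both adjacent segments; a
    fast-but-real transit does not.  Endpoint fixes (one neighbor) are never
    removed.  Returns ``(retained, removals)``.
    """
    if max_speed_kmh <= 0:
        raise ValueError("max_speed_kmh must be positive")
    df = _as_fixes(fixes)
    drop_idx = []
    for _, grp in df.groupby("animal_id", sort=False):
        if len(grp) < 3:
            continue
        t = grp["timestamp"].astype("int64").to_numpy() / 3.6e12  # hours
        xy = grp[["x", "y"]].to_numpy(float) / 1000.0  # km
        seg = np.hypot(*(xy[1:] - xy[:-1]).T)
        dt = np.diff(t)
        speed = np.divide(seg, dt, out=np.full_like(seg, np.inf), where=dt > 0)
        bad = (speed[:-1] > max_speed_kmh) & (speed[1:] > max_speed_kmh)
        drop_idx.extend(grp.index[1:-1][bad])
    removals = df.loc[drop_idx].reset_index(drop=True)
    retained = df.drop(index=drop_idx).reset_index(drop=True)
    return retained, removals


def compute_movement_rates(fixes: pd.DataFrame) -> pd.DataFrame:
    """Hourly movement rates from pairs of fixes in consecutive clock hours.

    The rate is the planar Euclidean distance (km) over the 1-h interval;
    the response is y = sqrt(rate).  Pairs spanning more than one hour yield
    no record.  Each record keeps the STARTING fix's timestamp and position
    (covariates are evaluated at the step's origin).
    """
    df = _as_fixes(fixes)
    out = []
    for _, grp in df.groupby("animal_id", sort=False):
        hours = grp["timestamp"].dt.floor("h")
        consecutive = (hours.diff().dt.total_seconds() == 3600.0).to_numpy()
        xy = grp[["x", "y"]].to_numpy(float)
        dist_km = np.hypot(*(xy[1:] - xy[:-1]).T) / 1000.0
        sel = consecutive[1:]
        sub = grp.iloc[:-1][sel].copy()
        sub["rate_kmh"] = dist_km[sel]
        out.append(sub)
    if not out:
        return df.head(0).assign(rate_kmh=np.nan, y=np.nan)
    res = pd.concat(out, ignore_index=True)
    res["y"] = np.sqrt(res["rate_kmh"])
    return res


def assign_hour_index(timestamp) -> int:
    """Clock hour as 1-24: hours 1-23 map to themselves, midnight maps to 24."""
    h = pd.Timestamp(timestamp).hour
    return 24 if h == 0 else h


def assign_season(date):
    """Dietary season 1-4, or None outside the March 1 - December 15 active period."""
    ts = pd.Timestamp(date)
    if ts.month == 12:
        return 4 if ts.day <= FALL_CUTOFF_DAY else None
    return _SEASON_BY_MONTH.get(ts.month)


# ---------------------------------------------------------------------------
# landscape features
# ---------------------------------------------------------------------------

class FeatureSet:
    """Typed planar geometries: road polylines and settlement points.

    Stored as a mapping ftype -> list of shapely geometries (meters).
    """

    def __init__(self, features: dict):
        unknown = set(features) - set(FEATURE_TYPES)
        if unknown:
            raise ValueError(f"unknown feature types: {sorted(unknown)}")
        self.features = {k: list(v) for k, v in features.items()}
        self._merged = {k: shapely.union_all(v) if v else None for k, v in self.features.items()}

    def geometries(self, ftype: str):
        return self.features.get(ftype, [])

    def merged(self, ftype: str):
        geom = self._merged.get(ftype)
        if geom is None or geom.is_empty:
            raise ValueError(f"no features of class {ftype!r}")
        return geom

    @classmethod
    def from_geojson(cls, path) -> "FeatureSet":
        with open(path) as fh:
            data = json.load(fh)
        feats: dict = {k: [] for k in FEATURE_TYPES}
        for i, f in enumerate(data.get("features", [])):
            ftype = f.get("properties", {}).get("ftype")
            if ftype not in FEATURE_TYPES:
                raise ValueError(f"feature {i}: missing or unknown ftype {ftype!r}")
            feats[ftype].append(shape(f["geometry"]))
        return cls(feats)

    def to_geojson(self, path=None) -> dict:
        fc = {"type": "FeatureCollection", "features": [
            {"type": "Feature", "properties": {"ftype": ftype}, "geometry": mapping(g)}
            for ftype in FEATURE_TYPES for g in self.features.get(ftype, [])]}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(fc, fh)
        return fc


def distance_to_features(point, features: FeatureSet, ftype: str) -> float:
    """Minimum planar distance (km) from a point to a feature class."""
    geom = features.merged(ftype)
    pt = shapely.points(point[0], point[1]) if not isinstance(point, shapely.Geometry) else point
    return float(shapely.distance(pt, geom)) / 1000.0


def _distance_columns(records: pd.DataFrame, features: FeatureSet) -> pd.DataFrame:
    pts = shapely.points(records["x"].to_numpy(float), records["y"].to_numpy(float))
    out = {}
    for j, ftype in ((2, "primary_road"), (3, "secondary_road"), (4, "settlement")):
        out[f"x{j}"] = shapely.distance(pts, features.merged(ftype)) / 1000.0
    out["x1"] = np.minimum(out["x2"], out["x3"])
    return records.assign(**out)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def build_observations(fixes: pd.DataFrame, features: FeatureSet | None = None,
                       covariates: pd.DataFrame | None = None,
                       max_speed_kmh: float = 10.0) -> pd.DataFrame:
    """Full preprocessing pipeline returning the observation table.

    Distance covariates come from ``features`` (GeoJSON geometries) or a
    precomputed ``covariates`` table (``animal_id, timestamp, x2_km, x3_km,
    x4_km``; x1 is derived as min(x2, x3)); with neither, the x columns are
    zero and only covariate-free models can be fitted.  Records outside the
    active period (no season) are dropped.
    """
    std = standardize_hourly(fixes)
    screened, _removed = screen_outliers(std, max_speed_kmh=max_speed_kmh)
    rec = compute_movement_rates(screened)
    if len(rec) == 0:
        return pd.DataFrame(columns=OBS_COLUMNS)
    rec["hour_index"] = rec["timestamp"].map(assign_hour_index)
    rec["season"] = rec["timestamp"].map(assign_season)
    rec = rec[rec["season"].notna()].copy()
    rec["season"] = rec["season"].astype(int)
    if features is not None:
        rec = _distance_columns(rec, features)
    elif covariates is not None:
        cov = covariates.copy()
        cov["timestamp"] = pd.to_datetime(cov["timestamp"])
        rec = rec.merge(cov, on=["animal_id", "timestamp"], how="left")
        for j in (2, 3, 4):
            rec[f"x{j}"] = rec[f"x{j}_km"]
        rec["x1"] = np.minimum(rec["x2"], rec["x3"])
        rec = rec.drop(columns=[f"x{j}_km" for j in (2, 3, 4)])
        if rec[["x2", "x3", "x4"]].isna().any().any():
            raise ValueError("covariate table does not cover all fixes")
    else:
        for j in (1, 2, 3, 4):
            rec[f"x{j}"] = 0.0
    return rec[OBS_COLUMNS].reset_index(drop=True)
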