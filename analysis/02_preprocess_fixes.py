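"""Demonstrate the raw-fix pipeline on a landscape-based simulation.

A small study (3 bears random-walking over a simulated landscape of roads
and settlements, GPS error with 24.7 m mean radial size, 90% acquisition)
is emitted as raw fixes, then pushed through hourly standardization,
speed-based outlier screening, movement rates and distance covariates.
Writes fixes, landscape and the derived observation table under
results/preprocessing/.
"""

import argparse
from pathlib import Path

from bearclock import (LandscapeSpec, SyntheticTruth, build_observations,
                       simulate_landscape, simulate_records)
from bearclock.io import ensure_dir, write_fixes, write_observations

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=7)
ap.add_argument("--out-dir", type=Path, default=Path("results/preprocessing"))
args = ap.parse_args()

out = ensure_dir(args.out_dir)
truth = SyntheticTruth.draw(1, seed=args.seed, n_bears=3, n_females=2,
                            alpha=0.7, acquisition_rate=0.9)
land = simulate_landscape(LandscapeSpec(seed=args.seed, extent_km=15.0))
records_true, fixes = simulate_records(truth, landscape=land, days_per_season=5)
land.to_geojson(out / "landscape.geojson")
write_fixes(fixes, out / "fixes.csv")

obs = build_observations(fixes, features=land)
write_observations(obs, out / "observations.csv")

merged = records_true.merge(obs, on=["animal_id", "timestamp"],
                            suffixes=("_true", "_obs"))
err = (merged["rate_kmh_true"] - merged["rate_kmh_obs"]).abs()
print(f"{len(fixes)} raw fixes -> {len(obs)} hourly movement records")
print(f"rate recovery vs generator truth: median |error| {err.median():.3f} km/h, "
      f"95th pct {err.quantile(0.95):.3f} km/h (GPS error 24.7 m per fix)")
print(f"wrote fixes, landscape and observations to {out}")
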