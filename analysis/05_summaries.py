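"""Posterior result surfaces from the best fitted model.

From the full-model fit: hourly activity curves per season and sex, the
even-sex-ratio population curve with its threshold classification into
active and inactive hours, the sex x season movement-rate table, and
movement-rate-versus-distance curves for each anthropogenic feature class
(flagging amplitudes whose 95% CI excludes zero).  Everything goes under
results/summaries/ as CSV, plus a PNG of the population curve.
"""

import argparse
import json
from pathlib import Path

from bearclock import (MODEL_REGISTRY, anthropogenic_response,
                       classify_active_hours, hourly_curve, movement_rate_table,
                       population_curve_5050)
from bearclock.cli import _plot_curve
from bearclock.io import ensure_dir, read_chains
from bearclock.model import SEASON_NAMES

ap = argparse.ArgumentParser()
ap.add_argument("--fits-dir", type=Path, default=Path("results/fits"))
ap.add_argument("--spec", type=int, default=9)
ap.add_argument("--out-dir", type=Path, default=Path("results/summaries"))
args = ap.parse_args()

out = ensure_dir(args.out_dir)
chains, sid = read_chains(args.fits_dir / f"draws_spec{args.spec:02d}.csv",
                          args.fits_dir / f"meta_spec{args.spec:02d}.json")
spec = MODEL_REGISTRY[sid]

for r in (1, 2, 3, 4):
    cF = hourly_curve(chains, spec, stratum=(r, 1))
    cM = hourly_curve(chains, spec, stratum=(r, 2))
    for tag, c in ((f"{SEASON_NAMES[r]}_F", cF), (f"{SEASON_NAMES[r]}_M", cM),
                   (f"{SEASON_NAMES[r]}_pop", population_curve_5050(cF, cM))):
        c.to_dataframe().to_csv(out / f"curve_{tag}.csv", index=False)

pop = hourly_curve(chains, spec, stratum=None)
pop.to_dataframe().to_csv(out / "curve_population.csv", index=False)
part = classify_active_hours(pop)
(out / "active_hours.json").write_text(json.dumps(part, indent=1))
peaks = pop.mean_rate.argsort()[-2:] + 1
print(f"population curve: peak hours {sorted(peaks.tolist())}, "
      f"24-h mean {part['threshold_kmh']:.3f} km/h")
print(f"active hours ({len(part['active'])}): {part['active']}")

table = movement_rate_table(chains, spec, part)
table.to_csv(out / "movement_rates.csv", index=False)
both = table.set_index(["sex", "season", "period"]).sort_index().loc[("both", "all")]
print("both sexes, all seasons (km/h): "
      + ", ".join(f"{p}: {both.loc[p, 'mean_kmh']:.2f} +/- {both.loc[p, 'sd_kmh']:.2f}"
                  for p in ("24h", "active", "inactive")))

print("\ndistance responses (95% CI of the amplitude excludes zero?):")
for feature, fname in ((2, "primary roads"), (3, "secondary roads"), (4, "settlements")):
    for r in (1, 2, 3, 4):
        resp = anthropogenic_response(chains, spec, season=r, feature=feature)
        resp.to_dataframe().to_csv(out / f"response_x{feature}_{SEASON_NAMES[r]}.csv",
                                   index=False)
        flag = "YES" if resp.ci_excludes_zero else "no "
        print(f"  {fname:15s} {SEASON_NAMES[r]:13s} beta={resp.beta_mean:+.3f} "
              f"CI=({resp.beta_ci[0]:+.3f}, {resp.beta_ci[1]:+.3f})  {flag}")

_plot_curve(pop, part, out / "activity_curve.png")
print(f"\nwrote curves, tables and plot to {out}")
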