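"""Generate the synthetic telemetry study the later steps analyse.

Eighteen collared bears (11 F, 7 M), one scheduled fix per hour over
ten-day blocks in each of the four dietary seasons, acquisition success
0.88, and movement records drawn from the full model (hour-by-season-by-sex
effects with cyclic covariance, individual effects, and distance-decay
responses to primary roads, secondary roads and settlements).  Writes the
observation table and the generating-truth sidecar under results/study/.
"""

import argparse
from pathlib import Path

from bearclock import SyntheticTruth, simulate_records
from bearclock.io import ensure_dir, write_observations

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=7)
ap.add_argument("--out-dir", type=Path, default=Path("results/study"))
args = ap.parse_args()

out = ensure_dir(args.out_dir)
truth = SyntheticTruth.draw(9, seed=args.seed)
records, _ = simulate_records(truth, days_per_season=10)
write_observations(records, out / "records.csv")
truth.to_json(out / "truth.json")

n_sched = truth.n_bears * 4 * 10 * 24
print(f"study: {truth.n_bears} bears ({truth.n_females} F), "
      f"{n_sched} scheduled hourly fixes, acquisition {truth.acquisition_rate:.2f}")
print(f"emitted {len(records)} movement records "
      f"({len(records) / n_sched:.1%} of scheduled pairs; misses break pairs)")
print(f"sqrt-rate truncation fraction: {records.attrs['truncation_fraction']:.4f}")
print(f"wrote {out}/records.csv and {out}/truth.json")
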