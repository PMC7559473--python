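"""From telemetry to matched used/available strata.

Aggregates fixes toward the 8-h target interval, builds steps with lengths
and turning angles, fits per-animal empirical movement kernels, and matches
every step that has a prior bearing with 10 available steps. Writes the long
stratum table to results/strata/strata.csv.

Run after 01:  python analysis/02_build_strata.py [--seed 0]
"""

import argparse
from pathlib import Path

import numpy as np

from thermalsteps.steps import aggregate_fixes, build_steps, build_strata, \
    fit_movement_kernel
from thermalsteps.synthetic import read_telemetry

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
parser.add_argument("--out", type=Path, default=Path("results/strata"))
args = parser.parse_args()

track = read_telemetry(args.fixture / "telemetry.csv")
agg = aggregate_fixes(track, target_interval=8.0)
steps = build_steps(agg)
kernels = fit_movement_kernel(steps, kind="empirical")
strata = build_strata(steps, kernels, M=10, seed=args.seed)

args.out.mkdir(parents=True, exist_ok=True)
strata.to_csv(args.out / "strata.csv", index=False)

n_usable = int(np.isfinite(steps["turn_angle"]).sum())
print(f"fixes in: {len(track)}; after aggregation: {len(agg)}")
print(f"steps: {len(steps)} ({n_usable} with a defined turning angle)")
print(f"strata: {strata['stratum_id'].nunique()} "
      f"({len(strata)} rows at 1 used + 10 available each)")
print(f"median observed step length: {steps['length_m'].median():.0f} m")
print(f"wrote {args.out / 'strata.csv'}")
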