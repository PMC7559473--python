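"""Compare model variants by QIC, validate by leave-one-animal-out CV, and
export conditional selection-probability curves.

For each population-sex partition the three model families are ranked by
QIC (lower is better fit) with leave-one-animal-out mean Spearman rank
correlations (higher is better prediction); the winning spline fit is then
turned into a plot-ready table of the conditional probability of selecting
denser canopy over the partition median as temperature varies, with the
10th/90th percentiles of experienced temperature annotated.

Run after 04:  python analysis/05_evaluate.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thermalsteps.evaluation import compare_variants, selection_curve
from thermalsteps.synthetic import read_telemetry

parser = argparse.ArgumentParser()
parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
parser.add_argument("--table", type=Path,
                    default=Path("results/covariates/covariate_table.csv"))
parser.add_argument("--out", type=Path, default=Path("results/evaluation"))
args = parser.parse_args()

table = pd.read_csv(args.table, parse_dates=["t"])
telemetry = read_telemetry(args.fixture / "telemetry.csv")
labels = telemetry.drop_duplicates("animal_id").set_index("animal_id")
table["population"] = table["animal_id"].map(labels["population"])
table["sex"] = table["animal_id"].map(labels["sex"])

args.out.mkdir(parents=True, exist_ok=True)
for (pop, sex), part in table.groupby(["population", "sex"]):
    label = f"{pop}_{sex}"
    comp = compare_variants(part)
    cols = ["variant", "qic", "delta_qic", "loocv_pct", "delta_loocv_pct"]
    print(f"\n=== partition {label} ===")
    print(comp.table[cols].round(2).to_string(index=False))
    verdict = ("QIC and LOOCV agree" if comp.agreement
               else f"QIC prefers {comp.best_qic}, LOOCV prefers {comp.best_loocv}")
    print(f"  best by QIC: {comp.best_qic}; best by LOOCV: {comp.best_loocv} ({verdict})")
    comp.to_csv(args.out / f"{label}_model_comparison.csv")

    spline_fits = {k: v for k, v in comp.fits.items() if v.bases}
    if spline_fits:
        name = comp.best_qic if comp.best_qic in spline_fits else next(iter(spline_fits))
        fit = spline_fits[name]
        temps = part.loc[part.case == 1, "temperature_c"].to_numpy()
        grid = np.linspace(temps.min(), temps.max(), 41)
        dense = float(np.quantile(part["canopy_pct"], 0.9))
        ref = float(np.quantile(part["canopy_pct"], 0.5))
        curves = selection_curve(fit, grid, np.array([dense]), reference_level=ref,
                                 experienced_temperatures=temps)
        curves.to_csv(args.out / f"{label}_selection_curves.csv", index=False)
        mid = curves.iloc[len(curves) // 2]
        print(f"  curve ({name}): P(select 90th- over 50th-percentile canopy) at "
              f"{mid.temperature_c:.1f} C = {mid.probability:.2f} "
              f"[{mid.lo95:.2f}, {mid.hi95:.2f}]")
print(f"\nwrote comparison and curve tables to {args.out}")
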