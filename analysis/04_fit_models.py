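"""Fit the three model families per population-sex partition.

For each partition: a base model (habitat main effects only), a linear
canopy x temperature interaction, and natural-spline interactions with 2 and
3 basis columns — by conditional logistic regression with animal-year
cluster-robust (GEE sandwich) standard errors. Writes one coefficient table
per partition and variant.

Run after 03:  python analysis/04_fit_models.py
"""

import argparse
from pathlib import Path

import pandas as pd

from thermalsteps.clr import build_design, fit_clr
from thermalsteps.evaluation import default_variants
from thermalsteps.synthetic import read_telemetry

parser = argparse.ArgumentParser()
parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
parser.add_argument("--table", type=Path,
                    default=Path("results/covariates/covariate_table.csv"))
parser.add_argument("--out", type=Path, default=Path("results/fits"))
args = parser.parse_args()

table = pd.read_csv(args.table, parse_dates=["t"])
telemetry = read_telemetry(args.fixture / "telemetry.csv")
labels = telemetry.drop_duplicates("animal_id").set_index("animal_id")

table["population"] = table["animal_id"].map(labels["population"])
table["sex"] = table["animal_id"].map(labels["sex"])

args.out.mkdir(parents=True, exist_ok=True)
mains = ("canopy_pct", "dist_water_m", "elevation_m", "sri")
for (pop, sex), part in table.groupby(["population", "sex"]):
    label = f"{pop}_{sex}"
    print(f"\n=== partition {label}: {part['stratum_id'].nunique()} strata, "
          f"{part.loc[part.case == 1, 'animal_year'].nunique()} clusters ===")
    for spec in default_variants(mains, ("canopy_pct",), (2, 3)):
        fit = fit_clr(build_design(part, spec))
        status = "converged" if fit.converged else "NOT CONVERGED"
        print(f"  {spec.name:22s} loglik {fit.loglik:9.2f}  ({status}, "
              f"{len(fit.beta)} terms)")
        fit.save(args.out / f"{label}_{spec.name}_coefficients.csv",
                 args.out / f"{label}_{spec.name}_fit.json")
    best = args.out / f"{label}_spline2_canopy_pct_coefficients.csv"
    print(pd.read_csv(best).round(3).to_string(index=False))
print(f"\nwrote coefficient tables and fit sidecars to {args.out}")
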