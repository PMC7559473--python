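"""Config-driven orchestration: telemetry + rasters -> fitted models, model
comparison, validation, and selection-curve tables.

A run is described by a TOML config (paths, partition definitions, analysis
parameters, seed) and executes, per population-sex partition:

    aggregate -> steps -> kernels -> availability -> annotate -> standardize
    -> collinearity screen -> variant comparison (QIC + LOOCV) -> curves

All outputs are CSV/JSON under the configured output directory; identical
config + seed reproduces them byte-for-byte. A manifest records per-stage
record counts, cluster counts, and warnings.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clr import Interaction, ModelSpec
from .covariates import (DEFAULT_PRIORITY, annotate, collinearity_screen, derive_stack,
                         standardize)
from .errors import ConfigurationError
from .evaluation import compare_variants, default_variants, selection_curve
from .raster import CovariateStack, RasterLayer
from .steps import aggregate_fixes, build_steps, build_strata, fit_movement_kernel
from .synthetic import (LandscapeConfig, SimulationConfig, generate_landscape,
                        read_telemetry, save_true_model, simulate_population,
                        write_telemetry)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the TOML config layout."""

    telemetry: Path
    canopy: Path
    water: Path
    elevation: Path
    out_dir: Path
    partitions: list[dict] = field(default_factory=list)  # {label, filters:{col: value}}
    target_interval_h: float = 8.0
    tolerance: float = 0.25
    n_available: int = 10
    min_steps: int = 20
    kernel_kind: str = "empirical"
    interaction_covariates: tuple[str, ...] = ("canopy_pct",)
    spline_dfs: tuple[int, ...] = (2, 3)
    collinearity_threshold: float = 0.70
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    loocv_bins: int = 10
    loocv_min_strata: int = 20
    latitude_deg: float = 65.0
    curve_canopy_quantiles: tuple[float, ...] = (0.9,)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        paths = raw.get("paths", {})
        params = raw.get("params", {})
        base = path.parent
        try:
            cfg = cls(
                telemetry=base / paths["telemetry"],
                canopy=base / paths["canopy"],
                water=base / paths["water"],
                elevation=base / paths["elevation"],
                out_dir=base / paths.get("out_dir", "outputs"),
                partitions=raw.get("partitions", []),
                seed=int(raw.get("seed", 0)),
                **{k: tuple(v) if isinstance(v, list) else v for k, v in params.items()},
            )
        except KeyError as exc:
            raise ConfigurationError(f"config missing required path: {exc}") from exc
        return cfg

    def validate(self) -> None:
        for name in ("telemetry", "canopy", "water", "elevation"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        if self.n_available < 1:
            raise ConfigurationError("n_available must be >= 1")


def _partition_frames(track: pd.DataFrame, partitions: list[dict]):
    if not partitions:
        yield "all", track
        return
    for part in partitions:
        label = part["label"]
        sub = track
        for col, val in part.get("filters", {}).items():
            if col not in sub.columns:
                raise ConfigurationError(f"partition '{label}' filters on missing column '{col}'")
            sub = sub[sub[col] == val]
        yield label, sub


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk).

    Partitions with fewer than 2 animals are skipped with a reason; a failure
    inside one partition is recorded and the remaining partitions proceed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    track = read_telemetry(config.telemetry)
    stack = CovariateStack(
        canopy=RasterLayer.read_ascii(config.canopy),
        water=RasterLayer.read_ascii(config.water),
        elevation=RasterLayer.read_ascii(config.elevation),
        latitude=np.deg2rad(config.latitude_deg),
    )
    derive_stack(stack)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items()},
        "n_fixes_in": int(len(track)),
        "partitions": {},
    }
    labels = [p["label"] for p in config.partitions] or ["all"]
    seeds = dict(zip(labels, np.random.SeedSequence([config.seed, 0xBEE]).spawn(len(labels))))

    for label, sub in _partition_frames(track, config.partitions):
        rec: dict = {"n_fixes": int(len(sub))}
        manifest["partitions"][label] = rec
        try:
            if sub["animal_id"].nunique() < 2:
                rec["skipped"] = "fewer than 2 animals"
                continue
            agg = aggregate_fixes(sub, config.target_interval_h, config.tolerance)
            rec["n_fixes_aggregated"] = int(len(agg))
            steps = build_steps(agg)
            rec["n_steps"] = int(len(steps))
            kernels = fit_movement_kernel(steps, config.min_steps, config.kernel_kind)
            strata = build_strata(steps, kernels, config.n_available, seeds[label])
            rec["n_strata"] = int(strata["stratum_id"].nunique())
            table = annotate(strata, stack)
            rec["n_strata_dropped"] = int(table.attrs["n_dropped_strata"])
            rec["n_strata_annotated"] = int(table["stratum_id"].nunique())
            rec["n_clusters"] = int(table.loc[table.case == 1, "animal_year"].nunique())
            table, record = standardize(table)
            record.to_csv(out / f"{label}_standardization.csv")
            retained, report = collinearity_screen(
                table, config.collinearity_threshold, config.priority)
            report.to_csv(out / f"{label}_collinearity.csv", index=False)
            rec["covariates_retained"] = retained

            variants = default_variants(
                tuple(retained),
                tuple(c for c in config.interaction_covariates if c in retained),
                config.spline_dfs)
            comp = compare_variants(table, variants, n_bins=config.loocv_bins,
                                    min_strata=config.loocv_min_strata)
            comp.to_csv(out / f"{label}_model_comparison.csv")
            rec["best_qic"] = comp.best_qic
            rec["best_loocv"] = comp.best_loocv
            rec["warnings"] = comp.warnings
            for name, fit in comp.fits.items():
                fit.save(out / f"{label}_{name}_coefficients.csv",
                         out / f"{label}_{name}_fit.json")

            best = comp.fits[comp.best_qic]
            if best.bases:
                cov = next(iter(best.bases))
                temps = table.loc[table.case == 1, "temperature_c"].to_numpy()
                grid = np.round(np.linspace(temps.min(), temps.max(), 41), 6)
                levels = np.quantile(table[cov], config.curve_canopy_quantiles)
                ref = float(np.quantile(table[cov], 0.5))
                curves = selection_curve(best, grid, levels, reference_level=ref,
                                         experienced_temperatures=temps, covariate=cov)
                curves.to_csv(out / f"{label}_selection_curves.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - isolate partition failures
            logger.exception("partition %s failed", label)
            rec["error"] = f"{type(exc).__name__}: {exc}"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# packaged synthetic fixture
# ---------------------------------------------------------------------------

#: the fixture's true selection coefficients (generator standardized scale);
#: same structure as the SimulationConfig default
FIXTURE_BETA = {
    "canopy_pct": -0.7,
    "dist_water_m": -0.4,
    "elevation_m": 0.2,
    "sri": -0.2,
    "canopy_pct:temp_ns2[1]": 2.5,
    "canopy_pct:temp_ns2[2]": -1.5,
}


def fixture_configs(seed: int = 0) -> tuple[LandscapeConfig, SimulationConfig]:
    """Desk-scale study system: 8 animals on a 150 x 150 landscape, 120 steps
    each at 8-h fixes. The movement scale is kept small relative to the
    4.5 km world so tracks rarely reach the boundary."""
    land = LandscapeConfig(n_rows=150, n_cols=150, seed=seed)
    sim = SimulationConfig(
        n_animals=8, n_steps_per_animal=120, step_shape=1.6, step_scale=110.0,
        beta_true=dict(FIXTURE_BETA), seed=seed + 1)
    return land, sim


def make_fixture(seed: int = 0, out_dir: str | Path = "fixture") -> Path:
    """Generate the packaged synthetic dataset plus a ready-to-run config.

    Writes canopy/water/elevation ASCII grids, a telemetry CSV with
    population and sex labels (2 populations x 2 sexes x 2 animals), the
    true generating model as JSON, and ``config.toml`` for
    :func:`run_pipeline`. Byte-identical for a given seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    land_cfg, sim_cfg = fixture_configs(seed)
    stack = generate_landscape(land_cfg)
    track, model = simulate_population(stack, sim_cfg)

    pops = {0: "north", 1: "north", 2: "north", 3: "north",
            4: "south", 5: "south", 6: "south", 7: "south"}
    sexes = {0: "f", 1: "f", 2: "m", 3: "m", 4: "f", 5: "f", 6: "m", 7: "m"}
    idx = track["animal_id"].str.slice(1).astype(int)
    track["population"] = idx.map(pops)
    track["sex"] = idx.map(sexes)

    stack.canopy.write_ascii(out / "canopy.asc", fmt="%.4f")
    stack.water.write_ascii(out / "water.asc", fmt="%.0f")
    stack.elevation.write_ascii(out / "elevation.asc", fmt="%.3f")
    write_telemetry(track, out / "telemetry.csv")
    save_true_model(model, out / "true_model.json")
    with open(out / "meta.json", "w") as fh:
        json.dump({"seed": seed, "beta_true": sim_cfg.beta_true,
                   "landscape": vars(land_cfg).copy() if hasattr(land_cfg, "__dict__") else None,
                   "n_animals": sim_cfg.n_animals,
                   "n_steps_per_animal": sim_cfg.n_steps_per_animal}, fh, indent=2, default=str)

    partitions = "\n".join(
        f'[[partitions]]\nlabel = "{pop}_{sex}"\n'
        f'filters = {{ population = "{pop}", sex = "{sex}" }}\n'
        for pop in ("north", "south") for sex in ("f", "m"))
    config_text = (
        f"seed = {seed}\n\n"
        "[paths]\n"
        'telemetry = "telemetry.csv"\n'
        'canopy = "canopy.asc"\n'
        'water = "water.asc"\n'
        'elevation = "elevation.asc"\n'
        'out_dir = "outputs"\n\n'
        "[params]\n"
        'kernel_kind = "empirical"\n'
        "loocv_min_strata = 20\n\n"
        f"{partitions}")
    (out / "config.toml").write_text(config_text)
    return out
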