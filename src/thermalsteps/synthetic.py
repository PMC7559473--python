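"""Synthetic landscapes, temperature series, and SSF-governed animal tracks.

The real telemetry this pipeline was designed around (GPS-collared moose,
restricted data) cannot be shipped, so this module generates a miniature
study system with the same structure and *known* selection parameters:

* spatially autocorrelated covariate fields (percent canopy, a water mask,
  elevation) built from Gaussian-smoothed white noise;
* an ambient temperature series with a 24-h diurnal sinusoid plus noise,
  shared by all animals (it emulates a regional gridded product, which is
  why temperature is constant within a stratum downstream);
* correlated-random-walk tracks (gamma step lengths, von Mises turning
  angles) in which each step's endpoint is chosen among ``n_candidates``
  kernel proposals with probability proportional to ``exp(beta' x)`` — the
  generative inverse of the step-selection model fitted downstream.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import ConfigurationError, SpecificationError
from .raster import CovariateStack, RasterLayer
from .splines import NaturalSplineBasis, natural_spline_basis

TELEMETRY_COLUMNS = ["animal_id", "timestamp", "x", "y", "temperature_c"]


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and texture of the synthetic covariate fields."""

    n_rows: int = 150
    n_cols: int = 150
    cell_size: float = 30.0
    smoothing_scale: float = 4.0      # Gaussian kernel sd, in pixels
    water_fraction: float = 0.05
    relief_amplitude: float = 120.0   # elevation sd, meters
    elevation_base: float = 300.0
    canopy_mean: float = 40.0         # target mean canopy percent
    canopy_spread: float = 3.0        # logistic steepness of the canopy rescale
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ConfigurationError("landscape grid needs >= 2 rows and columns")
        if not 0 <= self.water_fraction <= 1:
            raise ConfigurationError("water_fraction must lie in [0, 1]")
        if self.smoothing_scale < 0:
            raise ConfigurationError("smoothing_scale must be >= 0")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Movement, selection and temperature parameters of the generator.

    ``beta_true`` maps design-column names to coefficients on the generator's
    standardized scale (each covariate divided by twice its landscape SD).
    Recognised names: the covariates ``canopy_pct``, ``dist_water_m``,
    ``elevation_m``, ``sri`` and, for the temperature interaction,
    ``<covariate>:temp_ns{df}[j]`` with j in 1..df (natural-spline segment
    terms) or ``<covariate>:temperature_c`` (linear interaction).
    """

    n_animals: int = 8
    n_steps_per_animal: int = 120
    fix_interval: float = 8.0           # hours
    step_shape: float = 1.8             # gamma shape of step lengths
    step_scale: float = 220.0           # gamma scale, meters
    turn_concentration: float = 0.6     # von Mises kappa
    n_candidates: int = 50
    # Default selection kernel: static avoidance of open canopy plus a
    # nonlinear thermal-cover response (positive and saturating at warm
    # temperatures, weak or reversed when cool) — the sign structure seen in
    # fitted thermal SSFs for heat-sensitive ungulates.
    beta_true: dict[str, float] = field(
        default_factory=lambda: {
            "canopy_pct": -0.7,
            "dist_water_m": -0.5,
            "elevation_m": 0.3,
            "sri": -0.3,
            "canopy_pct:temp_ns2[1]": 2.5,
            "canopy_pct:temp_ns2[2]": -1.5,
        }
    )
    spline_df: int = 2
    temp_mean: float = 13.0             # deg C, summer boreal ambient
    temp_diurnal_amplitude: float = 6.0
    temp_noise_sd: float = 2.5
    start_time: str = "2015-06-01T00:00:00"
    seed: int = 0

    def validate(self) -> None:
        if self.n_candidates < 2:
            raise ConfigurationError("n_candidates must be >= 2")
        if self.step_scale <= 0 or self.step_shape <= 0:
            raise ConfigurationError("gamma step parameters must be > 0")
        if self.fix_interval <= 0:
            raise ConfigurationError("fix_interval must be > 0")
        if self.temp_noise_sd < 0:
            raise ConfigurationError("temp_noise_sd must be >= 0")


def _smoothed_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (unit variance, zero mean)."""
    z = rng.standard_normal(shape)
    if scale > 0:
        z = ndimage.gaussian_filter(z, sigma=scale, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_landscape(config: LandscapeConfig) -> CovariateStack:
    """Generate aligned canopy / water / elevation layers.

    Canopy is a logistic rescale of a smoothed Gaussian field into [0, 100];
    water is an independent smoothed field thresholded at the quantile that
    yields ``water_fraction``; elevation is a third independent field scaled
    by ``relief_amplitude``. Same seed, same config -> bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)

    zc = _smoothed_field(rng, shape, config.smoothing_scale)
    offset = np.log(config.canopy_mean / (100.0 - config.canopy_mean))
    canopy = 100.0 * expit(zc * config.canopy_spread / 2.0 + offset)

    zw = _smoothed_field(rng, shape, config.smoothing_scale)
    if config.water_fraction <= 0:
        water = np.zeros(shape)
        water[0, 0] = 1.0  # keep the distance transform well-defined
    elif config.water_fraction >= 1:
        water = np.ones(shape)
    else:
        thresh = np.quantile(zw, 1.0 - config.water_fraction)
        water = (zw > thresh).astype(float)

    ze = _smoothed_field(rng, shape, config.smoothing_scale)
    elevation = config.elevation_base + config.relief_amplitude * ze

    def layer(vals: np.ndarray) -> RasterLayer:
        return RasterLayer(vals, origin_x=0.0, origin_y=config.n_rows * config.cell_size,
                           cell_size=config.cell_size)

    return CovariateStack(canopy=layer(canopy), water=layer(water), elevation=layer(elevation))


def simulate_temperature(n_fixes: int, config: SimulationConfig) -> np.ndarray:
    """Ambient temperature at each fix: mean + 24-h sinusoid + Gaussian noise.

    The sinusoid peaks mid-afternoon relative to the fix clock; with an 8-h
    fix interval the deterministic part has period 3 in fix index.
    """
    config.validate()
    if n_fixes < 1:
        raise ConfigurationError("n_fixes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E49]))
    hours = np.arange(n_fixes) * config.fix_interval
    sinusoid = config.temp_diurnal_amplitude * np.sin(2 * np.pi * hours / 24.0)
    noise = rng.normal(0.0, config.temp_noise_sd, n_fixes) if config.temp_noise_sd > 0 else 0.0
    return config.temp_mean + sinusoid + noise


@dataclass(frozen=True, eq=False)
class TrueModel:
    """The generator's selection kernel: term names, coefficients, spline basis,
    and the fixed standardization divisors that define the coefficient scale."""

    terms: tuple[str, ...]
    beta: np.ndarray
    divisors: dict[str, float]
    temp_basis: NaturalSplineBasis | None

    def to_jsonable(self) -> dict:
        d = {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "divisors": self.divisors,
        }
        if self.temp_basis is not None:
            d["temp_basis"] = {
                "boundary": list(self.temp_basis.boundary),
                "interior": list(self.temp_basis.interior),
            }
        return d


def _landscape_divisors(stack: CovariateStack) -> dict[str, float]:
    """2 x SD of each covariate over all raster cells — the generator's fixed
    standardization, independent of any realized track."""
    from .covariates import derive_stack  # local import to avoid a cycle

    stack = derive_stack(stack)
    out = {}
    for name, layer in (
        ("canopy_pct", stack.canopy),
        ("dist_water_m", stack.dist_water),
        ("elevation_m", stack.elevation),
        ("sri", stack.sri),
    ):
        sd = float(np.std(layer.values, ddof=1))
        if sd <= 0:
            sd = 1.0
        out[name] = 2.0 * sd
    return out


def build_true_model(stack: CovariateStack, temperatures: np.ndarray,
                     config: SimulationConfig) -> TrueModel:
    """Resolve ``beta_true`` names against the covariate stack and freeze the
    temperature spline basis (knots from the simulated ambient series)."""
    known = {"canopy_pct", "dist_water_m", "elevation_m", "sri"}
    basis = None
    needs_spline = any(":temp_ns" in t for t in config.beta_true)
    if needs_spline:
        _, basis = natural_spline_basis(np.asarray(temperatures), config.spline_df)
    terms, beta = [], []
    for name, b in config.beta_true.items():
        root = name.split(":")[0]
        if root not in known:
            raise SpecificationError(f"beta_true names unknown covariate '{root}'")
        if ":" in name:
            suffix = name.split(":")[1]
            if suffix.startswith("temp_ns"):
                df = int(suffix[len("temp_ns")])
                if df != config.spline_df:
                    raise SpecificationError(
                        f"term '{name}' uses df={df} but spline_df={config.spline_df}")
            elif suffix != "temperature_c":
                raise SpecificationError(f"unrecognised interaction term '{name}'")
        terms.append(name)
        beta.append(float(b))
    return TrueModel(
        terms=tuple(terms),
        beta=np.asarray(beta),
        divisors=_landscape_divisors(stack),
        temp_basis=basis,
    )


def _design_at(model: TrueModel, stack: CovariateStack, x: np.ndarray, y: np.ndarray,
               temp: float) -> np.ndarray:
    """Evaluate the true-model design at endpoints (x, y) and temperature."""
    from .covariates import derive_stack

    stack = derive_stack(stack)
    raw = {
        "canopy_pct": stack.canopy.sample(x, y),
        "dist_water_m": stack.dist_water.sample(x, y),
        "elevation_m": stack.elevation.sample(x, y),
        "sri": stack.sri.sample(x, y),
    }
    std = {k: v / model.divisors[k] for k, v in raw.items()}
    if model.temp_basis is not None:
        bt = model.temp_basis.transform([temp])[0]
    cols = []
    for term in model.terms:
        root = term.split(":")[0]
        if ":" not in term:
            cols.append(std[root])
        elif "temp_ns" in term:
            j = int(term.split("[")[1].rstrip("]"))
            cols.append(std[root] * bt[j - 1])
        else:
            cols.append(std[root] * temp)
    return np.column_stack(cols)


def simulate_track(
    stack: CovariateStack,
    temperatures: np.ndarray,
    config: SimulationConfig,
    *,
    animal_id: str = "A00",
    rng: np.random.Generator | None = None,
    true_model: TrueModel | None = None,
    return_diagnostics: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Simulate one animal's track as a habitat-driven correlated random walk.

    At each fix the animal proposes ``n_candidates`` endpoints from the
    gamma/von Mises kernel (relative to its previous bearing), evaluates the
    true selection kernel exp(beta' x) at each, and moves to one chosen with
    those (normalized) probabilities. Proposals falling off the raster are
    redrawn (up to 100 rounds, then a fresh uniform bearing is used).

    Returns a telemetry frame with columns animal_id, timestamp, x, y,
    temperature_c; one row per fix (n_steps_per_animal + 1 rows).
    """
    config.validate()
    temperatures = np.asarray(temperatures, dtype=float)
    if len(temperatures) < config.n_steps_per_animal + 1:
        raise ConfigurationError("need one temperature per fix")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if true_model is None:
        true_model = build_true_model(stack, temperatures, config)

    xmin, xmax, ymin, ymax = stack.canopy.extent
    margin = 0.5 * stack.canopy.cell_size
    # start away from the edge so early steps rarely need redraws
    x0 = rng.uniform(xmin + 0.2 * (xmax - xmin), xmax - 0.2 * (xmax - xmin))
    y0 = rng.uniform(ymin + 0.2 * (ymax - ymin), ymax - 0.2 * (ymax - ymin))
    bearing = rng.uniform(-np.pi, np.pi)

    xs, ys = [x0], [y0]
    picks: list[int] = []
    K = config.n_candidates
    for step in range(config.n_steps_per_animal):
        base_bearing = bearing
        cx = np.empty(K)
        cy = np.empty(K)
        ch = np.empty(K)
        need = np.ones(K, dtype=bool)
        for attempt in range(200):
            n = int(need.sum())
            if n == 0:
                break
            lengths = rng.gamma(config.step_shape, config.step_scale, n)
            turns = rng.vonmises(0.0, config.turn_concentration, n)
            head = base_bearing + turns
            px = xs[-1] + lengths * np.cos(head)
            py = ys[-1] + lengths * np.sin(head)
            ok = (px > xmin + margin) & (px < xmax - margin) & \
                 (py > ymin + margin) & (py < ymax - margin)
            idx = np.flatnonzero(need)[ok]
            cx[idx], cy[idx], ch[idx] = px[ok], py[ok], head[ok]
            need[idx] = False
            if attempt == 99:  # give up on the inherited bearing, draw afresh
                base_bearing = rng.uniform(-np.pi, np.pi)
        if need.any():  # pragma: no cover - pathological landscape
            raise ConfigurationError("could not place candidates inside the raster")
        X = _design_at(true_model, stack, cx, cy, float(temperatures[step]))
        eta = X @ true_model.beta
        w = np.exp(eta - eta.max())
        pick = int(rng.choice(K, p=w / w.sum()))
        picks.append(pick)
        xs.append(float(cx[pick]))
        ys.append(float(cy[pick]))
        bearing = float(ch[pick])

    times = pd.Timestamp(config.start_time) + pd.to_timedelta(
        np.arange(config.n_steps_per_animal + 1) * config.fix_interval, unit="h")
    track = pd.DataFrame({
        "animal_id": animal_id,
        "timestamp": times,
        "x": xs,
        "y": ys,
        "temperature_c": temperatures[: config.n_steps_per_animal + 1],
    })
    if return_diagnostics:
        return track, {"chosen_index": np.array(picks), "true_model": true_model}
    return track


def simulate_population(
    stack: CovariateStack, config: SimulationConfig
) -> tuple[pd.DataFrame, TrueModel]:
    """Simulate ``n_animals`` tracks sharing one ambient temperature series.

    Per-animal RNG streams are split from the master seed so adding an animal
    does not perturb the others' draws.
    """
    config.validate()
    temps = simulate_temperature(config.n_steps_per_animal + 1, config)
    model = build_true_model(stack, temps, config)
    seeds = np.random.SeedSequence([config.seed, 0x5717]).spawn(config.n_animals)
    tracks = [
        simulate_track(stack, temps, config, animal_id=f"A{i:02d}",
                       rng=np.random.default_rng(seeds[i]), true_model=model)
        for i in range(config.n_animals)
    ]
    return pd.concat(tracks, ignore_index=True), model


def write_telemetry(track: pd.DataFrame, path: str | Path) -> None:
    """Write a telemetry frame as CSV with ISO-8601 UTC timestamps."""
    out = track.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.3f")


def read_telemetry(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a telemetry CSV; ``column_map`` renames foreign column names onto
    the package's (Movebank-like mappings go here)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("animal_id", "timestamp", "x", "y") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"telemetry file missing columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df


def save_true_model(model: TrueModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_jsonable(), fh, indent=2)


def config_to_json(config: LandscapeConfig | SimulationConfig) -> dict:
    return asdict(config)
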