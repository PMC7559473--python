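"""From raw GPS fixes to matched used/available strata.

The used-available design: each observed step (a pair of consecutive fixes
at a near-constant interval) is matched with M available steps starting from
the same fix at the same time, whose lengths and turning angles are drawn
from the animal's own movement kernel. A used step plus its M available
steps form a *stratum*, the conditioning unit of the conditional-logistic
likelihood.

Coordinates must be projected (meters); geographic coordinates are rejected.
Bearings are mathematical angles from atan2(dy, dx); turning angles are
signed differences of consecutive bearings wrapped to (-pi, pi],
counter-clockwise positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, KernelError

logger = logging.getLogger(__name__)

STEP_COLUMNS = [
    "animal_id", "burst_id", "t_start", "dt_h", "x_start", "y_start",
    "x_end", "y_end", "length_m", "abs_bearing", "turn_angle", "temperature_c",
]


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2 * np.pi) - np.pi)
    return out


def _check_projected(df: pd.DataFrame) -> None:
    # a track whose coordinates all fit in lon/lat ranges is almost surely
    # geographic; planar math on degrees is silently wrong, so refuse
    x, y = df["x"].to_numpy(float), df["y"].to_numpy(float)
    if np.abs(x).max() <= 180 and np.abs(y).max() <= 90:
        raise DataError(
            "coordinates look geographic (degrees); project the track to a metric CRS first"
        )


def aggregate_fixes(
    track: pd.DataFrame, target_interval: float = 8.0, tolerance: float = 0.25
) -> pd.DataFrame:
    """Greedily thin a fix series toward a target interval and split bursts.

    Walking forward in time, a fix is kept when its gap from the last kept
    fix reaches ``target*(1 - tolerance)``; gaps above ``target*(1 +
    tolerance)`` cannot be bridged by a step, so the next fix starts a new
    burst. Operates per animal; adds a ``burst_id`` column.
    """
    if not 0 <= tolerance < 1:
        raise ConfigurationError("tolerance must lie in [0, 1)")
    lo = target_interval * (1 - tolerance)
    hi = target_interval * (1 + tolerance)
    out = []
    for animal, g in track.groupby("animal_id", sort=True):
        t = pd.to_datetime(g["timestamp"]).to_numpy()
        if not (np.diff(t) > np.timedelta64(0, "s")).all():
            raise DataError(f"animal {animal}: timestamps not strictly increasing")
        keep = [0]
        burst = [0]
        burst_id = 0
        hours = (t - t[0]) / np.timedelta64(1, "h")
        for i in range(1, len(t)):
            gap = hours[i] - hours[keep[-1]]
            if gap < lo:
                continue
            if gap > hi:
                burst_id += 1
            keep.append(i)
            burst.append(burst_id)
        kept = g.iloc[keep].copy()
        kept["burst_id"] = [f"{animal}-b{b}" for b in burst]
        out.append(kept)
    return pd.concat(out, ignore_index=True)


def build_steps(track: pd.DataFrame, temperature_at: str = "start") -> pd.DataFrame:
    """Turn an aggregated fix series into steps with lengths and turn angles.

    One step per consecutive fix pair within a burst. The first step of a
    burst has no prior bearing, hence an undefined (NaN) turn angle, and is
    later excluded from strata. Bursts with fewer than 2 fixes yield no
    steps and are logged. ``temperature_at`` picks which fix's ambient
    temperature a step (and hence its stratum) carries: "start" (default)
    or "end".
    """
    if temperature_at not in ("start", "end"):
        raise ConfigurationError("temperature_at must be 'start' or 'end'")
    _check_projected(track)
    if "burst_id" not in track.columns:
        track = track.assign(burst_id=track["animal_id"])
    rows = []
    for (animal, burst), g in track.groupby(["animal_id", "burst_id"], sort=True):
        if len(g) < 2:
            logger.warning("burst %s of animal %s has < 2 fixes; skipped", burst, animal)
            continue
        t = pd.to_datetime(g["timestamp"]).to_numpy()
        x = g["x"].to_numpy(float)
        y = g["y"].to_numpy(float)
        dx, dy = np.diff(x), np.diff(y)
        dt = np.diff(t) / np.timedelta64(1, "h")
        if (dt <= 0).any():
            raise DataError(f"non-increasing timestamps in burst {burst}")
        bearing = np.arctan2(dy, dx)
        turn = np.full(len(bearing), np.nan)
        turn[1:] = wrap_angle(np.diff(bearing))
        if "temperature_c" in g.columns:
            series = g["temperature_c"].to_numpy(float)
            temp = series[:-1] if temperature_at == "start" else series[1:]
        else:
            temp = np.full(len(dx), np.nan)
        rows.append(pd.DataFrame({
            "animal_id": animal, "burst_id": burst,
            "t_start": t[:-1], "dt_h": dt,
            "x_start": x[:-1], "y_start": y[:-1],
            "x_end": x[1:], "y_end": y[1:],
            "length_m": np.hypot(dx, dy),
            "abs_bearing": wrap_angle(bearing),
            "turn_angle": turn,
            "temperature_c": temp,
        }))
    if not rows:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# movement kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmpiricalKernel:
    """An animal's movement kernel as the raw observed samples.

    Draws resample the stored step lengths and turning angles independently,
    with replacement — the literal reading of sampling availability from
    "empirical distributions".
    """

    animal_id: str
    lengths: np.ndarray
    turns: np.ndarray

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return (rng.choice(self.lengths, size=n, replace=True),
                rng.choice(self.turns, size=n, replace=True))


@dataclass(frozen=True)
class ParametricKernel:
    """Gamma step lengths and von Mises turning angles fitted by ML.

    Optional alternative to raw resampling; matches the kernel family the
    synthetic generator moves by, which removes availability-model
    misspecification from parameter-recovery experiments.
    """

    animal_id: str
    shape: float
    scale: float
    kappa: float
    mu: float = 0.0

    def draw(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        return (rng.gamma(self.shape, self.scale, n),
                wrap_angle(rng.vonmises(self.mu, self.kappa, n)))


def fit_movement_kernel(
    steps: pd.DataFrame,
    min_steps: int = 20,
    kind: str = "empirical",
    pooled: bool = False,
) -> dict[str, EmpiricalKernel | ParametricKernel]:
    """Fit one movement kernel per animal from its steps with defined turns.

    ``kind`` is "empirical" (resampling, default) or "parametric"
    (gamma / von Mises by maximum likelihood). Animals with fewer than
    ``min_steps`` usable steps raise a KernelError naming them. With
    ``pooled=True`` a single population-level kernel is fitted from all
    animals' steps and shared (every animal key maps to it); per-individual
    kernels are the default.
    """
    if pooled:
        merged = steps.copy()
        animals = sorted(steps["animal_id"].unique())
        merged["animal_id"] = "pooled"
        shared = fit_movement_kernel(merged, min_steps, kind)["pooled"]
        return {a: shared for a in animals}
    kernels: dict[str, EmpiricalKernel | ParametricKernel] = {}
    for animal, g in steps.groupby("animal_id", sort=True):
        usable = g[np.isfinite(g["turn_angle"])]
        if len(usable) < min_steps:
            raise KernelError(
                f"animal {animal}: {len(usable)} steps with defined turn angle "
                f"(< min_steps={min_steps})"
            )
        lengths = usable["length_m"].to_numpy(float)
        turns = usable["turn_angle"].to_numpy(float)
        if kind == "empirical":
            kernels[animal] = EmpiricalKernel(animal, lengths, turns)
        elif kind == "parametric":
            shape, _, scale = stats.gamma.fit(np.maximum(lengths, 1e-9), floc=0)
            kappa, mu, _ = stats.vonmises.fit(turns, fscale=1)
            kernels[animal] = ParametricKernel(animal, shape, scale, kappa, mu)
        else:
            raise ConfigurationError(f"unknown kernel kind '{kind}'")
    return kernels


# ---------------------------------------------------------------------------
# availability sampling
# ---------------------------------------------------------------------------

def build_strata(
    steps: pd.DataFrame,
    kernels: dict[str, EmpiricalKernel | ParametricKernel],
    M: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Match every step having a prior bearing with M available steps.

    Available endpoints are placed at the step's start, at a kernel-drawn
    length along (prior bearing + kernel-drawn turn angle), where the prior
    bearing is the bearing of the preceding observed step. Returns a long
    frame: one row per member, columns ``stratum_id, animal_id, animal_year,
    case, x, y, t, temperature_c`` (x, y, t are endpoint coordinates and the
    start-fix time). Per-animal RNG substreams make the draw for one animal
    independent of the presence of others.
    """
    if M < 1:
        raise ConfigurationError("M must be >= 1")
    base = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence([int(seed), 0xA5A1]))
    animals = sorted(steps["animal_id"].unique())
    streams = dict(zip(animals, base.spawn(len(animals))))
    out = []
    for animal, g in steps.groupby("animal_id", sort=True):
        rng = np.random.default_rng(streams[animal])
        usable = g[np.isfinite(g["turn_angle"])]
        if usable.empty:
            continue
        prior = wrap_angle(usable["abs_bearing"].to_numpy(float)
                           - usable["turn_angle"].to_numpy(float))
        n = len(usable)
        lengths, turns = kernels[animal].draw(n * M, rng)
        lengths = lengths.reshape(n, M)
        heads = prior[:, None] + turns.reshape(n, M)
        ax = usable["x_start"].to_numpy(float)[:, None] + lengths * np.cos(heads)
        ay = usable["y_start"].to_numpy(float)[:, None] + lengths * np.sin(heads)

        t_start = pd.to_datetime(usable["t_start"])
        years = t_start.dt.year.to_numpy()
        sid = [f"{animal}-s{i:05d}" for i in range(n)]
        used = pd.DataFrame({
            "stratum_id": sid,
            "animal_id": animal,
            "animal_year": [f"{animal}-{y}" for y in years],
            "case": 1,
            "x": usable["x_end"].to_numpy(float),
            "y": usable["y_end"].to_numpy(float),
            "t": t_start.to_numpy(),
            "temperature_c": usable["temperature_c"].to_numpy(float),
        })
        avail = used.loc[used.index.repeat(M)].copy()
        avail["case"] = 0
        avail["x"] = ax.ravel()
        avail["y"] = ay.ravel()
        out.append(pd.concat([used, avail], ignore_index=True))
    if not out:
        return pd.DataFrame(columns=[
            "stratum_id", "animal_id", "animal_year", "case", "x", "y", "t", "temperature_c"])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["stratum_id", "case"], ascending=[True, False],
                           kind="stable").reset_index(drop=True)


def sample_available(
    step: pd.Series,
    kernel: EmpiricalKernel | ParametricKernel,
    M: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Build one stratum (used + M available rows) for a single step.

    Thin wrapper over :func:`build_strata`; the step must have a defined
    turn angle (prior bearing).
    """
    if not np.isfinite(step["turn_angle"]):
        raise DataError("step has no prior bearing (undefined turn angle)")
    one = step.to_frame().T
    one = one.astype({c: float for c in
                      ("dt_h", "x_start", "y_start", "x_end", "y_end",
                       "length_m", "abs_bearing", "turn_angle")})
    return build_strata(one, {step["animal_id"]: kernel}, M=M, seed=seed)
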