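"""Habitat covariates: derivation, stratum annotation, scaling, screening.

Four continuous covariates drive the selection models: percent canopy
(thermal cover), Euclidean distance to the nearest water pixel, elevation,
and a solar radiation index (SRI) computed from latitude, slope and aspect.
Ambient temperature rides along per stratum but is never a covariate main
effect — it is constant within a stratum and cancels from the conditional
likelihood, so it only enters through interactions.

Covariates are standardized by dividing by twice their standard deviation,
which puts coefficients of binary and continuous predictors on a comparable
scale; pairs of predictors correlated beyond |r| > 0.70 are screened with an
explicit priority order deciding which member survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ConfigurationError, DataError, DomainError, SpecificationError
from .raster import CovariateStack, RasterLayer

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ["canopy_pct", "dist_water_m", "elevation_m", "sri"]

#: who wins when two covariates are collinear: thermal cover first, then
#: water (ecologically primary for thermoregulation), then the rest.
DEFAULT_PRIORITY = ("canopy_pct", "dist_water_m", "elevation_m", "sri")


# ---------------------------------------------------------------------------
# raster derivations
# ---------------------------------------------------------------------------

def distance_to_water(water_mask: RasterLayer) -> RasterLayer:
    """Exact Euclidean distance (m) from each cell center to the nearest
    water-cell center; water cells hold 0."""
    mask = water_mask.values
    water = (mask == 1.0)
    if not water.any():
        raise DomainError("water mask contains no water pixels")
    dist = ndimage.distance_transform_edt(~water, sampling=water_mask.cell_size)
    return RasterLayer(dist, water_mask.origin_x, water_mask.origin_y,
                       water_mask.cell_size, water_mask.nodata)


def terrain_derivatives(dem: RasterLayer) -> tuple[np.ndarray, np.ndarray]:
    """Slope and aspect from a DEM by Horn's eight-neighbour method.

    Returns
    -------
    slope
        Radians in [0, pi/2).
    aspect
        Downslope direction, radians clockwise from north in [0, 2*pi);
        NaN where the surface is flat (aspect undefined).

    Edge cells use edge-replicated padding; any nodata value inside a cell's
    3x3 window makes that cell's outputs nodata (NaN).
    """
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ConfigurationError("DEM must be at least 3x3")
    bad = (z == dem.nodata) | ~np.isfinite(z)
    zp = np.pad(np.where(bad, np.nan, z), 1, mode="edge")
    cell = dem.cell_size

    # window corners/edges; rows run north -> south
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]

    dz_de = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell)
    dz_dn = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cell)

    slope = np.arctan(np.hypot(dz_de, dz_dn))
    aspect = np.mod(np.arctan2(-dz_de, -dz_dn), 2 * np.pi)
    flat = (dz_de == 0) & (dz_dn == 0)
    aspect[flat] = np.nan
    nan_window = ~np.isfinite(slope) | bad  # a cell's own nodata poisons its window
    slope[nan_window] = np.nan
    aspect[nan_window] = np.nan
    return slope, aspect


def solar_radiation_index(latitude: float, slope: np.ndarray, aspect: np.ndarray) -> np.ndarray:
    """Daily-average extraterrestrial solar radiation on a tilted surface.

    The index is the mean over a 24-h equinoctial day (solar declination 0,
    unit solar constant) of the cosine of the solar incidence angle on the
    surface, restricted to hours when the sun is above the flat horizon and
    in front of the surface. A flat surface at latitude L gets cos(L)/pi.

    Computed in closed form: with slope S and aspect A (clockwise from
    north), the incidence cosine at hour angle h is R*cos(h + psi) where
    R = sqrt(C^2 + D^2), psi = atan2(D, C),
    C = cos(S)cos(L) - sin(S)sin(L)cos(A), D = sin(S)sin(A);
    the integral over the daylight window is then elementary.

    Parameters
    ----------
    latitude
        Radians, |latitude| <= pi/2.
    slope
        Radians in [0, pi/2].
    aspect
        Radians clockwise from north; ignored (any finite value or NaN)
        where slope == 0.
    """
    if not abs(latitude) <= np.pi / 2:
        raise DomainError("latitude must lie in [-pi/2, pi/2] radians")
    slope = np.asarray(slope, dtype=float)
    aspect = np.asarray(aspect, dtype=float)
    if np.any((slope < 0) | (slope > np.pi / 2)):
        raise DomainError("slope must lie in [0, pi/2] radians")
    a = np.where(np.isfinite(aspect), aspect, 0.0)  # flat-surface limit
    C = np.cos(slope) * np.cos(latitude) - np.sin(slope) * np.sin(latitude) * np.cos(a)
    D = np.sin(slope) * np.sin(a)
    R = np.hypot(C, D)
    psi = np.arctan2(D, C)
    # daylight: h in (-pi/2, pi/2); surface lit: h + psi in (-pi/2, pi/2)
    lo = np.maximum(-np.pi / 2, -np.pi / 2 - psi)
    hi = np.minimum(np.pi / 2, np.pi / 2 - psi)
    window = np.maximum(hi - lo, 0.0)
    integral = np.where(window > 0, R * (np.sin(hi + psi) - np.sin(lo + psi)), 0.0)
    return integral / (2 * np.pi)


def derive_stack(stack: CovariateStack, latitude: float | None = None) -> CovariateStack:
    """Fill in the derived layers (distance-to-water, SRI) of a stack.

    Idempotent: returns the stack unchanged if both are already present.
    """
    if stack.dist_water is not None and stack.sri is not None:
        return stack
    lat = stack.latitude if latitude is None else latitude
    if stack.dist_water is None:
        stack.dist_water = distance_to_water(stack.water)
    if stack.sri is None:
        slope, aspect = terrain_derivatives(stack.elevation)
        sri = solar_radiation_index(lat, np.nan_to_num(slope, nan=0.0), aspect)
        dem = stack.elevation
        stack.sri = RasterLayer(sri, dem.origin_x, dem.origin_y, dem.cell_size, dem.nodata)
    return stack


# ---------------------------------------------------------------------------
# stratum annotation
# ---------------------------------------------------------------------------

def annotate(
    strata: pd.DataFrame,
    stack: CovariateStack,
    temperatures: pd.Series | None = None,
) -> pd.DataFrame:
    """Attach covariates to every stratum member by nearest-cell sampling.

    Parameters
    ----------
    strata
        Long frame with one row per stratum member (used and available):
        ``stratum_id, animal_id, animal_year, case, x, y, t`` and optionally
        ``temperature_c``.
    stack
        Covariate stack; derived layers are computed if missing.
    temperatures
        Optional per-stratum ambient temperature indexed by ``stratum_id``;
        required if the strata carry no ``temperature_c`` column. One value
        per stratum is copied to all its members (temperature does not vary
        within a stratum).

    Strata with *any* member outside any layer's extent are dropped whole;
    the count is logged and recorded in ``table.attrs['n_dropped_strata']``.
    """
    stack = derive_stack(stack)
    table = strata.copy()
    if temperatures is not None:
        table["temperature_c"] = table["stratum_id"].map(temperatures)
    if "temperature_c" not in table.columns or table["temperature_c"].isna().any():
        raise DataError("strata need a temperature per stratum (column or `temperatures`)")

    x = table["x"].to_numpy(float)
    y = table["y"].to_numpy(float)
    ok = stack.canopy.inside(x, y)
    bad_strata = set(table.loc[~ok, "stratum_id"])
    n_dropped = len(bad_strata)
    if n_dropped:
        logger.warning("annotate: dropped %d strata with off-raster members", n_dropped)
        table = table[~table["stratum_id"].isin(bad_strata)].reset_index(drop=True)
        x = table["x"].to_numpy(float)
        y = table["y"].to_numpy(float)

    table["canopy_pct"] = stack.canopy.sample(x, y)
    table["dist_water_m"] = stack.dist_water.sample(x, y)
    table["elevation_m"] = stack.elevation.sample(x, y)
    table["sri"] = stack.sri.sample(x, y)

    counts = table.groupby("stratum_id")["case"].sum()
    if not (counts == 1).all():
        raise DataError("every stratum must contain exactly one used (case=1) row")
    table.attrs["n_dropped_strata"] = n_dropped
    return table


# ---------------------------------------------------------------------------
# scaling and screening
# ---------------------------------------------------------------------------

@dataclass
class StandardizationRecord:
    """Per-covariate mean, SD and the 2*SD divisor actually applied."""

    stats: pd.DataFrame  # index: covariate; columns: mean, sd, divisor

    def divisor(self, name: str) -> float:
        return float(self.stats.loc[name, "divisor"])

    def to_csv(self, path) -> None:
        self.stats.to_csv(path, index_label="covariate")

    @classmethod
    def from_csv(cls, path) -> "StandardizationRecord":
        return cls(pd.read_csv(path, index_col="covariate"))

    @classmethod
    def from_divisors(cls, divisors: dict[str, float]) -> "StandardizationRecord":
        df = pd.DataFrame({
            "mean": np.nan, "sd": {k: v / 2.0 for k, v in divisors.items()},
            "divisor": divisors,
        })
        return cls(df[["mean", "sd", "divisor"]])


def standardize(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    record: StandardizationRecord | None = None,
    *,
    center: bool = False,
) -> tuple[pd.DataFrame, StandardizationRecord]:
    """Scale covariates by dividing each by twice its standard deviation.

    SDs are computed over all rows (used and available pooled), the only
    choice that keeps both halves of the design on one scale. Centering is
    off by default — the scaling rule is a pure division — and would cancel
    from the conditional likelihood anyway. Pass a ``record`` to apply
    previously computed divisors (e.g. training-fold scaling to a test fold).
    """
    columns = columns or [c for c in COVARIATE_COLUMNS if c in table.columns]
    out = table.copy()
    if record is None:
        rows = {}
        for col in columns:
            v = out[col].to_numpy(float)
            sd = float(np.std(v, ddof=1))
            if not sd > 0:
                raise ConfigurationError(f"covariate '{col}' is constant; cannot standardize")
            rows[col] = {"mean": float(v.mean()), "sd": sd, "divisor": 2.0 * sd}
        record = StandardizationRecord(pd.DataFrame(rows).T[["mean", "sd", "divisor"]])
    for col in columns:
        v = out[col].to_numpy(float)
        if center:
            v = v - float(record.stats.loc[col, "mean"])
        out[col] = v / record.divisor(col)
    return out, record


def collinearity_screen(
    table: pd.DataFrame,
    threshold: float = 0.70,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    columns: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop the lower-priority member of every covariate pair with |r| > threshold.

    Returns the retained covariate names (in priority order) and a report of
    all pairwise Pearson correlations with a ``dropped`` flag.
    """
    columns = columns or [c for c in COVARIATE_COLUMNS if c in table.columns]
    if len(columns) < 2:
        raise ConfigurationError("collinearity screen needs at least 2 covariates")
    corr = table[columns].corr(method="pearson")

    ranked = [c for c in priority if c in columns]
    unranked = [c for c in columns if c not in priority]
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for col in ranked:
        clash = [k for k in retained if abs(corr.loc[col, k]) > threshold]
        if clash:
            dropped[col] = clash[0]
        else:
            retained.append(col)
    for col in unranked:
        clash = [k for k in retained if abs(corr.loc[col, k]) > threshold]
        if clash:
            raise SpecificationError(
                f"covariates '{col}' and '{clash[0]}' exceed |r| > {threshold} but "
                f"'{col}' has no rank in the priority list; extend the priority order"
            )
        retained.append(col)

    pairs = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = float(corr.loc[a, b])
            pairs.append({
                "covariate_a": a, "covariate_b": b, "pearson_r": r,
                "exceeds_threshold": abs(r) > threshold,
                "dropped": dropped.get(a) == b or dropped.get(b) == a,
            })
    report = pd.DataFrame(pairs)
    if dropped:
        logger.info("collinearity screen dropped: %s", dropped)
    return retained, report


def validate_temperature(collar_series, gridded_series) -> tuple[float, float]:
    """Regress collar temperature on a gridded product and summarize agreement.

    Returns ``(r_squared, rmse_c)``: the OLS coefficient of determination and
    the root-mean-square difference of the raw paired series (deg C).
    """
    collar = np.asarray(collar_series, dtype=float)
    gridded = np.asarray(gridded_series, dtype=float)
    if collar.shape != gridded.shape or collar.ndim != 1:
        raise DataError("collar and gridded series must be equal-length 1-D")
    if collar.size < 3:
        raise DataError("need at least 3 paired observations")
    if np.std(gridded) == 0:
        raise DataError("gridded series has zero variance; regression undefined")
    fit = stats.linregress(gridded, collar)
    rmse = float(np.sqrt(np.mean((collar - gridded) ** 2)))
    return float(fit.rvalue**2), rmse
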