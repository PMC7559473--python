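"""Model comparison (QIC) and leave-one-animal-out validation.

QIC — the quasi-likelihood under independence criterion — is the AIC
analogue for GEE-style fits: QIC = -2 * loglik + 2 * trace(A @ V_robust),
with A the naive (independence) information at the optimum. When the robust
and naive covariances coincide the penalty collapses to 2p and QIC is AIC.

Predictive validation leaves out one animal at a time, refits on the rest,
scores every member of the held-out animal's strata by exp(beta' x), bins
all scored points into equal-frequency bins, and rank-correlates bin rank
with the count of *used* points per bin (Boyce-style). The mean Spearman
coefficient over folds summarizes predictive ability; it is invariant to
monotone transforms of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clr import DesignMatrix, FitResult, Interaction, ModelSpec, build_design, fit_clr, \
    predict_design
from .errors import ConvergenceError, DataError
from .covariates import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)


def qic(fit: FitResult) -> float:
    """Quasi-likelihood under independence criterion of a converged CLR fit."""
    if not fit.converged:
        raise ConvergenceError("QIC requires a converged fit")
    if fit.robust_cov is None:
        raise ConvergenceError("QIC requires the robust covariance")
    penalty = 2.0 * float(np.trace(fit.naive_info @ fit.robust_cov))
    return -2.0 * fit.loglik + penalty


@dataclass
class CVResult:
    """Leave-one-animal-out validation scores."""

    per_fold: pd.DataFrame       # columns: animal_id, spearman_rho, n_strata
    n_bins: int
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_rho(self) -> float:
        return float(self.per_fold["spearman_rho"].mean())

    @property
    def mean_pct(self) -> float:
        """Mean Spearman rho expressed as a percentage."""
        return 100.0 * self.mean_rho

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


def _bin_rank_rho(scores: np.ndarray, case: np.ndarray, n_bins: int) -> float:
    """Spearman correlation between equal-frequency score-bin rank and the
    number of used points falling in each bin. Ties get average ranks."""
    ranks = stats.rankdata(scores, method="average")
    edges = np.quantile(ranks, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, ranks, side="right") - 1, 0, n_bins - 1)
    used_counts = np.bincount(bins[case == 1], minlength=n_bins)
    rho = float(stats.spearmanr(np.arange(1, n_bins + 1), used_counts).statistic)
    # a perfectly monotone count profile is exactly +/-1; shed float fuzz
    if abs(abs(rho) - 1.0) < 1e-12:
        rho = float(np.sign(rho))
    return rho


def score_points(fit: FitResult, table: pd.DataFrame) -> np.ndarray:
    """SSF score exp(beta' x) of every row of an annotated covariate table."""
    X = predict_design(fit, table)
    eta = X @ fit.beta
    return np.exp(eta - eta.max())


def loocv(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_bins: int = 10,
    min_strata: int = 20,
) -> CVResult:
    """Leave-one-animal-out cross-validation of one model spec.

    Each animal with at least ``min_strata`` strata is held out in turn; the
    model is refit on the remaining animals and the held-out animal's points
    are scored and binned. Folds whose training fit fails to converge are
    skipped and recorded.
    """
    animals = sorted(table["animal_id"].unique())
    if len(animals) < 2:
        raise DataError("leave-one-animal-out needs at least 2 animals")
    rows = []
    warnings: list[str] = []
    for animal in animals:
        held = table[table["animal_id"] == animal]
        n_held = held["stratum_id"].nunique()
        if n_held < min_strata:
            warnings.append(f"fold {animal}: skipped ({n_held} strata < {min_strata})")
            continue
        train = table[table["animal_id"] != animal]
        try:
            fit = fit_clr(build_design(train, spec), compute_robust=False)
        except Exception as exc:  # noqa: BLE001 - fold failure is data-dependent
            warnings.append(f"fold {animal}: fit failed ({exc})")
            continue
        if not fit.converged:
            warnings.append(f"fold {animal}: fit did not converge; fold skipped")
            continue
        scores = score_points(fit, held)
        rho = _bin_rank_rho(scores, held["case"].to_numpy(int), n_bins)
        rows.append({"animal_id": animal, "spearman_rho": rho, "n_strata": n_held})
    if warnings:
        logger.info("loocv: %s", "; ".join(warnings))
    return CVResult(pd.DataFrame(rows, columns=["animal_id", "spearman_rho", "n_strata"]),
                    n_bins, warnings)


def default_variants(
    main_effects: tuple[str, ...],
    interaction_covariates: tuple[str, ...] = ("canopy_pct",),
    spline_dfs: tuple[int, ...] = (2, 3),
) -> list[ModelSpec]:
    """The three model families compared: a base model with main effects
    only, linear temperature interactions, and natural-spline temperature
    interactions with 2 or 3 basis columns (one variant per covariate)."""
    variants = [ModelSpec(main_effects, (), name="base")]
    for cov in interaction_covariates:
        variants.append(ModelSpec(
            main_effects, (Interaction(cov, "linear"),), name=f"linear_{cov}"))
        for df in spline_dfs:
            variants.append(ModelSpec(
                main_effects, (Interaction(cov, "spline", df),), name=f"spline{df}_{cov}"))
    return variants


@dataclass
class ModelComparison:
    """QIC and LOOCV for a set of model variants on one data partition."""

    table: pd.DataFrame           # per variant, sorted by QIC ascending
    fits: dict[str, FitResult]
    best_qic: str
    best_loocv: str | None
    agreement: bool | None
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_variants(
    table: pd.DataFrame,
    variants: list[ModelSpec] | None = None,
    *,
    include_loocv: bool = True,
    n_bins: int = 10,
    min_strata: int = 20,
) -> ModelComparison:
    """Fit every variant, rank by QIC, optionally validate by LOOCV.

    The base variant anchors the deltas (its delta_qic is 0 by definition).
    The "best" model has the lowest QIC and the highest LOOCV; when the two
    rules disagree both winners are reported, not resolved.
    """
    if variants is None:
        mains = tuple(c for c in COVARIATE_COLUMNS if c in table.columns)
        variants = default_variants(mains)
    base_name = variants[0].name
    rows = []
    fits: dict[str, FitResult] = {}
    warnings: list[str] = []
    for spec in variants:
        try:
            fit = fit_clr(build_design(table, spec))
            if not fit.converged:
                raise ConvergenceError("variant did not converge")
            q = qic(fit)
        except Exception as exc:  # noqa: BLE001 - keep comparing the rest
            warnings.append(f"variant {spec.name}: {exc}")
            logger.warning("compare_variants: variant %s failed: %s", spec.name, exc)
            continue
        fits[spec.name] = fit
        row = {"variant": spec.name, "qic": q, "n_params": len(fit.beta),
               "loglik": fit.loglik}
        if include_loocv:
            cv = loocv(table, spec, n_bins=n_bins, min_strata=min_strata)
            row["loocv_mean_rho"] = cv.mean_rho
            row["loocv_pct"] = cv.mean_pct
            row["n_folds"] = cv.n_folds
            warnings.extend(cv.warnings)
        rows.append(row)
    if not rows:
        raise ConvergenceError("no variant could be fitted")
    comp = pd.DataFrame(rows)
    if base_name in set(comp["variant"]):
        base_qic = float(comp.loc[comp["variant"] == base_name, "qic"].iloc[0])
        comp["delta_qic"] = comp["qic"] - base_qic
        if include_loocv:
            base_cv = float(comp.loc[comp["variant"] == base_name, "loocv_pct"].iloc[0])
            comp["delta_loocv_pct"] = comp["loocv_pct"] - base_cv
    comp = comp.sort_values("qic", kind="stable").reset_index(drop=True)
    best_qic = str(comp["variant"].iloc[0])
    best_loocv = None
    agreement = None
    if include_loocv:
        best_loocv = str(comp.loc[comp["loocv_mean_rho"].idxmax(), "variant"])
        agreement = best_loocv == best_qic
        if not agreement:
            warnings.append(
                f"QIC favors '{best_qic}' but LOOCV favors '{best_loocv}'")
    return ModelComparison(comp, fits, best_qic, best_loocv, agreement, warnings)


def selection_curve(
    fit: FitResult,
    temperature_grid: np.ndarray,
    canopy_levels: np.ndarray,
    reference_level: float = 0.0,
    experienced_temperatures: np.ndarray | None = None,
    percentiles: tuple[float, float] = (0.10, 0.90),
    covariate: str = "canopy_pct",
) -> pd.DataFrame:
    """Conditional selection probability of a covariate level vs. a reference
    across a temperature grid, with pointwise 95% Wald bands.

    For each (temperature, level) pair the linear-predictor contrast between
    the level and ``reference_level`` (at that same temperature) is formed;
    the probability is expit(contrast) and the band comes from the robust
    covariance of the contrast. Temperatures outside the fitted spline's
    boundary knots are flagged as extrapolated (linear tails).
    """
    if not fit.converged:
        raise ConvergenceError("selection_curve needs a converged fit")
    temperature_grid = np.asarray(temperature_grid, dtype=float)
    canopy_levels = np.atleast_1d(np.asarray(canopy_levels, dtype=float))
    cov = fit.robust_cov if fit.robust_cov is not None else fit.naive_cov

    other = {c: 0.0 for c in (fit.spec.main_effects if fit.spec else ())}
    basis = fit.bases.get(covariate)
    lo, hi = (basis.boundary if basis is not None else (-np.inf, np.inf))

    q10, q90 = (np.quantile(experienced_temperatures, percentiles)
                if experienced_temperatures is not None else (np.nan, np.nan))
    out = []
    for level in canopy_levels:
        pts = pd.DataFrame({**other, covariate: level,
                            "temperature_c": temperature_grid})
        ref = pd.DataFrame({**other, covariate: reference_level,
                            "temperature_c": temperature_grid})
        d = predict_design(fit, pts) - predict_design(fit, ref)
        eta = d @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", d, cov, d))
        out.append(pd.DataFrame({
            "temperature_c": temperature_grid,
            "canopy_level": level,
            "probability": _expit(eta),
            "lo95": _expit(eta - 1.96 * se),
            "hi95": _expit(eta + 1.96 * se),
            "extrapolated": (temperature_grid < lo) | (temperature_grid > hi),
            "temp_p10": q10,
            "temp_p90": q90,
        }))
    return pd.concat(out, ignore_index=True)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))
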