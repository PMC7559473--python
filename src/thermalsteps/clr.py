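"""Conditional logistic regression for matched used/available strata.

The likelihood is the matched case-control conditional likelihood

    L(beta) = prod_s  exp(beta' x_used,s) / sum_{j in s} exp(beta' x_j,s),

the form that classical CLR software maximizes. Stratum-constant terms
(including ambient temperature as a main effect) cancel, which is why
temperature may only enter through interactions. The likelihood is concave,
so a damped Newton-Raphson with analytic gradient and Hessian is reliable.

Cluster-robust (GEE sandwich) covariance uses animal-year clusters:
V = A^{-1} B A^{-1} with A the observed information and B the outer-product
sum of within-cluster score sums. The sandwich is trustworthy with at least
20 independent clusters, comfortably so with 30 — fits warn below those
marks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, SpecificationError
from .splines import NaturalSplineBasis, natural_spline_basis

logger = logging.getLogger(__name__)

TEMPERATURE = "temperature_c"


@dataclass(frozen=True)
class Interaction:
    """One covariate x temperature interaction term group."""

    covariate: str
    form: str = "spline"       # "linear" or "spline"
    df: int = 2                # spline basis dimension, 2 or 3
    boundary: tuple[float, float] | None = None   # explicit spline knots,
    interior: tuple[float, ...] | None = None     # else data quantiles

    def __post_init__(self) -> None:
        if self.form not in ("linear", "spline"):
            raise SpecificationError(f"unknown interaction form '{self.form}'")


@dataclass(frozen=True)
class ModelSpec:
    """Term structure of one model variant.

    ``main_effects`` are covariate columns entering linearly;
    ``interactions`` are covariate x ambient-temperature terms, linear or
    natural-spline with df in {2, 3}. Temperature itself can never be a main
    effect: it is constant within strata and cancels from the conditional
    likelihood, so requesting it is a specification error.
    """

    main_effects: tuple[str, ...]
    interactions: tuple[Interaction, ...] = ()
    name: str = "model"

    def __post_init__(self) -> None:
        if TEMPERATURE in self.main_effects:
            raise SpecificationError(
                "ambient temperature cannot be a main effect: it does not vary "
                "within strata and cancels from the conditional likelihood; "
                "use an interaction term instead"
            )


@dataclass
class DesignMatrix:
    """A realized design: X plus the stratum / case / cluster bookkeeping."""

    X: np.ndarray
    columns: list[str]
    stratum_id: np.ndarray
    case: np.ndarray
    cluster: np.ndarray
    spec: ModelSpec
    bases: dict[str, NaturalSplineBasis] = field(default_factory=dict)

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.stratum_id))

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster))


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Build the design matrix for a covariate table under a model spec.

    Spline interactions contribute ``df`` columns named
    ``cov:ns(temperature_c,df)[j]``; linear interactions one column
    ``cov:temperature_c``; the base model is main effects only. The design is
    checked for full column rank after within-stratum centering (rank
    deficiency would leave the conditional likelihood unidentified).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cov in spec.main_effects:
        if cov not in table.columns:
            raise SpecificationError(f"main effect '{cov}' not in covariate table")
        cols.append(table[cov].to_numpy(float))
        names.append(cov)
    bases: dict[str, NaturalSplineBasis] = {}
    temps = table[TEMPERATURE].to_numpy(float) if TEMPERATURE in table.columns else None
    for inter in spec.interactions:
        if inter.covariate not in table.columns:
            raise SpecificationError(f"interaction covariate '{inter.covariate}' not in table")
        if temps is None:
            raise SpecificationError("interactions need a temperature_c column")
        v = table[inter.covariate].to_numpy(float)
        if inter.form == "linear":
            cols.append(v * temps)
            names.append(f"{inter.covariate}:{TEMPERATURE}")
        else:
            B, basis = natural_spline_basis(
                temps, inter.df, boundary=inter.boundary, interior=inter.interior)
            bases[inter.covariate] = basis
            for j in range(inter.df):
                cols.append(v * B[:, j])
                names.append(f"{inter.covariate}:ns({TEMPERATURE},{inter.df})[{j + 1}]")
    if not cols:
        raise SpecificationError("model spec has no terms")
    X = np.column_stack(cols)

    stratum = table["stratum_id"].to_numpy()
    case = table["case"].to_numpy(int)
    cluster = (table["animal_year"].to_numpy() if "animal_year" in table.columns
               else table["stratum_id"].to_numpy())
    design = DesignMatrix(X, names, stratum, case, cluster, spec, bases)

    Xc = X - _stratum_means(design)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        raise SpecificationError(
            "design is rank-deficient after within-stratum centering; "
            "some terms are stratum-constant or collinear"
        )
    return design


def _group_offsets(stratum_id: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sort order, group start offsets, per-row group index); rows need not
    be pre-sorted by stratum."""
    order = np.argsort(stratum_id, kind="stable")
    sorted_ids = stratum_id[order]
    starts = np.flatnonzero(np.r_[True, sorted_ids[1:] != sorted_ids[:-1]])
    group_of_sorted = np.cumsum(np.r_[0, sorted_ids[1:] != sorted_ids[:-1]])
    return order, starts, group_of_sorted


def _stratum_means(design: DesignMatrix) -> np.ndarray:
    order, starts, gids = _group_offsets(design.stratum_id)
    Xs = design.X[order]
    sums = np.add.reduceat(Xs, starts, axis=0)
    counts = np.add.reduceat(np.ones(len(Xs)), starts)
    means_sorted = sums[gids] / counts[gids, None]
    out = np.empty_like(design.X)
    out[order] = means_sorted
    return out


@dataclass
class FitResult:
    """Fitted CLR coefficients with naive and cluster-robust covariance."""

    beta: np.ndarray
    columns: list[str]
    loglik: float
    naive_cov: np.ndarray
    naive_info: np.ndarray
    robust_cov: np.ndarray | None
    n_strata: int
    n_clusters: int
    n_iter: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None
    bases: dict[str, NaturalSplineBasis] = field(default_factory=dict)

    def se(self, robust: bool = True) -> np.ndarray:
        cov = self.robust_cov if (robust and self.robust_cov is not None) else self.naive_cov
        return np.sqrt(np.diag(cov))

    def summary(self) -> pd.DataFrame:
        """Per-term table: estimate, robust and naive SE, z, two-sided p."""
        rse = self.se(robust=True)
        z = self.beta / rse
        return pd.DataFrame({
            "term": self.columns,
            "estimate": self.beta,
            "robust_se": rse,
            "naive_se": self.se(robust=False),
            "z": z,
            "p_value": 2 * stats.norm.sf(np.abs(z)),
        })

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.summary().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "loglik": self.loglik, "n_strata": self.n_strata,
                "n_clusters": self.n_clusters, "converged": bool(self.converged),
                "n_iter": self.n_iter, "warnings": self.warnings,
                "beta": dict(zip(self.columns, self.beta.tolist())),
                "robust_cov": None if self.robust_cov is None else self.robust_cov.tolist(),
                "naive_cov": self.naive_cov.tolist(),
                "bases": {
                    cov: {"boundary": list(b.boundary), "interior": list(b.interior)}
                    for cov, b in self.bases.items()
                },
            }
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def _loglik_parts(beta, Xs, ys, starts, gids):
    eta = Xs @ beta
    gmax = np.maximum.reduceat(eta, starts)
    ex = np.exp(eta - gmax[gids])
    denom = np.add.reduceat(ex, starts)
    p = ex / denom[gids]
    ll = float(eta[ys == 1].sum() - (np.log(denom) + gmax).sum())
    return ll, p


def _detect_separation(design: DesignMatrix) -> list[str]:
    """Columns whose used value is the strict extreme in every stratum —
    these give a monotone likelihood (no finite maximizer)."""
    order, starts, gids = _group_offsets(design.stratum_id)
    Xs, ys = design.X[order], design.case[order]
    flagged = []
    for j, name in enumerate(design.columns):
        col = Xs[:, j]
        mx = np.maximum.reduceat(col, starts)
        mn = np.minimum.reduceat(col, starts)
        used = col[ys == 1]
        # one used row per stratum, in stratum order
        hi = (used >= mx) & (used > mn)
        lo = (used <= mn) & (used < mx)
        if hi.all() or lo.all():
            flagged.append(name)
    return flagged


def fit_clr(
    design: DesignMatrix,
    *,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    loglik_tol: float = 1e-10,
    compute_robust: bool = True,
    drop_novar_strata: bool = True,
) -> FitResult:
    """Maximize the conditional likelihood by Newton-Raphson with step-halving.

    Convergence: max |score| < ``score_tol`` or relative log-likelihood
    change < ``loglik_tol``. Strata with no within-stratum covariate
    variation contribute nothing and are dropped (logged). Complete
    separation is detected and reported; the result is then flagged
    non-converged rather than reporting runaway coefficients.
    """
    warnings: list[str] = []
    order, starts, gids = _group_offsets(design.stratum_id)
    Xs = design.X[order]
    ys = design.case[order]
    clus = design.cluster[order]

    if drop_novar_strata:
        dev = np.abs(Xs - np.add.reduceat(Xs, starts, axis=0)[gids] /
                     np.add.reduceat(np.ones(len(Xs)), starts)[gids, None])
        novar = np.maximum.reduceat(dev.max(axis=1), starts) < 1e-12
        if novar.any():
            keep = ~novar[gids]
            n_drop = int(novar.sum())
            warnings.append(f"dropped {n_drop} strata without covariate variation")
            logger.warning("fit_clr: dropped %d strata without covariate variation", n_drop)
            Xs, ys, clus = Xs[keep], ys[keep], clus[keep]
            sid = design.stratum_id[order][keep]
            order2, starts, gids = _group_offsets(sid)
            Xs, ys, clus = Xs[order2], ys[order2], clus[order2]

    if len(Xs) == 0:
        raise ConvergenceError("no usable strata")
    counts = np.add.reduceat(ys, starts)
    if not (counts == 1).all():
        raise SpecificationError("every stratum must have exactly one case row")

    sep = _detect_separation(
        DesignMatrix(Xs, design.columns, np.repeat(np.arange(len(starts)),
                     np.diff(np.r_[starts, len(Xs)])), ys, clus, design.spec))
    separated = bool(sep)
    if separated:
        warnings.append(f"complete separation in: {', '.join(sep)}")
        logger.warning("fit_clr: separation diagnostic for %s", sep)

    p_dim = Xs.shape[1]
    beta = np.zeros(p_dim)
    ll, p = _loglik_parts(beta, Xs, ys, starts, gids)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = Xs.T @ (ys - p)
        G = np.add.reduceat(p[:, None] * Xs, starts, axis=0)
        A = (Xs * p[:, None]).T @ Xs - G.T @ G
        if np.abs(U).max() < score_tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(A, U)
        except np.linalg.LinAlgError:
            warnings.append("singular information matrix")
            break
        step = 1.0
        for _ in range(30):
            ll_new, p_new = _loglik_parts(beta + step * delta, Xs, ys, starts, gids)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        if abs(ll_new - ll) < loglik_tol * (abs(ll) + 1.0):
            beta, ll, p = beta + step * delta, ll_new, p_new
            converged = True
            break
        beta, ll, p = beta + step * delta, ll_new, p_new

    # final information at the optimum
    G = np.add.reduceat(p[:, None] * Xs, starts, axis=0)
    A = (Xs * p[:, None]).T @ Xs - G.T @ G
    try:
        naive_cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        naive_cov = np.full((p_dim, p_dim), np.nan)
        warnings.append("information matrix not invertible at the optimum")
        converged = False
    if separated:
        converged = False

    n_clusters = len(np.unique(clus))
    fit = FitResult(
        beta=beta, columns=list(design.columns), loglik=ll,
        naive_cov=naive_cov, naive_info=A, robust_cov=None,
        n_strata=len(starts), n_clusters=n_clusters,
        n_iter=it, converged=converged, warnings=warnings,
        spec=design.spec, bases=dict(design.bases),
    )
    if compute_robust and converged and n_clusters >= 2:
        inner = DesignMatrix(Xs, design.columns,
                             np.repeat(np.arange(len(starts)),
                                       np.diff(np.r_[starts, len(Xs)])),
                             ys, clus, design.spec)
        fit.robust_cov = robust_covariance(fit, inner)
    elif compute_robust and converged:
        warnings.append("robust covariance refused: fewer than 2 clusters")
    return fit


def robust_covariance(fit: FitResult, design: DesignMatrix,
                      cluster_correction: bool = False) -> np.ndarray:
    """Cluster-robust sandwich covariance A^{-1} B A^{-1}.

    A is the observed information at the optimum; B sums, over clusters, the
    outer products of within-cluster sums of per-stratum scores
    (x_used - weighted stratum mean). Warns below 20 clusters and notes
    20 <= n < 30. ``cluster_correction`` applies the optional G/(G-1)
    small-sample factor; off by default.
    """
    if not fit.converged:
        raise ConvergenceError("robust covariance needs a converged fit")
    order, starts, gids = _group_offsets(design.stratum_id)
    Xs, ys, clus = design.X[order], design.case[order], design.cluster[order]
    _, p = _loglik_parts(fit.beta, Xs, ys, starts, gids)
    G = np.add.reduceat(p[:, None] * Xs, starts, axis=0)      # weighted mean * 1
    used = Xs[ys == 1]                                         # one per stratum
    scores = used - G                                          # per-stratum score
    clus_of_stratum = clus[ys == 1]
    uniq = np.unique(clus_of_stratum)
    if len(uniq) < 2:
        raise ConvergenceError("robust covariance refused with a single cluster")
    if len(uniq) < 20:
        msg = f"only {len(uniq)} clusters (< 20): robust variance may be biased"
        fit.warnings.append(msg)
        logger.warning("robust_covariance: %s", msg)
    elif len(uniq) < 30:
        msg = f"{len(uniq)} clusters (20 <= n < 30): robust variance acceptable, 30+ preferred"
        fit.warnings.append(msg)
        logger.info("robust_covariance: %s", msg)
    frame = pd.DataFrame(scores)
    sums = frame.groupby(pd.Series(clus_of_stratum)).sum().to_numpy()
    B = sums.T @ sums
    if cluster_correction:
        B = B * len(uniq) / (len(uniq) - 1)
    Ainv = np.linalg.inv(fit.naive_info)
    V = Ainv @ B @ Ainv
    return (V + V.T) / 2


def predict_design(fit: FitResult, settings: pd.DataFrame) -> np.ndarray:
    """Rebuild design rows for new covariate settings using the fitted spec
    and the *fitted* spline bases (so prediction uses the training knots)."""
    if fit.spec is None:
        raise SpecificationError("fit carries no model spec")
    cols = []
    for cov in fit.spec.main_effects:
        if cov not in settings.columns:
            raise SpecificationError(f"setting missing term '{cov}'")
        cols.append(settings[cov].to_numpy(float))
    temps = settings[TEMPERATURE].to_numpy(float) if TEMPERATURE in settings.columns else None
    for inter in fit.spec.interactions:
        if inter.covariate not in settings.columns or temps is None:
            raise SpecificationError(
                f"setting missing term '{inter.covariate}' or '{TEMPERATURE}'")
        v = settings[inter.covariate].to_numpy(float)
        if inter.form == "linear":
            cols.append(v * temps)
        else:
            B = fit.bases[inter.covariate].transform(temps)
            for j in range(inter.df):
                cols.append(v * B[:, j])
    return np.column_stack(cols)


def selection_probability(
    fit: FitResult,
    points: pd.DataFrame,
    reference: pd.DataFrame | pd.Series,
) -> np.ndarray:
    """Conditional (paired-choice) probability of choosing each point over a
    reference setting: exp(eta(x)) / (exp(eta(x)) + exp(eta(ref))).

    Points and reference are covariate settings on the standardized scale;
    the reference may be a single row (broadcast) or one row per point.
    """
    if not fit.converged:
        raise ConvergenceError("selection_probability needs a converged fit")
    if isinstance(reference, pd.Series):
        reference = reference.to_frame().T
    Xp = predict_design(fit, points)
    Xr = predict_design(fit, reference)
    if Xr.shape[0] == 1:
        Xr = np.broadcast_to(Xr, Xp.shape)
    eta_diff = (Xp - Xr) @ fit.beta
    return 1.0 / (1.0 + np.exp(-eta_diff))
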