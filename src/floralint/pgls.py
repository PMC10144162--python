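"""Phylogenetic generalized least squares under three evolutionary models.

Closely related species are not independent data points: under Brownian
motion (BM) the covariance of a trait between two species is proportional
to the length of their shared root-to-ancestor path.  Pagel's lambda (PL)
scales the off-diagonal of that matrix by a signal parameter
``lambda in [0, 1]`` (0 = star phylogeny, 1 = BM), and the stationary
Ornstein-Uhlenbeck (OU) model gives tip correlations ``exp(-alpha * d_ij)``
in the patristic distance ``d_ij`` (Martins-Hansen form).  Regression
coefficients are estimated by GLS with the chosen covariance; the
structural parameter (lambda or alpha) is profiled out by maximum
likelihood, and models are compared by AIC.

Estimation is ML throughout.  Standard errors apply the usual
ML-to-unbiased rescale ``n / (n - p)`` of the error variance; t tests use
``n - p`` residual degrees of freedom (not reduced for the estimated
structural parameter, matching common comparative-methods practice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .errors import NumericError, ValidationError
from .trees import PhyloTree

__all__ = [
    "PhyloCovariance",
    "PGLSFit",
    "build_covariance",
    "fit_gls",
    "fit_pgls",
    "compare_evolutionary_models",
    "screen_predictors",
]

MODELS = ("BM", "PL", "OU")


@dataclass
class PhyloCovariance:
    """Tip covariance/correlation structure under one evolutionary model."""

    model: str
    matrix: np.ndarray
    tip_order: tuple[str, ...]
    parameter: float | None = None  # lambda (PL) or alpha (OU); None for BM


@dataclass
class PGLSFit:
    """One fitted (P)GLS regression."""

    model: str  # "BM" | "PL" | "OU" | "GLS" (fixed covariance)
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    coef_names: tuple[str, ...]
    sigma2_ml: float
    loglik: float
    aic: float
    n: int
    df_resid: int
    parameter: float | None = None  # estimated lambda or alpha
    parameter_name: str | None = None
    at_boundary: bool = False
    degenerate: bool = False
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def summary_row(self) -> dict:
        """Single-predictor reporting convention: slope is the last coefficient."""
        return {
            "model": self.model,
            "b": float(self.coef[-1]),
            "se": float(self.se[-1]),
            "t": float(self.t[-1]),
            "p": float(self.p[-1]),
            "parameter": None if self.parameter is None else float(self.parameter),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
        }


def build_covariance(
    tree: PhyloTree,
    model: str,
    parameter: float | None = None,
    *,
    tip_order=None,
) -> PhyloCovariance:
    """Covariance structure over the tree tips under one evolutionary model.

    BM: ``C_ij`` = shared root-to-MRCA path length, diagonal = root-to-tip
    depth.  PL: BM with off-diagonals multiplied by ``lambda``.  OU:
    correlation ``exp(-alpha * d_ij)`` with unit diagonal.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown evolutionary model {model!r}; use one of {MODELS}")
    order = tuple(tip_order) if tip_order is not None else tuple(tree.tip_labels)
    if model == "BM":
        if parameter is not None:
            raise ValidationError("BM takes no structural parameter")
        mat = tree.bm_covariance(order)
    elif model == "PL":
        lam = 1.0 if parameter is None else float(parameter)
        if not 0.0 <= lam <= 1.0:
            raise ValidationError(f"Pagel's lambda must lie in [0, 1], got {lam}")
        mat = tree.bm_covariance(order)
        diag = np.diag(mat).copy()
        mat = mat * lam
        np.fill_diagonal(mat, diag)
    else:  # OU
        if parameter is None or parameter <= 0:
            raise ValidationError(f"OU needs alpha > 0, got {parameter}")
        mat = np.exp(-float(parameter) * tree.patristic_matrix(order))
    try:
        cholesky(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"{model} covariance is not positive-definite: {exc}") from exc
    return PhyloCovariance(model=model, matrix=mat, tip_order=order, parameter=parameter)


def _as_matrix(V) -> np.ndarray:
    return V.matrix if isinstance(V, PhyloCovariance) else np.asarray(V, float)


def fit_gls(
    y: np.ndarray,
    X: np.ndarray,
    V,
    *,
    coef_names=None,
    model: str = "GLS",
    extra_params: int = 0,
) -> PGLSFit:
    """GLS fit with a fixed covariance structure.

    ``b = (X' V^-1 X)^-1 X' V^-1 y`` via the Cholesky factor of ``V``;
    ``sigma2_ML = r' V^-1 r / n``; ``loglik = -(n log(2 pi sigma2) +
    log|V| + n) / 2``.  ``extra_params`` adds estimated structural
    parameters to the AIC count (used by the profiling wrapper).
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        raise ValidationError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    n, p = X.shape
    mat = _as_matrix(V)
    if mat.shape != (n, n):
        raise ValidationError(f"covariance is {mat.shape}, expected ({n}, {n})")
    try:
        L = cholesky(mat, lower=True)
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"covariance not positive-definite: {exc}") from exc
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    xtx = Xw.T @ Xw
    # rank check on the whitened design
    if np.linalg.matrix_rank(xtx, tol=1e-10 * max(1.0, np.abs(xtx).max())) < p:
        raise NumericError("design matrix is rank-deficient in X' V^-1 X")
    xtx_cf = cho_factor(xtx, lower=True)
    coef = cho_solve(xtx_cf, Xw.T @ yw)
    rw = yw - Xw @ coef
    rss = float(rw @ rw)
    sigma2 = rss / n
    logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
    # residuals at roundoff level relative to the response scale
    degenerate = sigma2 <= 1e-12 * max(1.0, float(yw @ yw) / n)
    if degenerate:
        loglik = math.inf
        se = np.zeros(p)
        tvals = np.full(p, np.inf)
        pvals = np.zeros(p)
    else:
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet_v + n)
        cov_b = cho_solve(xtx_cf, np.eye(p)) * sigma2 * n / (n - p)
        se = np.sqrt(np.diag(cov_b))
        with np.errstate(divide="ignore"):
            tvals = coef / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    k = p + 1 + extra_params  # coefficients + sigma2 + structural parameters
    aic = -2.0 * loglik + 2.0 * k
    fitted = X @ coef
    names = tuple(coef_names) if coef_names is not None else tuple(f"b{i}" for i in range(p))
    return PGLSFit(
        model=model,
        coef=coef,
        se=se,
        t=tvals,
        p=pvals,
        coef_names=names,
        sigma2_ml=sigma2,
        loglik=loglik,
        aic=aic,
        n=n,
        df_resid=n - p,
        degenerate=degenerate,
        fitted=fitted,
        residuals=y - fitted,
    )


def _profile(tree, y, X, model, tip_order, coef_names):
    """Maximize the profile log-likelihood over the structural parameter."""
    if model == "PL":
        def negll(lam):
            try:
                V = build_covariance(tree, "PL", lam, tip_order=tip_order)
                return -fit_gls(y, X, V).loglik
            except NumericError:
                return 1e12  # near-singular covariance: treat as very unlikely

        res = optimize.minimize_scalar(
            negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
        )
        param = float(res.x)
        boundary = param < 1e-6 or param > 1.0 - 1e-6
        # the bounded optimizer never evaluates the exact endpoints; check them
        for endpoint in (0.0, 1.0):
            if negll(endpoint) < res.fun - 1e-12:
                param, boundary = endpoint, True
        V = build_covariance(tree, "PL", param, tip_order=tip_order)
        name = "lambda"
    else:  # OU over log-alpha
        def negll_log(la):
            try:
                V = build_covariance(tree, "OU", math.exp(la), tip_order=tip_order)
                return -fit_gls(y, X, V).loglik
            except NumericError:
                return 1e12

        res = optimize.minimize_scalar(
            negll_log, bounds=(-10.0, 10.0), method="bounded", options={"xatol": 1e-8}
        )
        param = float(math.exp(res.x))
        boundary = res.x < -10 + 1e-5 or res.x > 10 - 1e-5
        V = build_covariance(tree, "OU", param, tip_order=tip_order)
        name = "alpha"
    fit = fit_gls(y, X, V, coef_names=coef_names, model=model, extra_params=1)
    fit.parameter = param
    fit.parameter_name = name
    fit.at_boundary = boundary
    return fit


def fit_pgls(
    y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree,
    model: str = "PL",
    *,
    tip_order=None,
    coef_names=None,
) -> PGLSFit:
    """PGLS with the structural parameter (if any) estimated by ML.

    ``model="BM"`` has no free structural parameter; ``"PL"`` profiles
    Pagel's lambda over [0, 1]; ``"OU"`` profiles log-alpha over [-10, 10].
    A boundary optimum is flagged on the returned fit, not raised.
    """
    if model not in MODELS:
        raise ValidationError(f"unknown evolutionary model {model!r}")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    order = tuple(tip_order) if tip_order is not None else tuple(tree.tip_labels)
    if len(order) != len(y):
        raise ValidationError("tip order length does not match data length")
    if model != "BM" and len(y) < 4:
        raise ValidationError("structural-parameter estimation needs >= 4 species")
    if model == "BM":
        V = build_covariance(tree, "BM", tip_order=order)
        return fit_gls(y, X, V, coef_names=coef_names, model="BM")
    return _profile(tree, y, X, model, order, coef_names)


def compare_evolutionary_models(
    y: np.ndarray,
    X: np.ndarray,
    tree: PhyloTree,
    models=MODELS,
    *,
    tip_order=None,
    coef_names=None,
) -> tuple[PGLSFit, pd.DataFrame]:
    """Fit each evolutionary model and return the minimum-AIC fit.

    Ties (delta AIC < 1e-6) are broken by simplicity, BM before PL before
    OU.  A model that fails to fit is marked failed in the comparison
    table; the comparison proceeds over the remainder.
    """
    models = tuple(models)
    if len(set(models)) != len(models):
        raise ValidationError(f"duplicate model in {models}")
    fits: dict[str, PGLSFit] = {}
    rows = []
    for m in models:
        try:
            fit = fit_pgls(y, X, tree, m, tip_order=tip_order, coef_names=coef_names)
            fits[m] = fit
            rows.append(
                {
                    "model": m,
                    "aic": fit.aic,
                    "loglik": fit.loglik,
                    "parameter": fit.parameter,
                    "failed": False,
                }
            )
        except (NumericError, ValidationError) as exc:
            rows.append(
                {"model": m, "aic": np.nan, "loglik": np.nan, "parameter": None,
                 "failed": True, "error": str(exc)}
            )
    if not fits:
        raise NumericError(f"all evolutionary models failed on this data: {rows}")
    order_rank = {m: i for i, m in enumerate(MODELS)}
    best_name = min(
        fits, key=lambda m: (round(fits[m].aic / 1e-6) * 1e-6, order_rank[m])
    )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - fits[best_name].aic
    table["selected"] = table["model"] == best_name
    return fits[best_name], table


def screen_predictors(
    species_table: pd.DataFrame,
    response: str,
    predictors,
    tree: PhyloTree,
    models=MODELS,
) -> pd.DataFrame:
    """Single-predictor screen of a response against each candidate.

    Each predictor is fitted alone (intercept + slope) against the
    response; the evolutionary models are compared by AIC and the selected
    model's slope, SE, t and p are reported.  A plain non-phylogenetic OLS
    (GLM) fit is reported alongside for every predictor.
    """
    order = tuple(species_table.index.astype(str))
    tree.check_species(order)
    y = species_table[response].to_numpy(float)
    rows = []
    for pred in predictors:
        x = species_table[pred].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        best, table = compare_evolutionary_models(
            y, X, tree, models, tip_order=order, coef_names=("intercept", pred)
        )
        ols = fit_gls(y, X, np.eye(len(y)), coef_names=("intercept", pred), model="GLM")
        row = {"response": response, "predictor": pred, **best.summary_row(),
               "selected": True, "lambda_or_alpha": best.parameter,
               "ols_b": float(ols.coef[-1]), "ols_t": float(ols.t[-1]),
               "ols_p": float(ols.p[-1])}
        rows.append(row)
    return pd.DataFrame(rows)
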