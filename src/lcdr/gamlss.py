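"""Weighted maximum-likelihood fitting of a single distributional
regression component.

A component models both distribution parameters of a two-parameter family
through additive predictors:

    g_mu(mu_i)       = eta_mu_i    = X_mu  beta_mu
    g_sigma(sigma_i) = eta_sigma_i = X_sigma beta_sigma

where each design matrix holds an intercept plus linear, categorical
indicator, or B-spline terms.  The fit maximizes the *weighted* log
likelihood sum_i w_i log f(y_i | mu_i, sigma_i), which is exactly the inner
objective required by the EM algorithm for mixtures of such components.

The optimizer is a quasi-Newton (L-BFGS-B) maximization over the stacked
coefficient vector with analytic gradients; the coefficient dimension in
typical reference-limit models is small (around 8 per component), so this
is both simpler and more transparent than backfitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import families as fam
from .families import Family
from .splines import BasisSpec, build_basis, evaluate_basis

__all__ = [
    "SchemaError",
    "DegenerateComponentError",
    "LinearTerm",
    "CategoricalTerm",
    "SplineTerm",
    "ModelSpec",
    "FittedComponent",
    "fit_weighted",
    "predict_params",
    "component_loglik",
]

log = logging.getLogger("lcdr")


class SchemaError(ValueError):
    """Data does not provide a column the model or schema references."""


class DegenerateComponentError(ValueError):
    """A component cannot be fit (e.g. all weights zero)."""


# ---------------------------------------------------------------------------
# Model terms and specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearTerm:
    """A raw linear covariate column."""

    var: str


@dataclass(frozen=True)
class CategoricalTerm:
    """A 0/1 indicator ``I(var == level)``."""

    var: str
    level: str


@dataclass(frozen=True)
class SplineTerm:
    """A cubic B-spline of ``var``; ``by=(col, level)`` multiplies the
    covariate by the indicator ``I(col == level)`` before the basis is
    built, giving group-specific smooth effects (the zeroed rows land on
    the left boundary where all non-intercept basis columns vanish)."""

    var: str
    df: int = 3
    degree: int = 3
    by: Optional[tuple[str, str]] = None
    basis: Optional[BasisSpec] = None  # finalized after fitting


Term = Union[LinearTerm, CategoricalTerm, SplineTerm]


@dataclass(frozen=True)
class ModelSpec:
    """Family plus one term list per distribution parameter.

    Both formulas implicitly include an intercept.
    """

    family: Family
    mu: tuple[Term, ...] = ()
    sigma: tuple[Term, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mu", tuple(self.mu))
        object.__setattr__(self, "sigma", tuple(self.sigma))


def _term_covariate(term: Term, data: pd.DataFrame) -> np.ndarray:
    for col in _term_columns(term):
        if col not in data.columns:
            raise SchemaError(f"model term references missing column {col!r}")
    if isinstance(term, LinearTerm):
        return data[term.var].to_numpy(dtype=float)
    if isinstance(term, CategoricalTerm):
        return (data[term.var].astype(str) == term.level).to_numpy(dtype=float)
    if isinstance(term, SplineTerm):
        x = data[term.var].to_numpy(dtype=float)
        if term.by is not None:
            col, level = term.by
            x = x * (data[col].astype(str) == level).to_numpy(dtype=float)
        return x
    raise TypeError(f"unknown term type {type(term).__name__}")


def _term_columns(term: Term) -> list[str]:
    cols = [term.var]
    if isinstance(term, SplineTerm) and term.by is not None:
        cols.append(term.by[0])
    return cols


def build_design(
    terms: Sequence[Term], data: pd.DataFrame, finalize: bool
) -> tuple[np.ndarray, tuple[Term, ...]]:
    """Assemble the design matrix (intercept first) for one parameter.

    With ``finalize=True`` spline knots are derived from the data and the
    returned terms carry frozen :class:`BasisSpec` objects; otherwise each
    spline term must already be finalized and is evaluated as-is.
    """
    n = len(data)
    cols = [np.ones(n)]
    out_terms: list[Term] = []
    for term in terms:
        x = _term_covariate(term, data)
        if isinstance(term, SplineTerm):
            if finalize:
                spec = term.basis or BasisSpec(var=term.var, df=term.df, degree=term.degree)
                mat, final_spec = build_basis(x, spec)
                term = replace(term, basis=final_spec)
            else:
                if term.basis is None or not term.basis.finalized:
                    raise RuntimeError(
                        f"spline term {term.var!r} has no finalized basis; fit the model first"
                    )
                mat = evaluate_basis(term.basis, x)
            cols.append(mat)
        else:
            cols.append(x[:, None])
        out_terms.append(term)
    return np.column_stack(cols), tuple(out_terms)


# ---------------------------------------------------------------------------
# Fitted component
# ---------------------------------------------------------------------------


@dataclass
class FittedComponent:
    spec: ModelSpec  # with finalized spline bases
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    sigma_floor: float
    converged: bool
    n_iter: int
    loglik: float
    response: str = "y"
    diagnostics: dict = field(default_factory=dict)


def _default_start(family: Family, y: np.ndarray, w: np.ndarray, p_mu: int, p_sigma: int) -> np.ndarray:
    sw = w.sum()
    m = float(np.sum(w * y) / sw)
    s = float(np.sqrt(np.sum(w * (y - m) ** 2) / sw))
    beta = np.zeros(p_mu + p_sigma)
    if family.name == "gamma":
        # sigma is a coefficient of variation in the GA parameterization
        s = max(s / max(m, 1e-12), 1e-6)
        m = max(m, 1e-12)
    beta[0] = family.link("mu", m)
    beta[p_mu] = family.link("sigma", max(s, 1e-12))
    return beta


def fit_weighted(
    spec: ModelSpec,
    data: pd.DataFrame,
    weights=None,
    response: str = "y",
    sigma_floor: Optional[float] = None,
    start: Optional[np.ndarray] = None,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> FittedComponent:
    """Fit one component by weighted maximum likelihood.

    ``weights`` are per-observation non-negative reals (default: all one).
    The fit is deterministic given data, weights, spec and starting values
    (defaults: mu-intercept at the link of the weighted mean, sigma-intercept
    at the link of the weighted spread, remaining coefficients zero).

    Non-convergence is *flagged* on the result, not raised; genuinely
    degenerate inputs (all-zero weights, domain violations) raise.
    """
    if response not in data.columns:
        raise SchemaError(f"response column {response!r} missing from data")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights must be one non-negative real per row")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise DegenerateComponentError("all observation weights are zero")
    family = spec.family
    if family.name == "gamma" and np.any(y[w > 0] <= 0):
        raise ValueError("gamma: response must be > 0 on rows with positive weight")

    X_mu, mu_terms = build_design(spec.mu, data, finalize=True)
    X_sigma, sigma_terms = build_design(spec.sigma, data, finalize=True)
    final_spec = ModelSpec(family=family, mu=mu_terms, sigma=sigma_terms)
    p_mu, p_sigma = X_mu.shape[1], X_sigma.shape[1]

    if sigma_floor is None:
        sw = w.sum()
        m0 = np.sum(w * y) / sw
        sd = float(np.sqrt(np.sum(w * (y - m0) ** 2) / sw))
        sigma_floor = max(1e-4 * sd, 1e-10)

    active = w > 0
    yw, ww = y[active], w[active]
    Xm, Xs = X_mu[active], X_sigma[active]
    if active.sum() < max(p_mu, p_sigma):
        raise DegenerateComponentError(
            f"only {int(active.sum())} rows with positive weight for "
            f"{max(p_mu, p_sigma)} coefficients"
        )

    if np.allclose(yw, yw[0]):
        log.warning("weighted response is constant; sigma pinned at the floor")

    def objective(beta):
        eta_mu = Xm @ beta[:p_mu]
        eta_sigma = Xs @ beta[p_mu:]
        mu = family.inverse_link("mu", eta_mu)
        sigma_raw = family.inverse_link("sigma", eta_sigma)
        clamped = sigma_raw < sigma_floor
        sigma = np.where(clamped, sigma_floor, sigma_raw)
        if family.name == "gamma":
            mu = np.maximum(mu, 1e-300)
        with np.errstate(over="ignore", invalid="ignore"):
            ll = fam.logpdf(family, yw, mu, sigma)
        if not np.all(np.isfinite(ll)):
            return np.inf, np.zeros_like(beta)
        d_mu, d_sigma = fam.score_eta(family, yw, mu, sigma)
        d_sigma = np.where(clamped, 0.0, d_sigma)  # floor-projected rows carry no score
        grad = -np.concatenate([Xm.T @ (ww * d_mu), Xs.T @ (ww * d_sigma)])
        return -float(np.sum(ww * ll)), grad

    beta0 = start if start is not None else _default_start(family, yw, ww, p_mu, p_sigma)
    res = minimize(
        objective,
        np.asarray(beta0, dtype=float),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    beta = res.x
    return FittedComponent(
        spec=final_spec,
        beta_mu=beta[:p_mu],
        beta_sigma=beta[p_mu:],
        sigma_floor=float(sigma_floor),
        converged=bool(res.success),
        n_iter=int(res.nit),
        loglik=-float(res.fun),
        response=response,
        diagnostics={"grad_norm": float(np.max(np.abs(res.jac))), "message": str(res.message)},
    )


def predict_params(fit: FittedComponent, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (mu, sigma) at new covariates; sigma is floored."""
    family = fit.spec.family
    X_mu, _ = build_design(fit.spec.mu, data, finalize=False)
    X_sigma, _ = build_design(fit.spec.sigma, data, finalize=False)
    mu = family.inverse_link("mu", X_mu @ fit.beta_mu)
    sigma = np.maximum(family.inverse_link("sigma", X_sigma @ fit.beta_sigma), fit.sigma_floor)
    return mu, sigma


def component_loglik(fit: FittedComponent, data: pd.DataFrame, weights=None) -> float:
    """Weighted log likelihood of ``data`` under a fitted component."""
    y = data[fit.response].to_numpy(dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if not np.any(w != 0):
        return 0.0
    mu, sigma = predict_params(fit, data)
    return float(np.sum(w * fam.logpdf(fit.spec.family, y, mu, sigma)))
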