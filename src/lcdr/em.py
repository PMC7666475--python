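"""EM estimation of mixtures of distributional regression components
(latent class distributional regression).

The model is a finite mixture whose M components are each a two-parameter
distributional regression (see :mod:`lcdr.gamlss`):

    f(y_i | x_i) = sum_m alpha_m f_m(y_i | mu_m(x_i), sigma_m(x_i))

with alpha_m > 0, sum alpha_m = 1.  Estimation alternates

* E-step: membership weights w_im proportional to alpha_m f_m(y_i),
* M-step: each component refit by weighted maximum likelihood with its
  weight column, and alpha_m updated to the mean membership weight,

which monotonically increases the mixture log likelihood.  Convergence is
declared when the absolute change in total log likelihood drops below a
threshold epsilon (default 0.001).

Initialization matters: random one-hot memberships often land the highly
flexible components in poor local maxima, so the recommended strategy
derives initial weights from the CDF of a "naive" single-component fit to
all the data — observations in the naive fit's upper tail are handed to
the contaminating component (or the lower tail / both tails, depending on
where the pathological values are expected to sit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import families as fam
from .gamlss import (
    DegenerateComponentError,
    FittedComponent,
    ModelSpec,
    fit_weighted,
    predict_params,
)

__all__ = [
    "MixtureSpec",
    "MixtureFit",
    "mixture_logpdf",
    "e_step",
    "m_step",
    "init_weights_naive_cdf",
    "init_weights_random",
    "fit_lcdr",
]

log = logging.getLogger("lcdr")

WEIGHT_FLOOR = 1e-12  # membership weights are floored so no row is dropped


@dataclass
class MixtureSpec:
    """Configuration of a mixture fit.

    ``components`` is one :class:`ModelSpec` per mixture component (M >= 2).
    ``init`` is one of ``"naive-cdf"`` (recommended, M=2 only), ``"random"``
    or ``"user"`` (pass explicit ``init_weights`` to :func:`fit_lcdr`).
    ``init_mode`` directs the naive-CDF weights at contamination sitting
    above ("upper"), below ("lower") or on both sides ("two-sided") of the
    main component.
    """

    components: tuple[ModelSpec, ...]
    epsilon: float = 1e-3
    max_iter: int = 500
    init: str = "naive-cdf"
    init_mode: str = "upper"
    seed: Optional[int] = None
    sigma_floor: Optional[float] = None
    response: str = "y"
    random_fallback: bool = False
    alpha_floor_scale: float = 1e-3  # fail if alpha_m < M * scale / n

    def __post_init__(self):
        self.components = tuple(self.components)
        if self.M < 2:
            raise ValueError("a mixture needs at least M=2 components")
        if self.epsilon <= 0:
            raise ValueError("convergence threshold epsilon must be > 0")

    @property
    def M(self) -> int:
        return len(self.components)


@dataclass
class MixtureFit:
    alpha: np.ndarray
    components: list[FittedComponent]
    weights: np.ndarray  # n x M membership weights
    loglik_trace: list[float]
    status: str  # "converged" | "max-iter" | "failed"
    n_iter: int
    init_record: dict
    naive_fit: Optional[FittedComponent] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def mixture_logpdf(alpha, log_dens: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-row log mixture density and its total.

    ``log_dens`` is an ``n x M`` matrix of per-component log densities
    evaluated at each observation's own covariates.  Computed with
    log-sum-exp so extreme rows do not underflow.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.shape[0] != log_dens.shape[1]:
        raise ValueError("alpha length must match the number of components")
    if np.any(alpha <= 0) or abs(alpha.sum() - 1.0) > 1e-8:
        raise ValueError("alpha must be a strictly positive simplex vector")
    rows = logsumexp(np.log(alpha)[None, :] + log_dens, axis=1)
    return rows, float(rows.sum())


def e_step(alpha, log_dens: np.ndarray) -> np.ndarray:
    """Membership weights w_im = alpha_m f_m(y_i) / sum_l alpha_l f_l(y_i)."""
    alpha = np.asarray(alpha, dtype=float)
    a = np.log(alpha)[None, :] + log_dens
    norm = logsumexp(a, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    if np.any(bad):
        log.warning("e_step: %d rows with vanishing density in every component; "
                    "assigned uniform memberships", int(bad.sum()))
        a[bad] = 0.0
        norm[bad] = np.log(log_dens.shape[1])
    return np.exp(a - norm)


def _component_logdens(fits: Sequence[FittedComponent], data: pd.DataFrame, response: str) -> np.ndarray:
    y = data[response].to_numpy(dtype=float)
    cols = []
    for f in fits:
        mu, sigma = predict_params(f, data)
        cols.append(fam.logpdf(f.spec.family, y, mu, sigma))
    return np.column_stack(cols)


def m_step(
    data: pd.DataFrame,
    w: np.ndarray,
    spec: MixtureSpec,
    warm_starts: Optional[Sequence[FittedComponent]] = None,
) -> tuple[list[FittedComponent], np.ndarray]:
    """Refit every component on its weight column; update mixture weights.

    ``alpha_m`` becomes the mean membership weight of component m.  Raises
    :class:`DegenerateComponentError` on component collapse (vanishing
    alpha or too small an effective sample for the coefficient count).
    """
    n, M = w.shape
    if M != spec.M:
        raise ValueError("weight matrix width must equal the number of components")
    if np.any(w < 0) or not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("membership weight rows must be non-negative and sum to 1")
    alpha = w.mean(axis=0)
    alpha_floor = spec.M * spec.alpha_floor_scale / n
    if np.any(alpha < alpha_floor):
        m_bad = int(np.argmin(alpha))
        raise DegenerateComponentError(
            f"component {m_bad} collapsed: alpha={alpha[m_bad]:.3e} < floor {alpha_floor:.3e}"
        )
    fits = []
    for m, comp_spec in enumerate(spec.components):
        start = None
        if warm_starts is not None:
            prev = warm_starts[m]
            start = np.concatenate([prev.beta_mu, prev.beta_sigma])
        fit = fit_weighted(
            comp_spec,
            data,
            weights=w[:, m],
            response=spec.response,
            sigma_floor=spec.sigma_floor,
            start=start,
        )
        n_coef = len(fit.beta_mu) + len(fit.beta_sigma)
        ess = float(w[:, m].sum())
        if ess < n_coef + 1:
            raise DegenerateComponentError(
                f"component {m}: effective sample size {ess:.2f} below {n_coef + 1}"
            )
        fits.append(fit)
    return fits, alpha


# ---------------------------------------------------------------------------
# Initialization strategies
# ---------------------------------------------------------------------------


def init_weights_naive_cdf(
    data: pd.DataFrame, spec: MixtureSpec, mode: Optional[str] = None
) -> tuple[np.ndarray, FittedComponent]:
    """Initial memberships from the CDF of a naive single-component fit.

    The first component's model is fit to *all* rows with unit weights,
    ignoring the mixture structure; with u_i the naive CDF value of y_i,
    the initial weight of the main (first) component is ``1 - u_i`` in
    "upper" mode, ``u_i`` in "lower" mode, and ``1 - |2u_i - 1|`` in
    "two-sided" mode, the remainder going to the second component.

    Only defined for M = 2.  Also returns the naive fit itself, which is
    both a useful baseline and the "NAIVE" comparator in simulations.
    """
    if spec.M != 2:
        raise ValueError("naive-cdf initialization supports exactly M=2 components")
    mode = mode or spec.init_mode
    naive = fit_weighted(
        spec.components[0],
        data,
        weights=None,
        response=spec.response,
        sigma_floor=spec.sigma_floor,
    )
    y = data[spec.response].to_numpy(dtype=float)
    mu, sigma = predict_params(naive, data)
    u = fam.cdf(naive.spec.family, y, mu, sigma)
    if mode == "upper":
        w1 = 1.0 - u
    elif mode == "lower":
        w1 = u
    elif mode == "two-sided":
        w1 = 1.0 - np.abs(2.0 * u - 1.0)
    else:
        raise ValueError(f"unknown init mode {mode!r}; expected upper|lower|two-sided")
    w = np.column_stack([w1, 1.0 - w1])
    w = np.clip(w, WEIGHT_FLOOR, None)
    w /= w.sum(axis=1, keepdims=True)
    return w, naive


def init_weights_random(n: int, M: int, seed) -> np.ndarray:
    """One-hot membership rows for uniformly random components."""
    if n < M:
        raise ValueError("need at least as many rows as components")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, M, size=n)
    w = np.zeros((n, M))
    w[np.arange(n), labels] = 1.0
    return w


# ---------------------------------------------------------------------------
# The EM driver
# ---------------------------------------------------------------------------


def fit_lcdr(
    data: pd.DataFrame,
    spec: MixtureSpec,
    init_weights: Optional[np.ndarray] = None,
) -> MixtureFit:
    """Fit the latent class distributional regression model by EM.

    Statistical failure (component collapse, inner non-convergence cascade)
    is reported through ``status="failed"`` with diagnostics, never raised;
    exceptions indicate malformed input.  When ``spec.random_fallback`` is
    true a failed non-random initialization is retried once with random
    one-hot memberships.
    """
    fit = _run_em(data, spec, init_weights)
    if fit.status == "failed" and spec.random_fallback and spec.init != "random":
        log.info("EM failed under %s initialization; retrying with random memberships", spec.init)
        retry_spec = MixtureSpec(**{**spec.__dict__, "init": "random"})
        retry = _run_em(data, retry_spec, None)
        retry.diagnostics["fallback_from"] = fit.diagnostics.get("failure", spec.init)
        return retry
    return fit


def _initialize(data, spec, init_weights):
    n = len(data)
    naive = None
    if init_weights is not None or spec.init == "user":
        if init_weights is None:
            raise ValueError("init='user' requires an explicit init_weights matrix")
        w0 = np.asarray(init_weights, dtype=float)
        if w0.shape != (n, spec.M):
            raise ValueError("init_weights must be n x M")
        record = {"strategy": "user", "seed": spec.seed}
    elif spec.init == "naive-cdf":
        w0, naive = init_weights_naive_cdf(data, spec)
        record = {"strategy": "naive-cdf", "mode": spec.init_mode, "seed": spec.seed}
    elif spec.init == "random":
        w0 = init_weights_random(n, spec.M, spec.seed)
        record = {"strategy": "random", "seed": spec.seed}
    else:
        raise ValueError(f"unknown initialization strategy {spec.init!r}")
    w0 = np.clip(w0, WEIGHT_FLOOR, None)
    w0 /= w0.sum(axis=1, keepdims=True)
    return w0, record, naive


def _run_em(data, spec, init_weights):
    w, record, naive = _initialize(data, spec, init_weights)
    trace: list[float] = []
    fits: list[FittedComponent] = []
    alpha = np.full(spec.M, 1.0 / spec.M)
    status = "max-iter"
    failure = None
    n_iter = 0
    warm = None
    for it in range(spec.max_iter + 1):
        try:
            fits, alpha = m_step(data, w, spec, warm_starts=warm)
        except DegenerateComponentError as err:
            status, failure = "failed", str(err)
            break
        log_dens = _component_logdens(fits, data, spec.response)
        _, total = mixture_logpdf(alpha, log_dens)
        trace.append(total)
        n_iter = it
        if it > 0 and abs(trace[-1] - trace[-2]) < spec.epsilon:
            status = "converged"
            break
        w = e_step(alpha, log_dens)
        w = np.clip(w, WEIGHT_FLOOR, None)
        w /= w.sum(axis=1, keepdims=True)
        warm = fits
    if status == "failed":
        log.warning("EM failed: %s", failure)
    else:
        log.info(
            "EM %s after %d iterations: loglik=%.4f alpha=%s epsilon=%g",
            status, n_iter, trace[-1], np.round(alpha, 4), spec.epsilon,
        )
    diag = {"failure": failure} if failure else {}
    return MixtureFit(
        alpha=np.asarray(alpha, dtype=float),
        components=fits,
        weights=w,
        loglik_trace=trace,
        status=status,
        n_iter=n_iter,
        init_record=record,
        naive_fit=naive,
        diagnostics=diag,
    )
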