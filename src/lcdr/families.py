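"""Two-parameter response distributions for distributional regression.

Each family describes a response distribution through a location-type
parameter ``mu`` and a scale/dispersion-type parameter ``sigma``, together
with a monotone link function per parameter.  Only two-parameter families
are supported; skewness/kurtosis parameters of the wider GAMLSS family zoo
are deliberately out of scope.

Parameterizations
-----------------
gaussian
    ``y ~ N(mu, sigma^2)``; identity link for mu, log link for sigma.
gamma
    The mean/dispersion ("GA") parameterization common in distributional
    regression software: ``E[y] = mu``, ``Var[y] = sigma^2 mu^2`` (sigma is
    the coefficient of variation).  In shape/scale terms this is
    ``Gamma(shape=1/sigma^2, scale=sigma^2 mu)``.  Log link for both
    parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special, stats

__all__ = [
    "Family",
    "GAUSSIAN",
    "GAMMA",
    "get_family",
    "logpdf",
    "cdf",
    "quantile",
    "rvs",
    "score_eta",
]


# ---------------------------------------------------------------------------
# Link functions
# ---------------------------------------------------------------------------

_LINKS: dict[str, tuple[Callable, Callable]] = {
    # name -> (link g, inverse link g^-1)
    "identity": (lambda t: np.asarray(t, dtype=float), lambda e: np.asarray(e, dtype=float)),
    "log": (np.log, np.exp),
}


@dataclass(frozen=True)
class Family:
    """A two-parameter response distribution with per-parameter links."""

    name: str
    mu_link: str
    sigma_link: str

    def link(self, param: str, value):
        """Apply the link function g for ``param`` ('mu' or 'sigma')."""
        return _LINKS[self._link_name(param)][0](value)

    def inverse_link(self, param: str, eta):
        """Apply the inverse link g^-1 for ``param``."""
        return _LINKS[self._link_name(param)][1](eta)

    def _link_name(self, param: str) -> str:
        if param == "mu":
            return self.mu_link
        if param == "sigma":
            return self.sigma_link
        raise ValueError(f"unknown parameter {param!r}; expected 'mu' or 'sigma'")


GAUSSIAN = Family("gaussian", mu_link="identity", sigma_link="log")
GAMMA = Family("gamma", mu_link="log", sigma_link="log")

_REGISTRY = {"gaussian": GAUSSIAN, "gamma": GAMMA}


def get_family(name: str) -> Family:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Density, CDF, quantile, sampling
# ---------------------------------------------------------------------------


def _check_domain(family: Family, y, mu, sigma, check_y: bool = True) -> None:
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError(f"{family.name}: sigma must be > 0")
    if family.name == "gamma":
        if np.any(np.asarray(mu) <= 0):
            raise ValueError("gamma: mu must be > 0")
        if check_y and y is not None and np.any(np.asarray(y) <= 0):
            raise ValueError("gamma: y must be > 0")


def _frozen(family: Family, mu, sigma):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if family.name == "gaussian":
        return stats.norm(loc=mu, scale=sigma)
    if family.name == "gamma":
        shape = 1.0 / sigma**2
        return stats.gamma(shape, scale=sigma**2 * mu)
    raise ValueError(f"unknown family {family.name!r}")


_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def logpdf(family: Family, y, mu, sigma):
    """Log density of ``y`` under the family at parameters (mu, sigma).

    Evaluated in closed form (this sits inside optimizer and EM inner
    loops, where generic distribution dispatch is the dominant cost).
    """
    _check_domain(family, y, mu, sigma)
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if family.name == "gaussian":
        r = (y - mu) / sigma
        return -_HALF_LOG_2PI - np.log(sigma) - 0.5 * r * r
    if family.name == "gamma":
        shape = 1.0 / sigma**2
        scale = sigma**2 * mu
        return (
            (shape - 1.0) * np.log(y)
            - y / scale
            - shape * np.log(scale)
            - special.gammaln(shape)
        )
    raise ValueError(f"unknown family {family.name!r}")


def cdf(family: Family, y, mu, sigma):
    """Cumulative distribution function at ``y``."""
    _check_domain(family, y, mu, sigma)
    return _frozen(family, mu, sigma).cdf(np.asarray(y, dtype=float))


def quantile(family: Family, q, mu, sigma):
    """Quantile function (inverse CDF) at probability ``q`` in (0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantile level q must lie strictly in (0, 1)")
    _check_domain(family, None, mu, sigma, check_y=False)
    return _frozen(family, mu, sigma).ppf(q)


def rvs(family: Family, mu, sigma, rng: np.random.Generator, size=None):
    """Draw random variates; ``rng`` is an explicit numpy Generator."""
    _check_domain(family, None, mu, sigma, check_y=False)
    return _frozen(family, mu, sigma).rvs(size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Scores on the predictor scale (used by the weighted fitter)
# ---------------------------------------------------------------------------


def score_eta(family: Family, y, mu, sigma):
    """Per-observation derivatives of the log density w.r.t. the linear
    predictors eta_mu and eta_sigma (i.e. after the chain rule through the
    inverse links).

    Returns ``(d_eta_mu, d_eta_sigma)`` as arrays shaped like ``y``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if family.name == "gaussian":
        r = (y - mu) / sigma
        d_mu = r / sigma  # identity link
        d_sigma = r * r - 1.0  # log link: dl/dsigma * sigma
        return d_mu, d_sigma
    if family.name == "gamma":
        shape = 1.0 / sigma**2
        scale = sigma**2 * mu
        # dl/dmu = (y - mu) / (sigma^2 mu^2); log link multiplies by mu
        d_mu = (y - mu) / (sigma**2 * mu)
        # dl/dsigma via shape and scale derivatives; log link multiplies by sigma
        dl_dshape = np.log(y) - np.log(scale) - special.digamma(shape)
        dl_dscale = y / scale**2 - shape / scale
        d_sigma = sigma * (dl_dshape * (-2.0 / sigma**3) + dl_dscale * (2.0 * sigma * mu))
        return d_mu, d_sigma
    raise ValueError(f"unknown family {family.name!r}")
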