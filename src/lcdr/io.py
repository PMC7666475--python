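"""CSV/JSON input-output, model-spec (de)serialization, and a synthetic
hemoglobin-like fixture generator.

Model formulas are declared in JSON rather than a formula mini-language:

    {
      "family": "gaussian",
      "mu":    [{"type": "spline", "var": "age", "df": 3,
                 "by": ["sex", "f"]},
                {"type": "categorical", "var": "sex", "level": "f"}],
      "sigma": [...]
    }

Fitted mixtures round-trip through JSON with their frozen spline knots and
coefficients, so quantile curves recomputed from a saved fit are bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .em import MixtureFit, MixtureSpec
from .families import get_family
from .gamlss import (
    CategoricalTerm,
    FittedComponent,
    LinearTerm,
    ModelSpec,
    SchemaError,
    SplineTerm,
)
from .splines import BasisSpec

__all__ = [
    "DataSchema",
    "read_dataset",
    "model_spec_from_dict",
    "model_spec_to_dict",
    "mixture_spec_from_json",
    "fit_to_json",
    "fit_from_json",
    "make_hemoglobin_fixture",
]

log = logging.getLogger("lcdr")


@dataclass(frozen=True)
class DataSchema:
    response: str
    covariates: tuple[str, ...]
    group: Optional[str] = None


def read_dataset(path, schema: DataSchema) -> pd.DataFrame:
    """Read a CSV with a header row and validate it against a schema.

    Rows with missing response or covariate values are dropped (the count
    is logged); a missing *column* is an error naming that column.
    """
    data = pd.read_csv(path)
    required = [schema.response, *schema.covariates]
    if schema.group:
        required.append(schema.group)
    for col in required:
        if col not in data.columns:
            raise SchemaError(f"dataset {path} is missing required column {col!r}")
    numeric = [schema.response, *schema.covariates]
    for col in numeric:
        data[col] = pd.to_numeric(data[col], errors="coerce")
    keep = data[numeric].notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("read_dataset: dropped %d rows with missing values", dropped)
    return data.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model spec JSON schema
# ---------------------------------------------------------------------------


def _term_to_dict(term) -> dict:
    if isinstance(term, LinearTerm):
        return {"type": "linear", "var": term.var}
    if isinstance(term, CategoricalTerm):
        return {"type": "categorical", "var": term.var, "level": term.level}
    if isinstance(term, SplineTerm):
        d = {"type": "spline", "var": term.var, "df": term.df, "degree": term.degree}
        if term.by is not None:
            d["by"] = list(term.by)
        if term.basis is not None and term.basis.finalized:
            d["basis"] = {
                "boundary": list(term.basis.boundary),
                "interior_knots": list(term.basis.interior_knots),
            }
        return d
    raise TypeError(f"unknown term type {type(term).__name__}")


def _term_from_dict(d: dict):
    kind = d.get("type")
    if kind == "linear":
        return LinearTerm(d["var"])
    if kind == "categorical":
        return CategoricalTerm(d["var"], str(d["level"]))
    if kind == "spline":
        basis = None
        if "basis" in d:
            basis = BasisSpec(
                var=d["var"],
                df=int(d.get("df", 3)),
                degree=int(d.get("degree", 3)),
                boundary=tuple(d["basis"]["boundary"]),
                interior_knots=tuple(d["basis"]["interior_knots"]),
            )
        return SplineTerm(
            var=d["var"],
            df=int(d.get("df", 3)),
            degree=int(d.get("degree", 3)),
            by=tuple(d["by"]) if "by" in d and d["by"] else None,
            basis=basis,
        )
    raise SchemaError(f"unknown model term type {kind!r}")


def model_spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "family": spec.family.name,
        "mu": [_term_to_dict(t) for t in spec.mu],
        "sigma": [_term_to_dict(t) for t in spec.sigma],
    }


def model_spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        family=get_family(d["family"]),
        mu=tuple(_term_from_dict(t) for t in d.get("mu", [])),
        sigma=tuple(_term_from_dict(t) for t in d.get("sigma", [])),
    )


def mixture_spec_from_json(path, seed: Optional[int] = None) -> MixtureSpec:
    """Load a mixture configuration: component model specs plus EM settings."""
    with open(path) as fh:
        cfg = json.load(fh)
    comps = cfg.get("components")
    if not comps:
        raise SchemaError("mixture config must list at least two 'components'")
    return MixtureSpec(
        components=tuple(model_spec_from_dict(c) for c in comps),
        epsilon=float(cfg.get("epsilon", 1e-3)),
        max_iter=int(cfg.get("max_iter", 500)),
        init=cfg.get("init", "naive-cdf"),
        init_mode=cfg.get("init_mode", "upper"),
        seed=seed if seed is not None else cfg.get("seed"),
        sigma_floor=cfg.get("sigma_floor"),
        response=cfg.get("response", "y"),
        random_fallback=bool(cfg.get("random_fallback", False)),
    )


# ---------------------------------------------------------------------------
# Fitted model JSON
# ---------------------------------------------------------------------------


def _component_to_dict(fit: FittedComponent) -> dict:
    return {
        "spec": model_spec_to_dict(fit.spec),
        "beta_mu": fit.beta_mu.tolist(),
        "beta_sigma": fit.beta_sigma.tolist(),
        "sigma_floor": fit.sigma_floor,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "loglik": fit.loglik,
        "response": fit.response,
    }


def _component_from_dict(d: dict) -> FittedComponent:
    return FittedComponent(
        spec=model_spec_from_dict(d["spec"]),
        beta_mu=np.asarray(d["beta_mu"], dtype=float),
        beta_sigma=np.asarray(d["beta_sigma"], dtype=float),
        sigma_floor=float(d["sigma_floor"]),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        loglik=float(d["loglik"]),
        response=d.get("response", "y"),
    )


def fit_to_json(fit: MixtureFit, path) -> None:
    payload = {
        "alpha": fit.alpha.tolist(),
        "components": [_component_to_dict(c) for c in fit.components],
        "loglik_trace": list(map(float, fit.loglik_trace)),
        "status": fit.status,
        "n_iter": fit.n_iter,
        "init": fit.init_record,
        "naive_fit": _component_to_dict(fit.naive_fit) if fit.naive_fit is not None else None,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def fit_from_json(path) -> MixtureFit:
    with open(path) as fh:
        d = json.load(fh)
    return MixtureFit(
        alpha=np.asarray(d["alpha"], dtype=float),
        components=[_component_from_dict(c) for c in d["components"]],
        weights=np.zeros((0, max(len(d["components"]), 1))),  # not persisted
        loglik_trace=d["loglik_trace"],
        status=d["status"],
        n_iter=int(d["n_iter"]),
        init_record=d.get("init", {}),
        naive_fit=_component_from_dict(d["naive_fit"]) if d.get("naive_fit") else None,
    )


# ---------------------------------------------------------------------------
# Synthetic hemoglobin-like fixture
# ---------------------------------------------------------------------------

# Synthetic pediatric hemoglobin-like parameters (g/dL), chosen to mimic the
# qualitative shape of real data: healthy concentration rises with age,
# faster and further for boys in adolescence, and a minority pathologic
# (anemic) component sits a few g/dL below the healthy one.
_HB = {
    "f": {"base": 12.0, "gain": 1.3, "power": 0.7},
    "m": {"base": 12.0, "gain": 2.8, "power": 1.6},
}
_HB_SIGMA = (0.75, 0.02)  # healthy sd = 0.75 + 0.02 * age
_HB_PATH_SHIFT = 2.8  # pathologic mean sits this far below healthy
_HB_PATH_SIGMA = 1.5
_HB_ALPHA_HEALTHY = 0.8


def healthy_hemoglobin_mean(age, sex: str):
    p = _HB[sex]
    return p["base"] + p["gain"] * (np.asarray(age, dtype=float) / 18.0) ** p["power"]


def make_hemoglobin_fixture(
    n_per_sex: int = 2000, seed: int = 0, path=None
) -> pd.DataFrame:
    """Generate a synthetic hemoglobin-like dataset (age, sex, value, label).

    This is *synthetic* data emulating the structure of routine pediatric
    laboratory records: ages uniform on (1, 18), a dominant healthy
    component with a smooth age/sex-dependent mean and mildly growing
    spread, and a 20% pathologic component centered a few g/dL lower —
    i.e. contamination sits *below* the healthy component.  ``label`` 1
    marks healthy rows and is retained for benchmarking only.
    """
    if n_per_sex < 200:
        raise ValueError("need at least 200 observations per sex")
    rng = np.random.default_rng(seed)
    frames = []
    for sex in ("f", "m"):
        age = rng.uniform(1.0, 18.0, size=n_per_sex)
        healthy = rng.uniform(size=n_per_sex) < _HB_ALPHA_HEALTHY
        mu_h = healthy_hemoglobin_mean(age, sex)
        sd_h = _HB_SIGMA[0] + _HB_SIGMA[1] * age
        mu = np.where(healthy, mu_h, mu_h - _HB_PATH_SHIFT)
        sd = np.where(healthy, sd_h, _HB_PATH_SIGMA)
        value = rng.normal(mu, sd)
        frames.append(pd.DataFrame({
            "age": age,
            "sex": sex,
            "value": value,
            "label": np.where(healthy, 1, 2),
        }))
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def hemoglobin_model_spec() -> ModelSpec:
    """The sex-stratified component model: a sex indicator plus separate
    age splines for girls and boys, for both mu and log sigma."""
    terms = (
        CategoricalTerm("sex", "f"),
        SplineTerm("age", df=3, by=("sex", "f")),
        SplineTerm("age", df=3, by=("sex", "m")),
    )
    return ModelSpec(family=get_family("gaussian"), mu=terms, sigma=terms)
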