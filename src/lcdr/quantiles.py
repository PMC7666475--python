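"""Component-specific conditional quantile curves (reference limits).

Quantiles are always those of one *extracted component* of the mixture,
never of the mixture itself — the mixture quantile is what a naive fit to
contaminated data effectively reports.  Curves are evaluated pointwise on
a covariate grid, so they inherit the continuity of the fitted predictors;
outside the training covariate range the underlying spline bases clamp to
the boundary, keeping the limits flat rather than extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import families as fam
from .em import MixtureFit
from .gamlss import FittedComponent, predict_params

__all__ = ["QuantileCurve", "component_quantile_curve", "fit_quantile_curve", "reference_interval"]


@dataclass
class QuantileCurve:
    component: int
    level: float
    grid: np.ndarray
    values: np.ndarray
    var: str
    group: Optional[dict] = None


def _grid_frame(var: str, grid: np.ndarray, fixed: Optional[dict]) -> pd.DataFrame:
    frame = pd.DataFrame({var: np.asarray(grid, dtype=float)})
    for col, val in (fixed or {}).items():
        frame[col] = val
    return frame


def fit_quantile_curve(
    fit: FittedComponent,
    q: float,
    var: str,
    grid,
    fixed: Optional[dict] = None,
    component: int = 0,
) -> QuantileCurve:
    """Quantile curve of a single fitted component on a covariate grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be one-dimensional and strictly increasing")
    if not 0 < q < 1:
        raise ValueError("quantile level q must lie strictly in (0, 1)")
    frame = _grid_frame(var, grid, fixed)
    mu, sigma = predict_params(fit, frame)
    values = fam.quantile(fit.spec.family, q, mu, sigma)
    return QuantileCurve(component=component, level=q, grid=grid, values=values,
                         var=var, group=dict(fixed) if fixed else None)


def component_quantile_curve(
    fit: MixtureFit,
    m: int,
    q: float,
    var: str,
    grid,
    fixed: Optional[dict] = None,
) -> QuantileCurve:
    """Quantile curve Q_{m,q}(x) of component ``m`` of a mixture fit.

    Refuses fits with ``status="failed"``; a max-iteration fit is accepted
    (with whatever accuracy it reached), matching how non-converged runs
    are treated as data rather than errors.
    """
    if fit.status == "failed":
        raise RuntimeError(
            f"cannot extract quantiles from a failed mixture fit: "
            f"{fit.diagnostics.get('failure', 'unknown failure')}"
        )
    if not 0 <= m < len(fit.components):
        raise ValueError(f"component index {m} out of range for M={len(fit.components)}")
    return fit_quantile_curve(fit.components[m], q, var, grid, fixed, component=m)


def reference_interval(
    fit: MixtureFit,
    m: int,
    var: str,
    grid,
    levels: tuple[float, float] = (0.025, 0.975),
    group_var: Optional[str] = None,
    group_values: Optional[Sequence] = None,
    fixed: Optional[dict] = None,
) -> pd.DataFrame:
    """Lower/upper reference limit curves, optionally per group level.

    Returns a tidy frame with columns ``group`` (empty string when no group
    factor is given), ``x``, ``level`` and ``value``.
    """
    lo, hi = sorted(levels)
    groups = [None] if group_var is None else list(group_values or [])
    if group_var is not None and not groups:
        raise ValueError("group_values must be provided along with group_var")
    rows = []
    for g in groups:
        fx = dict(fixed or {})
        if group_var is not None:
            fx[group_var] = g
        for level in (lo, hi):
            curve = component_quantile_curve(fit, m, level, var, grid, fixed=fx or None)
            rows.append(pd.DataFrame({
                "group": "" if g is None else str(g),
                "x": curve.grid,
                "level": level,
                "value": curve.values,
            }))
    return pd.concat(rows, ignore_index=True)
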