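"""Cubic B-spline bases for the non-linear terms of additive predictors.

The convention matches R's ``bs(x, df=...)``: the basis has ``df`` columns
*excluding* the intercept (the first column of the full basis is dropped and
absorbed into the model intercept).  With degree 3 and df 3 there are no
interior knots, so the basis spans the cubic polynomials on the boundary
interval.  When ``df > degree`` the interior knots are placed at quantiles
of the training covariate.

Evaluation outside the boundary knots clamps to the boundary: reference
limit curves must stay flat, not explode, beyond the observed covariate
range.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "build_basis", "evaluate_basis"]


class RankError(ValueError):
    """Too few distinct covariate values to support the requested basis."""


@dataclass(frozen=True)
class BasisSpec:
    """Specification of one B-spline term.

    ``boundary`` and ``interior_knots`` are ``None`` until the basis has
    been built on training data ("finalized"); afterwards they freeze the
    basis so prediction reproduces the training columns exactly.
    """

    var: str
    df: int = 3
    degree: int = 3
    boundary: Optional[tuple[float, float]] = None
    interior_knots: Optional[tuple[float, ...]] = None

    @property
    def finalized(self) -> bool:
        return self.boundary is not None and self.interior_knots is not None

    def knot_vector(self) -> np.ndarray:
        if not self.finalized:
            raise RuntimeError("BasisSpec is not finalized; call build_basis first")
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.full(self.degree + 1, lo),
                np.asarray(self.interior_knots, dtype=float),
                np.full(self.degree + 1, hi),
            ]
        )


def _full_design(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Full (intercept-inclusive) design matrix, df+1 columns."""
    t = spec.knot_vector()
    lo, hi = spec.boundary
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, t, spec.degree, extrapolate=False).toarray()


def build_basis(x, spec: BasisSpec) -> tuple[np.ndarray, BasisSpec]:
    """Construct the training basis and freeze the knots.

    Returns an ``n x df`` matrix (first full-basis column dropped) and the
    finalized :class:`BasisSpec`.  Raises :class:`RankError` when ``x`` has
    fewer than ``df + 1`` distinct values.
    """
    x = np.asarray(x, dtype=float)
    distinct = np.unique(x)
    if distinct.size < spec.df + 1:
        raise RankError(
            f"term {spec.var!r}: needs at least df+1={spec.df + 1} distinct "
            f"covariate values, got {distinct.size}"
        )
    if spec.df < spec.degree:
        raise ValueError(f"term {spec.var!r}: df ({spec.df}) must be >= degree ({spec.degree})")
    n_interior = spec.df - spec.degree
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = tuple(np.quantile(x, probs))
    else:
        interior = ()
    final = replace(
        spec,
        boundary=(float(distinct[0]), float(distinct[-1])),
        interior_knots=interior,
    )
    design = _full_design(x, final)[:, 1:]
    # the intercept-augmented basis must be identifiable on the training data
    aug = np.column_stack([np.ones(len(x)), design])
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        raise RankError(f"term {spec.var!r}: basis is rank deficient on the training data")
    return design, final


def evaluate_basis(spec: BasisSpec, x_new) -> np.ndarray:
    """Evaluate a finalized basis at new covariate values.

    Values outside the boundary knots are clamped to the boundary.
    """
    if not spec.finalized:
        raise RuntimeError("BasisSpec is not finalized; call build_basis first")
    return _full_design(np.asarray(x_new, dtype=float), spec)[:, 1:]
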