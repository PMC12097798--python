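"""Linear superpopulation model, stratum cost model, and the total objective.

The study variable y is linked to the two stratification variables by
y = a1 + a2·x1 + a3·x2 + e with E(e|x1,x2) = 0 and V(e|x1,x2) = η. Under this
model the study-variable variance inside a stratum cell is

    σ²_y = a2²·σ²_x1 + a3²·σ²_x2

(the error variance η is excluded by default, matching the design-based
objective that only the systematic part responds to the boundaries; pass
``include_error_var=True`` to add η under the square root).

The quantity minimized over strata boundaries is Σ_hk W_hk·S_hk·√C_hk, the
cost-weighted Neyman sum whose square, divided by the net budget C − C1,
is the optimum-allocation variance of the stratified mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densities import BivariateDesign, StratumMoments
from .errors import InputError, SingularFitError


@dataclass(frozen=True)
class LinearSuperpopModel:
    """y = intercept + coef1·x1 + coef2·x2 + e, with V(e) = error_var ≥ 0."""

    intercept: float
    coef1: float
    coef2: float
    error_var: float = 0.0

    def __post_init__(self) -> None:
        if self.error_var < 0:
            raise InputError("error_var must be >= 0")


@dataclass(frozen=True)
class CostModel:
    """Survey cost: overhead C1 plus per-unit stratum costs C_hk, budget C.

    ``unit_costs`` is an L×M matrix addressed row-major by (h, k); a scalar
    broadcasts to any grid shape.
    """

    overhead: float
    unit_costs: np.ndarray
    budget: float

    def __post_init__(self) -> None:
        costs = np.atleast_2d(np.asarray(self.unit_costs, dtype=float))
        object.__setattr__(self, "unit_costs", costs)
        if self.overhead < 0:
            raise InputError("overhead must be >= 0")
        if np.any(costs <= 0):
            raise InputError("all unit costs must be > 0")
        if self.budget <= self.overhead:
            raise InputError("budget must exceed overhead")

    @property
    def net_budget(self) -> float:
        """C − C1, the amount available for measurement."""
        return self.budget - self.overhead

    def cost_matrix(self, L: int, M: int) -> np.ndarray:
        c = self.unit_costs
        if c.shape == (1, 1):
            return np.full((L, M), float(c[0, 0]))
        if c.shape != (L, M):
            raise InputError(f"cost matrix shape {c.shape} does not match ({L}, {M})")
        return c


def equal_costs(L: int, M: int, unit: float = 1.0, overhead: float = 0.0,
                budget: float = None) -> CostModel:
    if budget is None:
        budget = overhead + 1.0
    return CostModel(overhead, np.full((L, M), unit), budget)


def y_cell_variance(
    model: LinearSuperpopModel,
    moments: StratumMoments,
    include_error_var: bool = False,
) -> float:
    """Model-implied study-variable variance of one cell."""
    v = model.coef1**2 * moments.var1 + model.coef2**2 * moments.var2
    if include_error_var:
        v += model.error_var
    return float(v)


def cell_objective(moments: StratumMoments, unit_cost: float) -> float:
    """One summand W_hk·S_hk·√C_hk of the total objective (S from var_y)."""
    if unit_cost <= 0:
        raise InputError("unit cost must be > 0")
    return float(moments.weight * np.sqrt(moments.var_y) * np.sqrt(unit_cost))


def total_objective(
    design: BivariateDesign,
    model: LinearSuperpopModel,
    grid,
    costs: CostModel,
    include_error_var: bool = False,
) -> float:
    """Σ_hk W_hk·S_hk·√C_hk over all cells of a strata grid.

    ``grid`` is any object with ordered cut arrays ``cuts1`` (length L+1) and
    ``cuts2`` (length M+1) partitioning the two supports.
    """
    cuts1 = np.asarray(grid.cuts1, dtype=float)
    cuts2 = np.asarray(grid.cuts2, dtype=float)
    L, M = len(cuts1) - 1, len(cuts2) - 1
    cmat = costs.cost_matrix(L, M)
    w1, _, v1 = design.axis1.moments(cuts1[:-1], cuts1[1:])
    w2, _, v2 = design.axis2.moments(cuts2[:-1], cuts2[1:])
    var_y = model.coef1**2 * v1[:, None] + model.coef2**2 * v2[None, :]
    if include_error_var:
        var_y = var_y + model.error_var
    contrib = w1[:, None] * w2[None, :] * np.sqrt(var_y) * np.sqrt(cmat)
    return float(contrib.sum())


def fit_linear_superpop(y, x1, x2) -> LinearSuperpopModel:
    """Ordinary least squares of y on (1, x1, x2).

    error_var is the residual mean square with n − 3 degrees of freedom.
    Raises :class:`SingularFitError` on a rank-deficient design matrix.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (len(y) == len(x1) == len(x2)):
        raise InputError("y, x1, x2 must have equal lengths")
    n = len(y)
    if n < 3:
        raise InputError("need at least 3 observations")
    X = np.column_stack([np.ones(n), x1, x2])
    if np.linalg.matrix_rank(X) < 3:
        raise SingularFitError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 3
    error_var = float(resid @ resid / dof) if dof > 0 else 0.0
    return LinearSuperpopModel(
        intercept=float(beta[0]),
        coef1=float(beta[1]),
        coef2=float(beta[2]),
        error_var=error_var,
    )
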