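"""Optimal strata boundaries by dynamic programming over discretized widths.

The boundary problem is posed in strata widths: choose non-negative widths
R_1h (axis 1) and R_2k (axis 2) summing to the axis ranges so that the total
objective Σ_hk W_hk·S_hk·√C_hk is minimal. Widths are discretized on a grid
of ``grid_points`` equal steps per axis and each axis is solved exactly by a
forward Bellman recursion ψ over cumulative width: ψ_h(r) is the best value
of the first h strata using cumulative width r, and

    ψ_h(r) = min_{0 ≤ r' ≤ r} [ ψ_{h−1}(r') + g_h(r', r) ]

with g_h the single-stratum cost of [r', r] at stage h. Stage costs may
depend on h (row-dependent unit costs), which the recursion handles directly.

The bivariate objective couples the two axes through
√(a2²σ²_1h + a3²σ²_2k), so a single separable DP is not exact; the bivariate
solver alternates exact axis-wise DP sweeps (each axis re-optimized globally
while the other axis's cuts are held fixed), starting from equal-width cuts,
until the objective stops improving. An exhaustive enumerator certifies
global optimality on small grids and serves as the test oracle.

Ties are broken deterministically: the smallest cumulative-width index wins,
which yields the lexicographically smallest cut vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Optional

import itertools

import numpy as np

from .densities import BivariateDesign
from .errors import BudgetExceededError, InfeasibleError, InputError
from .superpop import CostModel, LinearSuperpopModel

DEFAULT_GRID_POINTS = 200
SWEEP_TOL = 1e-10
MAX_SWEEPS = 20


# ---------------------------------------------------------------------------
# Strata grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrataGrid:
    """Ordered boundary vectors on each axis defining L×M rectangular strata.

    ``cuts1`` runs a = x1_0 ≤ … ≤ x1_L = b and ``cuts2`` likewise, so the
    widths on each axis sum exactly to the axis range.
    """

    cuts1: np.ndarray
    cuts2: np.ndarray

    def __post_init__(self) -> None:
        c1 = np.asarray(self.cuts1, dtype=float)
        c2 = np.asarray(self.cuts2, dtype=float)
        if len(c1) < 2 or len(c2) < 2:
            raise InputError("each axis needs at least two cuts (the endpoints)")
        if np.any(np.diff(c1) < 0) or np.any(np.diff(c2) < 0):
            raise InputError("cut sequences must be non-decreasing")
        object.__setattr__(self, "cuts1", c1)
        object.__setattr__(self, "cuts2", c2)

    @property
    def L(self) -> int:
        return len(self.cuts1) - 1

    @property
    def M(self) -> int:
        return len(self.cuts2) - 1

    def collapse_empty(self) -> "StrataGrid":
        """Drop zero-width strata (duplicate cuts) on both axes."""
        return StrataGrid(np.unique(self.cuts1), np.unique(self.cuts2))


def equal_width_grid(design: BivariateDesign, L: int, M: int) -> StrataGrid:
    a1, a2 = design.axis1, design.axis2
    return StrataGrid(
        np.linspace(a1.support_lo, a1.support_hi, L + 1),
        np.linspace(a2.support_lo, a2.support_hi, M + 1),
    )


@dataclass(frozen=True)
class BoundaryResult:
    grid: StrataGrid
    objective: float
    sweeps: int = 0
    converged: bool = True


@dataclass(frozen=True)
class UnivariateResult:
    cuts: np.ndarray
    objective: float


# ---------------------------------------------------------------------------
# Core DP on a single axis
# ---------------------------------------------------------------------------


def _dp_solve(stage_costs) -> tuple[float, np.ndarray]:
    """Exact DP over monotone cut-index sequences.

    ``stage_costs`` is a sequence of (G+1)×(G+1) matrices; entry [i, j] of
    the h-th matrix is the cost of stratum h spanning grid indices i → j
    (i ≤ j; the lower triangle is ignored). Returns the optimal value and the
    optimal cut-index vector of length L+1 (0 … G). ``argmin`` scans ascending
    indices, so ties resolve to the smallest cumulative-width index.
    """
    L = len(stage_costs)
    G = stage_costs[0].shape[0] - 1
    psi = np.full(G + 1, np.inf)
    psi[0] = 0.0
    back = np.zeros((L, G + 1), dtype=int)
    for h in range(L):
        g = np.where(
            np.arange(G + 1)[:, None] <= np.arange(G + 1)[None, :],
            stage_costs[h],
            np.inf,
        )
        cand = psi[:, None] + g
        back[h] = np.argmin(cand, axis=0)
        psi = np.min(cand, axis=0)
    idx = np.empty(L + 1, dtype=int)
    idx[L] = G
    for h in range(L - 1, -1, -1):
        idx[h] = back[h, idx[h + 1]]
    return float(psi[G]), idx


def optimize_univariate(
    objective_fn: Callable,
    support: tuple,
    L: int,
    grid_points: int = DEFAULT_GRID_POINTS,
) -> BoundaryResult:
    """Globally optimal univariate strata boundaries on a discretized axis.

    ``objective_fn(lo, hi)`` is the single-stratum cost of [lo, hi]; it must
    accept numpy array bounds (it is evaluated once on the full (G+1)² mesh).
    Returns cuts anchored at the support endpoints achieving the minimal
    Σ_h objective over all grid-restricted partitions into L strata.
    """
    if L < 1:
        raise InputError("L must be >= 1")
    if grid_points < L:
        raise InfeasibleError(f"grid_points={grid_points} < L={L}")
    lo, hi = float(support[0]), float(support[1])
    points = np.linspace(lo, hi, grid_points + 1)
    LO, HI = np.meshgrid(points, points, indexing="ij")
    with np.errstate(invalid="ignore"):
        g = np.asarray(objective_fn(LO, HI), dtype=float)
    g = np.where(np.isfinite(g), g, np.inf)
    value, idx = _dp_solve([g] * L)
    return UnivariateResult(cuts=points[idx], objective=value)


# ---------------------------------------------------------------------------
# Bivariate alternating DP
# ---------------------------------------------------------------------------


def _axis_tables(dens, grid_points: int):
    """(G+1)-point axis grid plus (G+1)² mass and variance pair tables."""
    points = np.linspace(dens.support_lo, dens.support_hi, grid_points + 1)
    LO, HI = np.meshgrid(points, points, indexing="ij")
    w, _, v = dens.moments(np.minimum(LO, HI), np.maximum(LO, HI))
    return points, w, v


def _stage_costs_given_other(w_pair, v_pair, w_other, v_other, coef_self,
                             coef_other, cmat_rows, eta: float):
    """Per-stage (G+1)² cost tables for one axis, other axis's strata fixed.

    ``cmat_rows[h, k]`` must be indexed so h is the stage of the axis being
    optimized and k enumerates the fixed strata of the other axis.
    """
    L = cmat_rows.shape[0]
    tables = []
    for h in range(L):
        acc = 0.0
        for k in range(cmat_rows.shape[1]):
            s = np.sqrt(coef_self**2 * v_pair + coef_other**2 * v_other[k] + eta)
            acc = acc + w_other[k] * np.sqrt(cmat_rows[h, k]) * w_pair * s
        tables.append(acc)
    return tables


def optimize_bivariate(
    design: BivariateDesign,
    model: LinearSuperpopModel,
    costs: CostModel,
    L: int,
    M: int,
    grid_points: int = DEFAULT_GRID_POINTS,
    tol: float = SWEEP_TOL,
    max_sweeps: int = MAX_SWEEPS,
    include_error_var: bool = False,
) -> BoundaryResult:
    """Strata boundaries for two axes by alternating exact axis-wise DP.

    Starting from equal-width cuts on both axes, each sweep re-optimizes one
    axis globally (exact DP on the width grid) with the other axis fixed,
    then the converse, until the objective improves by less than ``tol`` or
    ``max_sweeps`` sweeps have run. The result is a coordinate-wise optimum:
    no univariate re-optimization of either axis can improve it on the grid.
    """
    if L < 1 or M < 1:
        raise InputError("L and M must be >= 1")
    if grid_points < max(L, M):
        raise InfeasibleError("grid_points must be >= max(L, M)")
    cmat = costs.cost_matrix(L, M)
    eta = model.error_var if include_error_var else 0.0
    a2, a3 = model.coef1, model.coef2

    pts1, w1_pair, v1_pair = _axis_tables(design.axis1, grid_points)
    pts2, w2_pair, v2_pair = _axis_tables(design.axis2, grid_points)

    idx1 = np.round(np.linspace(0, grid_points, L + 1)).astype(int)
    idx2 = np.round(np.linspace(0, grid_points, M + 1)).astype(int)

    def strata_moments(w_pair, v_pair, idx):
        i, j = idx[:-1], idx[1:]
        return w_pair[i, j], v_pair[i, j]

    def current_value(idx1, idx2):
        w1, v1 = strata_moments(w1_pair, v1_pair, idx1)
        w2, v2 = strata_moments(w2_pair, v2_pair, idx2)
        s = np.sqrt(a2**2 * v1[:, None] + a3**2 * v2[None, :] + eta)
        return float((w1[:, None] * w2[None, :] * s * np.sqrt(cmat)).sum())

    value = current_value(idx1, idx2)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        w2, v2 = strata_moments(w2_pair, v2_pair, idx2)
        tables1 = _stage_costs_given_other(
            w1_pair, v1_pair, w2, v2, a2, a3, cmat, eta
        )
        _, idx1 = _dp_solve(tables1)
        w1, v1 = strata_moments(w1_pair, v1_pair, idx1)
        tables2 = _stage_costs_given_other(
            w2_pair, v2_pair, w1, v1, a3, a2, cmat.T, eta
        )
        _, idx2 = _dp_solve(tables2)
        new_value = current_value(idx1, idx2)
        if value - new_value < tol:
            value = min(value, new_value)
            converged = True
            break
        value = new_value
    grid = StrataGrid(pts1[idx1], pts2[idx2])
    return BoundaryResult(grid=grid, objective=value, sweeps=sweeps,
                          converged=converged)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def _partition_count(grid_points: int, n_interior: int) -> int:
    # multisets of interior indices 0..G with repetition allowed
    return comb(grid_points + n_interior, n_interior)


def exhaustive_search(
    design: BivariateDesign,
    model: LinearSuperpopModel,
    costs: CostModel,
    L: int,
    M: int,
    grid_points: int,
    max_evals: int = 10**6,
    include_error_var: bool = False,
) -> BoundaryResult:
    """Enumerate every grid-restricted partition; exact minimizer, test oracle.

    Ties break to the lexicographically smallest cut-index vector. Refuses
    (with the size estimate) when the enumeration would exceed ``max_evals``.
    """
    if L < 1 or M < 1:
        raise InputError("L and M must be >= 1")
    total = _partition_count(grid_points, L - 1) * _partition_count(
        grid_points, M - 1
    )
    if total > max_evals:
        raise BudgetExceededError(
            f"{total} partitions exceed the enumeration budget {max_evals}"
        )
    cmat = costs.cost_matrix(L, M)
    eta = model.error_var if include_error_var else 0.0
    a2, a3 = model.coef1, model.coef2
    pts1, w1_pair, v1_pair = _axis_tables(design.axis1, grid_points)
    pts2, w2_pair, v2_pair = _axis_tables(design.axis2, grid_points)
    G = grid_points

    def value_of(idx1, idx2):
        i1 = np.asarray(idx1)
        i2 = np.asarray(idx2)
        w1, v1 = w1_pair[i1[:-1], i1[1:]], v1_pair[i1[:-1], i1[1:]]
        w2, v2 = w2_pair[i2[:-1], i2[1:]], v2_pair[i2[:-1], i2[1:]]
        s = np.sqrt(a2**2 * v1[:, None] + a3**2 * v2[None, :] + eta)
        return float((w1[:, None] * w2[None, :] * s * np.sqrt(cmat)).sum())

    best = (np.inf, None, None)
    inner1 = itertools.combinations_with_replacement(range(G + 1), L - 1)
    for c1 in inner1:
        idx1 = (0, *c1, G)
        inner2 = itertools.combinations_with_replacement(range(G + 1), M - 1)
        for c2 in inner2:
            idx2 = (0, *c2, G)
            v = value_of(idx1, idx2)
            if v < best[0]:
                best = (v, idx1, idx2)
    value, idx1, idx2 = best
    grid = StrataGrid(pts1[list(idx1)], pts2[list(idx2)])
    return BoundaryResult(grid=grid, objective=value)
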