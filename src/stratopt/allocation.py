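"""Sample allocation across strata under a cost budget, and design variances.

Given stratum weights W_hk, study-variable standard deviations S_hk, per-unit
costs C_hk and a net budget C − C1, the Lagrangian (optimum-allocation)
solution is

    n_hk = (C − C1) / (Σ W·S·√C) · W_hk·S_hk / √C_hk,

which spends the net budget exactly and attains the optimum variance

    V_opt = (Σ W·S·√C)² / (C − C1) − Σ W²·S²/N_hk.

With equal unit costs this reduces to Neyman allocation. A fixed-total mode
replaces the budget normalization so Σ n_hk equals a requested sample size.
The finite-population correction term is applied only when the per-stratum
population counts N_hk are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InfeasibleError, InputError
from .superpop import CostModel


@dataclass(frozen=True)
class AllocationResult:
    """Per-stratum sample sizes with achieved variance and total cost."""

    n_real: np.ndarray
    n_int: np.ndarray
    achieved_variance: float
    optimal_variance: float
    total_cost: float
    total_n: int


def _as_grid(weights, sds):
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    S = np.atleast_2d(np.asarray(sds, dtype=float))
    if W.shape != S.shape:
        raise InputError("weights and sds must have the same shape")
    if np.any(W < 0) or np.any(S < 0):
        raise InputError("weights and sds must be non-negative")
    return W, S


def optimal_allocation(weights, sds, costs: CostModel) -> np.ndarray:
    """Budget-exhausting optimum allocation n_hk (real-valued, pre-rounding)."""
    W, S = _as_grid(weights, sds)
    cmat = costs.cost_matrix(*W.shape)
    ws = W * S
    denom = float((ws * np.sqrt(cmat)).sum())
    if denom <= 0:
        raise InfeasibleError("all strata are degenerate (W·S = 0 everywhere)")
    return costs.net_budget / denom * ws / np.sqrt(cmat)


def neyman_allocation(weights, sds, total: float, costs: Optional[CostModel] = None
                      ) -> np.ndarray:
    """Fixed-total allocation: n_hk ∝ W·S/√C normalized so Σ n_hk = total."""
    W, S = _as_grid(weights, sds)
    root_c = (
        np.sqrt(costs.cost_matrix(*W.shape)) if costs is not None else np.ones(W.shape)
    )
    shares = W * S / root_c
    if shares.sum() <= 0:
        raise InfeasibleError("all strata are degenerate (W·S = 0 everywhere)")
    return total * shares / shares.sum()


def stratified_variance(weights, sds, n, N=None) -> float:
    """Variance of the stratified mean: Σ (1/n_hk − 1/N_hk)·W²·S².

    The finite-population correction 1/N_hk is dropped when ``N`` is None.
    Strata with W·S = 0 contribute nothing regardless of n.
    """
    W, S = _as_grid(weights, sds)
    n = np.atleast_2d(np.asarray(n, dtype=float))
    ws2 = (W * S) ** 2
    active = ws2 > 0
    if np.any(active & (n <= 0)):
        raise InputError("n must be > 0 in every stratum with positive W·S")
    inv_n = np.zeros_like(ws2)
    inv_n[active] = 1.0 / n[active]
    if N is not None:
        Nm = np.atleast_2d(np.asarray(N, dtype=float))
        inv_n = inv_n - np.where(Nm > 0, 1.0 / np.where(Nm > 0, Nm, 1.0), 0.0)
    return float((inv_n * ws2).sum())


def optimal_variance(weights, sds, costs: CostModel, N=None) -> float:
    """V_opt = (Σ W·S·√C)²/(C − C1) − Σ W²S²/N_hk (second term only with N)."""
    W, S = _as_grid(weights, sds)
    cmat = costs.cost_matrix(*W.shape)
    lead = float((W * S * np.sqrt(cmat)).sum()) ** 2 / costs.net_budget
    if N is None:
        return lead
    Nm = np.atleast_2d(np.asarray(N, dtype=float))
    fpc = np.where(Nm > 0, (W * S) ** 2 / np.where(Nm > 0, Nm, 1.0), 0.0)
    return lead - float(fpc.sum())


def total_cost(n, costs: CostModel) -> float:
    """C = C1 + Σ C_hk·n_hk."""
    n = np.atleast_2d(np.asarray(n, dtype=float))
    cmat = costs.cost_matrix(*n.shape)
    return float(costs.overhead + (cmat * n).sum())


def round_allocation(n_real, mode: str = "largest_remainder",
                     total: Optional[int] = None) -> np.ndarray:
    """Integer sample sizes from a real allocation.

    Every stratum with n_real > 0 receives at least 1 unit (so its variance
    is estimable). ``largest_remainder`` preserves a stated total exactly
    (ties broken by row-major index); ``floor_repair`` floors and never
    exceeds the implied total.
    """
    n = np.atleast_2d(np.asarray(n_real, dtype=float))
    if np.any(n < 0):
        raise InputError("n_real must be >= 0")
    positive = n > 0
    n_pos = int(positive.sum())
    if mode == "floor_repair":
        out = np.floor(n).astype(int)
        out[positive & (out == 0)] = 1
        return out
    if mode != "largest_remainder":
        raise InputError(f"unknown rounding mode {mode!r}")
    if total is None:
        total = int(round(n.sum()))
    if total < n_pos:
        raise InfeasibleError(
            f"total {total} cannot give every one of {n_pos} active strata >= 1 unit"
        )
    if n.sum() > 0 and total != 0:
        n = n * (total / n.sum())  # keep proportions when the stated total differs
    out = np.floor(n).astype(int)
    out[positive & (out == 0)] = 1
    deficit = total - int(out.sum())
    remainder = np.where(positive, n - np.floor(n), -1.0)
    order = np.lexsort(
        (np.arange(n.size), -remainder.ravel())
    )  # largest remainder first, row-major tie-break
    flat = out.ravel()
    if deficit > 0:
        for idx in order[:deficit]:
            flat[idx] += 1
    elif deficit < 0:
        # min-1 top-ups overshot the total: take back from smallest remainders
        for idx in order[::-1]:
            if deficit == 0:
                break
            if flat[idx] > 1 or (flat[idx] == 1 and n.ravel()[idx] == 0):
                flat[idx] -= 1
                deficit += 1
        if deficit != 0:
            raise InfeasibleError("cannot satisfy total with min-1 constraint")
    return flat.reshape(n.shape)


def allocate(
    weights,
    sds,
    costs: Optional[CostModel] = None,
    total_n: Optional[int] = None,
    N=None,
    rounding: str = "largest_remainder",
) -> AllocationResult:
    """End-to-end allocation: real sizes, rounding, variances and cost.

    Either a :class:`CostModel` (budget mode, the Lagrangian solution) or
    ``total_n`` (fixed-total Neyman mode) must be given. When per-stratum
    population counts ``N`` are supplied, allocations are clipped at N_hk
    with the surplus re-spread across the remaining strata to a fixpoint.
    """
    W, S = _as_grid(weights, sds)
    if costs is None and total_n is None:
        raise InputError("provide a CostModel or total_n")
    if costs is not None and total_n is None:
        n_real = optimal_allocation(W, S, costs)
    else:
        n_real = neyman_allocation(W, S, total_n, costs)
    if N is not None:
        n_real = _clip_to_population(n_real, W, S, costs, total_n, N)
    rounding_total = total_n if total_n is not None else None
    n_int = round_allocation(n_real, mode=rounding, total=rounding_total)
    cm = costs if costs is not None else _unit_cost_model(W.shape)
    # reported variances ignore the FPC; N is used for clipping only
    achieved = stratified_variance(W, S, np.where(n_real > 0, n_real, 1.0))
    vopt = optimal_variance(W, S, cm) if costs is not None else achieved
    return AllocationResult(
        n_real=n_real,
        n_int=n_int,
        achieved_variance=achieved,
        optimal_variance=vopt,
        total_cost=total_cost(n_int, cm),
        total_n=int(n_int.sum()),
    )


def _unit_cost_model(shape) -> CostModel:
    return CostModel(0.0, np.ones(shape), 1.0)


def _clip_to_population(n_real, W, S, costs, total_n, N, max_iter: int = 50):
    """Clip n_hk at N_hk, re-allocating the surplus among unclipped strata."""
    Nm = np.atleast_2d(np.asarray(N, dtype=float))
    n = np.array(n_real, dtype=float)
    clipped = np.zeros(n.shape, dtype=bool)
    for _ in range(max_iter):
        over = (n > Nm) & ~clipped
        if not over.any():
            break
        clipped |= over
        n = np.where(clipped, Nm, n)
        free = ~clipped & (W * S > 0)
        if not free.any():
            break
        if total_n is not None:
            residual = total_n - n[clipped].sum()
            shares = np.where(free, W * S, 0.0)
            if costs is not None:
                shares = shares / np.sqrt(costs.cost_matrix(*W.shape))
            n = np.where(free, residual * shares / shares.sum(), n)
        else:
            cmat = costs.cost_matrix(*W.shape)
            residual = costs.net_budget - (cmat[clipped] * n[clipped]).sum()
            ws = np.where(free, W * S, 0.0)
            denom = (ws * np.sqrt(cmat)).sum()
            n = np.where(free, residual / denom * ws / np.sqrt(cmat), n)
    return n
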