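"""Classical univariate stratification rules and a common evaluation metric.

Implemented comparators:

* cumulative square-root-frequency rule (Dalenius–Hodges): histogram the
  sample, accumulate √frequency, cut at bin edges nearest the equal splits of
  the cumulative-√f scale;
* geometric rule (Gunning–Horgan): boundaries in geometric progression
  between the sample extremes (positive data only);
* Kozak-style random search refining Lavallée–Hidiroglou boundaries: start
  from the cum-√f cuts snapped to observed values, perturb one random cut at
  a time along the sorted sample, accept only improvements of the Neyman
  objective Σ W_h·S_h;
* width-grid dynamic programming on the same Neyman objective (the
  mathematical-programming comparator and the proposed method at different
  grid resolutions).

All methods are scored on one metric, (Σ_h W_h·S_h)² — the equal-cost,
FPC-ignored optimum-allocation variance numerator — computed from the sample
moments of the induced strata. Empty strata contribute zero; single-unit
strata have S_h = 0 under the N_h − 1 divisor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, InputError
from .boundaries import _dp_solve

DEFAULT_KOZAK_ITERATIONS = 200


@dataclass(frozen=True)
class MethodResult:
    method_name: str
    cuts: np.ndarray
    objective: float  # Σ W_h·S_h
    variance_metric: float  # (Σ W_h·S_h)²


# ---------------------------------------------------------------------------
# Sample-moment machinery (shared by objective evaluations)
# ---------------------------------------------------------------------------


class _SampleMoments:
    """Prefix-sum moments of a sorted sample for O(1) stratum W, S queries."""

    def __init__(self, sample) -> None:
        xs = np.asarray(sample, dtype=float)
        if xs.ndim != 1 or len(xs) == 0:
            raise InputError("sample must be a non-empty 1-D array")
        self.sorted = np.sort(xs)
        self.n = len(xs)
        self.c1 = np.concatenate([[0.0], np.cumsum(self.sorted)])
        self.c2 = np.concatenate([[0.0], np.cumsum(self.sorted**2)])

    def ws_for_cuts(self, cuts) -> tuple[np.ndarray, np.ndarray]:
        """Per-stratum (W_h, S_h) for boundary vector ``cuts`` (len L+1).

        Strata are [lo, hi), upper-closed on the last stratum.
        """
        cuts = np.asarray(cuts, dtype=float)
        idx = np.searchsorted(self.sorted, cuts, side="left")
        idx[-1] = self.n  # last stratum takes everything up to the maximum
        counts = np.diff(idx)
        w = counts / self.n
        s1 = np.diff(self.c1[idx])
        s2 = np.diff(self.c2[idx])
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, s1 / np.maximum(counts, 1), 0.0)
            ss = s2 - counts * mean**2
            var = np.where(counts > 1, ss / np.maximum(counts - 1, 1), 0.0)
        return w, np.sqrt(np.maximum(var, 0.0))

    def neyman(self, cuts) -> float:
        w, s = self.ws_for_cuts(cuts)
        return float((w * s).sum())


def _full_cuts(mom: _SampleMoments, cuts) -> np.ndarray:
    """Boundary vector anchored at the sample extremes (interior cuts kept)."""
    cuts = np.sort(np.asarray(cuts, dtype=float).ravel())
    lo, hi = mom.sorted[0], mom.sorted[-1]
    inner = cuts[(cuts > lo) & (cuts < hi)]
    return np.concatenate([[lo], inner, [hi]])


def neyman_objective(sample, cuts) -> float:
    """Σ_h W_h·S_h of the strata induced on the sample by ``cuts``.

    ``cuts`` may be the interior boundaries alone or include the endpoints.
    """
    mom = _SampleMoments(sample)
    return mom.neyman(_full_cuts(mom, cuts))


def evaluate_method(sample, cuts) -> float:
    """Common variance metric (Σ_h W_h·S_h)² for any boundary set."""
    return neyman_objective(sample, cuts) ** 2


# ---------------------------------------------------------------------------
# Boundary rules
# ---------------------------------------------------------------------------


def cum_root_f_boundaries(sample, L: int, n_bins: Optional[int] = None) -> np.ndarray:
    """Cumulative square-root-frequency boundaries.

    Cuts are placed at histogram bin edges nearest the j/L splits of the
    cumulative-√frequency scale, j = 1..L−1.
    """
    xs = np.asarray(sample, dtype=float)
    if len(xs) == 0:
        raise InputError("empty sample")
    if L < 2:
        raise InputError("L must be >= 2")
    if n_bins is None:
        n_bins = min(max(int(round(np.sqrt(len(xs)))), L), 100)
    if n_bins < L:
        raise InputError("n_bins must be >= L")
    freq, edges = np.histogram(xs, bins=n_bins)
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(freq))])
    targets = cum[-1] * np.arange(1, L) / L
    cut_idx = np.array([int(np.argmin(np.abs(cum - t))) for t in targets])
    return edges[cut_idx]


def geometric_boundaries(lo: float, hi: float, L: int) -> np.ndarray:
    """Geometric-progression boundaries lo·r^j with r = (hi/lo)^(1/L)."""
    if lo <= 0:
        raise DomainError("geometric rule requires a strictly positive minimum")
    if hi <= lo:
        raise InputError("hi must exceed lo")
    if L < 2:
        raise InputError("L must be >= 2")
    r = (hi / lo) ** (1.0 / L)
    return lo * r ** np.arange(1, L)


def lh_kozak_boundaries(
    sample,
    L: int,
    seed: int,
    iterations: int = DEFAULT_KOZAK_ITERATIONS,
) -> np.ndarray:
    """Kozak random-search refinement of Lavallée–Hidiroglou boundaries.

    Boundaries live on sorted-sample positions (finite search space). From
    the cum-√f seed cuts, one randomly chosen cut is moved by a random number
    of positions; moves are accepted only if the Neyman objective Σ W·S
    decreases, and the search stops after ``iterations`` consecutive
    non-improving proposals. ``iterations=0`` returns the seed cuts.
    """
    xs = np.asarray(sample, dtype=float)
    if len(xs) < L:
        raise InputError("sample smaller than number of strata")
    mom = _SampleMoments(xs)
    srt = mom.sorted
    start = cum_root_f_boundaries(xs, L)
    pos = np.clip(np.searchsorted(srt, start), 1, mom.n - 1)
    pos = np.sort(pos)

    def cuts_of(p):
        return np.concatenate([[srt[0]], srt[p], [srt[-1]]])

    best = mom.neyman(cuts_of(pos))
    rng = np.random.default_rng(seed)
    max_step = max(1, mom.n // 100)
    stale = 0
    while stale < iterations:
        j = int(rng.integers(L - 1))
        step = int(rng.integers(1, max_step + 1)) * (1 if rng.random() < 0.5 else -1)
        cand = pos.copy()
        lo_lim = cand[j - 1] + 1 if j > 0 else 1
        hi_lim = cand[j + 1] - 1 if j < L - 2 else mom.n - 1
        if hi_lim < lo_lim:
            stale += 1
            continue
        cand[j] = int(np.clip(cand[j] + step, lo_lim, hi_lim))
        val = mom.neyman(cuts_of(cand))
        if val < best:
            best, pos = val, cand
            stale = 0
        else:
            stale += 1
    return srt[pos]


def dp_boundaries(sample, L: int, grid_points: int) -> np.ndarray:
    """Width-grid DP minimizing Σ W_h·S_h on the observed range.

    At a fine grid this is the proposed method specialized to one axis and
    equal costs; at a coarser grid it serves as the mathematical-programming
    comparator. Returns the L−1 interior cuts.
    """
    mom = _SampleMoments(sample)
    lo, hi = mom.sorted[0], mom.sorted[-1]
    points = np.linspace(lo, hi, grid_points + 1)
    idx = np.searchsorted(mom.sorted, points, side="left")
    idx[-1] = mom.n
    counts = idx[None, :] - idx[:, None]
    s1 = mom.c1[idx][None, :] - mom.c1[idx][:, None]
    s2 = mom.c2[idx][None, :] - mom.c2[idx][:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, s1 / np.maximum(counts, 1), 0.0)
        ss = s2 - counts * mean**2
        var = np.where(counts > 1, ss / np.maximum(counts - 1, 1), 0.0)
    g = (counts / mom.n) * np.sqrt(np.maximum(var, 0.0))
    _, cut_idx = _dp_solve([g] * L)
    return points[cut_idx][1:-1]


def snap_to_grid(cuts, lo: float, hi: float, grid_points: int) -> np.ndarray:
    """Snap boundary values to the nearest width-grid point on [lo, hi]."""
    points = np.linspace(lo, hi, grid_points + 1)
    cuts = np.asarray(cuts, dtype=float)
    snapped = points[np.argmin(np.abs(points[None, :] - cuts[:, None]), axis=1)]
    return np.sort(snapped)
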