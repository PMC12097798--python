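"""Auxiliary-variable distributions on finite supports and rectangular-cell moments.

A stratification variable is modelled by a :class:`DensitySpec`: a parametric
density (uniform, standard power, standard Cauchy) restricted to a finite
interval, or an empirical sample. Two independent axes form a
:class:`BivariateDesign`, and every rectangular stratum :class:`Cell` has a
weight (probability mass), per-axis means and variances — the ingredients of
the stratified-variance objective.

All parametric moments have analytic closed forms (the fast path) and an
adaptive-quadrature ground truth (``method="quadrature"``) used as the oracle
in the test suite. The truncated Cauchy is *not* renormalized by default: the
full-line density is integrated over the cell, so weights over a restricted
support sum to the support's total mass (arctan(b) − arctan(a))/π rather than
1. Pass ``normalize=True`` for a proper truncated distribution; the
stratification objective is unaffected by such a common factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import integrate

from .errors import (
    ConfigurationError,
    DomainError,
    InputError,
    UndefinedMomentError,
)

FAMILIES = ("uniform", "power_standard", "cauchy_standard", "empirical")

_QUAD_ABS_TOL = 1e-10


# ---------------------------------------------------------------------------
# Density specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensitySpec:
    """One marginal distribution on a finite support ``[support_lo, support_hi]``.

    Parameters
    ----------
    family:
        ``uniform`` | ``power_standard`` | ``cauchy_standard`` | ``empirical``.
    support_lo, support_hi:
        Finite support endpoints (the stratification range R = hi − lo).
    location, scale:
        Cauchy location θ′ and scale t (defaults 0, 1 — the standard Cauchy).
    shape_delta, scale_theta:
        Power-distribution shape δ > 0 and scale θ > 0; density δx^{δ−1}/θ^δ
        on [0, θ].
    sample:
        Observed values (empirical family only), all inside the support.
    normalize:
        Renormalize mass so the support carries total mass 1. Only the
        truncated Cauchy is affected; uniform/empirical/θ-scaled power already
        integrate to 1.
    """

    family: str
    support_lo: float
    support_hi: float
    location: float = 0.0
    scale: float = 1.0
    shape_delta: Optional[float] = None
    scale_theta: Optional[float] = None
    sample: Optional[np.ndarray] = None
    normalize: bool = False
    _sorted: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _cum1: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _cum2: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not (self.support_lo < self.support_hi):
            raise ConfigurationError("support_lo must be < support_hi")
        if self.family == "power_standard":
            if self.shape_delta is None or self.shape_delta <= 0:
                raise ConfigurationError("power family needs shape_delta > 0")
            theta = 1.0 if self.scale_theta is None else self.scale_theta
            if theta <= 0:
                raise ConfigurationError("power family needs scale_theta > 0")
            object.__setattr__(self, "scale_theta", theta)
        if self.family == "cauchy_standard" and self.scale <= 0:
            raise ConfigurationError("Cauchy scale must be > 0")
        if self.family == "empirical":
            if self.sample is None or len(self.sample) == 0:
                raise ConfigurationError("empirical family needs a non-empty sample")
            xs = np.asarray(self.sample, dtype=float)
            if xs.min() < self.support_lo or xs.max() > self.support_hi:
                raise ConfigurationError("empirical sample outside declared support")
            srt = np.sort(xs)
            object.__setattr__(self, "sample", xs)
            object.__setattr__(self, "_sorted", srt)
            object.__setattr__(self, "_cum1", np.concatenate([[0.0], np.cumsum(srt)]))
            object.__setattr__(self, "_cum2", np.concatenate([[0.0], np.cumsum(srt**2)]))

    # -- basic quantities ---------------------------------------------------

    @property
    def range(self) -> float:
        return self.support_hi - self.support_lo

    def pdf(self, x):
        """Density at ``x`` (continuous families only), zero outside support."""
        x = np.asarray(x, dtype=float)
        inside = (x >= self.support_lo) & (x <= self.support_hi)
        if self.family == "uniform":
            f = np.full_like(x, 1.0 / self.range)
        elif self.family == "power_standard":
            d, th = self.shape_delta, self.scale_theta
            with np.errstate(invalid="ignore"):
                f = d * np.clip(x, 0.0, None) ** (d - 1.0) / th**d
        elif self.family == "cauchy_standard":
            u = (x - self.location) / self.scale
            f = 1.0 / (np.pi * self.scale * (1.0 + u * u))
        else:
            raise ConfigurationError("empirical family has no continuous pdf")
        f = np.where(inside, f, 0.0)
        if self.normalize:
            f = f / self._raw_mass(self.support_lo, self.support_hi)
        return f

    @property
    def total_mass(self) -> float:
        """Mass of the whole support (1 when normalized)."""
        return float(self.mass(self.support_lo, self.support_hi))

    # -- analytic raw integrals over [lo, hi] --------------------------------

    def _raw_mass(self, lo, hi):
        if self.family == "uniform":
            return (hi - lo) / self.range
        if self.family == "power_standard":
            d, th = self.shape_delta, self.scale_theta
            return (hi**d - lo**d) / th**d
        if self.family == "cauchy_standard":
            t, m = self.scale, self.location
            return (np.arctan((hi - m) / t) - np.arctan((lo - m) / t)) / np.pi
        # empirical: counting measure / N
        n = len(self._sorted)
        ilo = np.searchsorted(self._sorted, lo, side="left")
        # upper-closed on the final stratum of the axis
        side = np.where(np.asarray(hi) >= self.support_hi, 1, 0)
        ihi_l = np.searchsorted(self._sorted, hi, side="left")
        ihi_r = np.searchsorted(self._sorted, hi, side="right")
        ihi = np.where(side == 1, ihi_r, ihi_l)
        return (ihi - ilo) / n

    def _raw_moment(self, lo, hi, k: int):
        """∫ x^k f(x) dx over [lo, hi] (un-normalized density)."""
        if self.family == "uniform":
            return (hi ** (k + 1) - lo ** (k + 1)) / ((k + 1) * self.range)
        if self.family == "power_standard":
            d, th = self.shape_delta, self.scale_theta
            return d * (hi ** (d + k) - lo ** (d + k)) / ((d + k) * th**d)
        if self.family == "cauchy_standard":
            t, m = self.scale, self.location
            ul, uh = (lo - m) / t, (hi - m) / t
            mass = (np.arctan(uh) - np.arctan(ul)) / np.pi
            # ∫ u/(π(1+u²)) du = log(1+u²)/(2π); ∫ u²/(π(1+u²)) du = (u − arctan u)/π
            m1u = (np.log1p(uh * uh) - np.log1p(ul * ul)) / (2.0 * np.pi)
            if k == 1:
                return m * mass + t * m1u
            m2u = ((uh - np.arctan(uh)) - (ul - np.arctan(ul))) / np.pi
            return m * m * mass + 2.0 * m * t * m1u + t * t * m2u
        # empirical
        ilo = np.searchsorted(self._sorted, lo, side="left")
        side = np.asarray(hi) >= self.support_hi
        ihi = np.where(
            side,
            np.searchsorted(self._sorted, hi, side="right"),
            np.searchsorted(self._sorted, hi, side="left"),
        )
        cum = self._cum1 if k == 1 else self._cum2
        return (cum[ihi] - cum[ilo]) / len(self._sorted)

    # -- public vectorized moments -------------------------------------------

    def mass(self, lo, hi):
        """Probability mass of ``[lo, hi]`` (vectorized over array bounds)."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        w = np.where(hi > lo, self._raw_mass(lo, hi), 0.0)
        if self.normalize:
            w = w / self._raw_mass(self.support_lo, self.support_hi)
        return w

    def moments(self, lo, hi):
        """Return ``(weight, mean, variance)`` of the slice ``[lo, hi]``.

        Vectorized over array bounds. Zero-width or zero-mass slices get
        weight 0, mean at the midpoint and variance 0 so dynamic-programming
        sweeps can explore degenerate partitions safely.
        """
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        w = self.mass(lo, hi)
        pos = w > 0
        safe_w = np.where(pos, w, 1.0)
        norm = (
            self._raw_mass(self.support_lo, self.support_hi) if self.normalize else 1.0
        )
        m1 = self._raw_moment(lo, hi, 1) / norm
        m2 = self._raw_moment(lo, hi, 2) / norm
        mean = np.where(pos, m1 / safe_w, 0.5 * (lo + hi))
        var = np.where(pos, m2 / safe_w - mean * mean, 0.0)
        var = np.maximum(var, 0.0)  # guard cancellation on thin slices
        return w, mean, var

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values from the density restricted to its support.

        Inverse-CDF sampling for the parametric families (the restriction is
        renormalized for sampling purposes regardless of ``normalize``);
        resampling with replacement for the empirical family.
        """
        u = rng.random(n)
        if self.family == "uniform":
            return self.support_lo + u * self.range
        if self.family == "power_standard":
            d, th = self.shape_delta, self.scale_theta
            flo = (self.support_lo / th) ** d
            fhi = (self.support_hi / th) ** d
            return th * (flo + u * (fhi - flo)) ** (1.0 / d)
        if self.family == "cauchy_standard":
            t, m = self.scale, self.location
            plo = np.arctan((self.support_lo - m) / t)
            phi = np.arctan((self.support_hi - m) / t)
            return m + t * np.tan(plo + u * (phi - plo))
        return rng.choice(self._sorted, size=n, replace=True)

    # -- quadrature ground truth ---------------------------------------------

    def mass_quad(self, lo: float, hi: float) -> float:
        """Adaptive-quadrature mass of ``[lo, hi]`` (oracle path)."""
        if self.family == "empirical":
            return float(self.mass(lo, hi))
        if hi <= lo:
            return 0.0
        val, _ = integrate.quad(self.pdf, lo, hi, epsabs=_QUAD_ABS_TOL, limit=200)
        return val

    def moments_quad(self, lo: float, hi: float):
        """Adaptive-quadrature ``(weight, mean, variance)`` (oracle path)."""
        if self.family == "empirical":
            return tuple(float(v) for v in self.moments(lo, hi))
        w = self.mass_quad(lo, hi)
        if w <= 0:
            return 0.0, 0.5 * (lo + hi), 0.0
        m1, _ = integrate.quad(
            lambda x: x * self.pdf(x), lo, hi, epsabs=_QUAD_ABS_TOL, limit=200
        )
        m2, _ = integrate.quad(
            lambda x: x * x * self.pdf(x), lo, hi, epsabs=_QUAD_ABS_TOL, limit=200
        )
        mean = m1 / w
        return w, mean, max(m2 / w - mean * mean, 0.0)


def uniform_density(lo: float = 0.0, hi: float = 1.0) -> DensitySpec:
    return DensitySpec("uniform", lo, hi)


def power_density(delta: float, theta: float = 1.0) -> DensitySpec:
    """Standard power density δx^{δ−1}/θ^δ on its natural support [0, θ]."""
    return DensitySpec(
        "power_standard", 0.0, theta, shape_delta=delta, scale_theta=theta
    )


def cauchy_density(
    lo: float, hi: float, location: float = 0.0, scale: float = 1.0,
    normalize: bool = False,
) -> DensitySpec:
    """Standard(izable) Cauchy restricted to [lo, hi], unrenormalized by default."""
    return DensitySpec(
        "cauchy_standard", lo, hi, location=location, scale=scale, normalize=normalize
    )


def empirical_density(sample: Sequence[float]) -> DensitySpec:
    xs = np.asarray(sample, dtype=float)
    lo, hi = float(xs.min()), float(xs.max())
    if hi <= lo:  # constant sample: widen infinitesimally so support is valid
        hi = lo + max(abs(lo), 1.0) * 1e-12
    return DensitySpec("empirical", lo, hi, sample=xs)


# ---------------------------------------------------------------------------
# Bivariate designs and cells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BivariateDesign:
    """Two independent stratification axes (the joint density factorizes)."""

    axis1: DensitySpec
    axis2: DensitySpec
    independent: bool = True

    def __post_init__(self) -> None:
        if not self.independent:
            raise ConfigurationError("only independent axes are supported")

    def axis(self, which: int) -> DensitySpec:
        if which == 1:
            return self.axis1
        if which == 2:
            return self.axis2
        raise InputError("axis must be 1 or 2")


@dataclass(frozen=True)
class Cell:
    """One rectangular stratum [x1_lo, x1_hi] × [x2_lo, x2_hi]."""

    x1_lo: float
    x1_hi: float
    x2_lo: float
    x2_hi: float

    def __post_init__(self) -> None:
        if self.x1_hi < self.x1_lo or self.x2_hi < self.x2_lo:
            raise InputError("cell bounds must be ordered")

    @property
    def width1(self) -> float:
        return self.x1_hi - self.x1_lo

    @property
    def width2(self) -> float:
        return self.x2_hi - self.x2_lo


@dataclass(frozen=True)
class StratumMoments:
    """Weight and per-axis moments of one stratum cell.

    ``var_y`` is the model-implied study-variable variance (filled in by the
    superpopulation layer); ``n_units`` is the empirical cell count when the
    moments came from data.
    """

    weight: float
    mean1: float
    mean2: float
    var1: float
    var2: float
    var_y: float = 0.0
    n_units: Optional[int] = None


def _check_cell_in_support(design: BivariateDesign, cell: Cell) -> None:
    a1, a2 = design.axis1, design.axis2
    eps1 = 1e-12 * max(1.0, abs(a1.range))
    eps2 = 1e-12 * max(1.0, abs(a2.range))
    if cell.x1_lo < a1.support_lo - eps1 or cell.x1_hi > a1.support_hi + eps1:
        raise DomainError("cell outside axis-1 support")
    if cell.x2_lo < a2.support_lo - eps2 or cell.x2_hi > a2.support_hi + eps2:
        raise DomainError("cell outside axis-2 support")


# ---------------------------------------------------------------------------
# Cell-moment operations
# ---------------------------------------------------------------------------


def cell_weight(design: BivariateDesign, cell: Cell, method: str = "auto") -> float:
    """Mass W_hk = ∬ f(x1, x2) dx1 dx2 over the cell.

    With independent marginals this is the product of two one-dimensional
    masses; ``method="quadrature"`` forces nested adaptive quadrature per axis
    (the ground-truth path).
    """
    _check_cell_in_support(design, cell)
    if cell.width1 == 0.0 or cell.width2 == 0.0:
        return 0.0
    if method == "quadrature":
        return design.axis1.mass_quad(cell.x1_lo, cell.x1_hi) * design.axis2.mass_quad(
            cell.x2_lo, cell.x2_hi
        )
    return float(
        design.axis1.mass(cell.x1_lo, cell.x1_hi)
        * design.axis2.mass(cell.x2_lo, cell.x2_hi)
    )


def _axis_bounds(cell: Cell, axis: int):
    return (cell.x1_lo, cell.x1_hi) if axis == 1 else (cell.x2_lo, cell.x2_hi)


def cell_axis_mean(
    design: BivariateDesign, cell: Cell, axis: int, method: str = "auto"
) -> float:
    """Weight-normalized mean of one axis over the cell (μ_hk on that axis)."""
    _check_cell_in_support(design, cell)
    if cell_weight(design, cell) <= 0.0:
        raise UndefinedMomentError("mean undefined on a zero-weight cell")
    lo, hi = _axis_bounds(cell, axis)
    dens = design.axis(axis)
    if method == "quadrature":
        return dens.moments_quad(lo, hi)[1]
    return float(dens.moments(lo, hi)[1])


def cell_axis_variance(
    design: BivariateDesign, cell: Cell, axis: int, method: str = "auto"
) -> float:
    """Weight-normalized variance of one axis over the cell (σ²_hk on that axis)."""
    _check_cell_in_support(design, cell)
    if cell_weight(design, cell) <= 0.0:
        raise UndefinedMomentError("variance undefined on a zero-weight cell")
    lo, hi = _axis_bounds(cell, axis)
    dens = design.axis(axis)
    if method == "quadrature":
        return dens.moments_quad(lo, hi)[2]
    return float(dens.moments(lo, hi)[2])


def cell_moments(design: BivariateDesign, cell: Cell) -> StratumMoments:
    """All analytic moments of one cell bundled as :class:`StratumMoments`."""
    _check_cell_in_support(design, cell)
    w1, m1, v1 = (float(v) for v in design.axis1.moments(cell.x1_lo, cell.x1_hi))
    w2, m2, v2 = (float(v) for v in design.axis2.moments(cell.x2_lo, cell.x2_hi))
    return StratumMoments(weight=w1 * w2, mean1=m1, mean2=m2, var1=v1, var2=v2)


def closed_form_cauchy_power_weight(design: BivariateDesign, cell: Cell) -> float:
    """Closed-form cell weight for standard Cauchy × standard power.

    W_hk = P1·P2 / (π θ^δ) with P1 = arctan(x1_hi) − arctan(x1_lo) and
    P2 = x2_hi^δ − x2_lo^δ. Must agree with :func:`cell_weight` to 1e−10
    relative error (the Cauchy axis is not renormalized).
    """
    a1, a2 = design.axis1, design.axis2
    if a1.family != "cauchy_standard" or a2.family != "power_standard":
        raise ConfigurationError("closed form requires cauchy axis1 × power axis2")
    if a1.location != 0.0 or a1.scale != 1.0 or a1.normalize:
        raise ConfigurationError("closed form requires the *standard* Cauchy")
    _check_cell_in_support(design, cell)
    d, th = a2.shape_delta, a2.scale_theta
    p1 = np.arctan(cell.x1_hi) - np.arctan(cell.x1_lo)
    p2 = cell.x2_hi**d - cell.x2_lo**d
    return float(p1 * p2 / (np.pi * th**d))


def empirical_cell_moments(
    sample1: Sequence[float],
    sample2: Sequence[float],
    cell: Cell,
    population_size: Optional[int] = None,
    support1: Optional[tuple] = None,
    support2: Optional[tuple] = None,
) -> StratumMoments:
    """Design-based moments of one cell from a paired finite population.

    Membership intervals are half-open ``[lo, hi)``, upper-closed on the last
    stratum of an axis (a cell whose upper bound reaches the axis maximum), so
    every unit belongs to exactly one stratum of a partition. Variances use
    the N_hk − 1 divisor; cells with N_hk ≤ 1 contribute zero variance.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1 or len(x1) == 0:
        raise InputError("samples must be paired, non-empty and equal length")
    n_total = population_size if population_size is not None else len(x1)
    hi1 = support1[1] if support1 is not None else x1.max()
    hi2 = support2[1] if support2 is not None else x2.max()
    in1 = (x1 >= cell.x1_lo) & (
        (x1 < cell.x1_hi) | ((cell.x1_hi >= hi1) & (x1 <= cell.x1_hi))
    )
    in2 = (x2 >= cell.x2_lo) & (
        (x2 < cell.x2_hi) | ((cell.x2_hi >= hi2) & (x2 <= cell.x2_hi))
    )
    mask = in1 & in2
    nhk = int(mask.sum())
    if nhk == 0:
        return StratumMoments(
            weight=0.0,
            mean1=0.5 * (cell.x1_lo + cell.x1_hi),
            mean2=0.5 * (cell.x2_lo + cell.x2_hi),
            var1=0.0,
            var2=0.0,
            n_units=0,
        )
    s1, s2 = x1[mask], x2[mask]
    var1 = float(s1.var(ddof=1)) if nhk > 1 else 0.0
    var2 = float(s2.var(ddof=1)) if nhk > 1 else 0.0
    return StratumMoments(
        weight=nhk / n_total,
        mean1=float(s1.mean()),
        mean2=float(s2.mean()),
        var1=var1,
        var2=var2,
        n_units=nhk,
    )
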