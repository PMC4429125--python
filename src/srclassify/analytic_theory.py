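"""Closed-form accuracy of the spoiled, noisy perceptron.

The weighted sum S = Σᵢ wᵢUᵢ of i.i.d. uniform[0,1] inputs follows a
weighted Irwin–Hall-type density

    fₙ(s) = 1 / (Πᵢwᵢ · (n−1)!) · Σ_{J ⊆ {1..n}} (−1)^|J| ((s − Σ_{j∈J} wⱼ)₊)^{n−1}

supported on [0, W], W = Σᵢwᵢ.  Adding independent N(0, σ²) noise to
every input adds N(0, σ_new²) noise to the sum, σ_new² = σ²Σᵢwᵢ².  The
probability that the noisy sum falls on the same side of the spoiled
threshold T₂ as the clean sum falls of the unspoiled threshold T₁ —
the population analogue of the Monte-Carlo accuracy — is

    P = ½ [ 1 + ∫₀^{T₁} fₙ(x) erf((T₂−x)/(√2 σ_new)) dx
              − ∫_{T₁}^{W} fₙ(x) erf((T₂−x)/(√2 σ_new)) dx ].

At σ = 0 the erf degenerates to ±1 and P reduces to the noiseless
overlap 1 − |Fₙ(T₂) − Fₙ(T₁)| in terms of the CDF Fₙ.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import factorial
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from scipy.special import erf


class BoundaryOptimumWarning(UserWarning):
    """An optimizer's argmax landed on the boundary of the search range."""


@dataclass(frozen=True)
class WeightedSumPDF:
    """Density of Σ wᵢUᵢ for i.i.d. Uᵢ ~ uniform(0,1).

    Piecewise polynomial of degree n−1 with knots at the 2ⁿ subset sums
    of the weights.  ``normalizer`` is Wₙ = Πᵢwᵢ·(n−1)!.
    """

    weights: tuple[float, ...]
    support_max: float = field(init=False)
    normalizer: float = field(init=False)
    # inclusion–exclusion terms: subset-sum offsets with alternating signs
    _offsets: np.ndarray = field(init=False, repr=False)
    _signs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.weights)
        if len(w) == 0:
            raise ValueError("weight vector must be non-empty")
        if any(v <= 0 for v in w):
            raise ValueError(f"all weights must be positive, got {w}")
        object.__setattr__(self, "weights", w)
        n = len(w)
        object.__setattr__(self, "support_max", float(sum(w)))
        object.__setattr__(
            self, "normalizer", float(np.prod(w)) * factorial(n - 1)
        )
        offsets, signs = [], []
        for k in range(n + 1):
            for subset in itertools.combinations(w, k):
                offsets.append(sum(subset))
                signs.append((-1.0) ** k)
        object.__setattr__(self, "_offsets", np.asarray(offsets))
        object.__setattr__(self, "_signs", np.asarray(signs))

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def knots(self) -> np.ndarray:
        """Sorted subset sums where the density is non-smooth."""
        return np.unique(self._offsets)

    def pdf(self, s: np.ndarray | float) -> np.ndarray | float:
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        rel = np.clip(s_arr[:, None] - self._offsets[None, :], 0.0, None)
        vals = (self._signs[None, :] * rel ** (self.n - 1)).sum(axis=1)
        vals /= self.normalizer
        # the alternating sum telescopes to 0 outside [0, W]; clamp the
        # floating-point residue (and tiny negatives from cancellation)
        vals = np.where(
            (s_arr < 0) | (s_arr > self.support_max), 0.0, np.maximum(vals, 0.0)
        )
        return float(vals[0]) if np.isscalar(s) or np.ndim(s) == 0 else vals

    def cdf(self, s: np.ndarray | float) -> np.ndarray | float:
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        rel = np.clip(s_arr[:, None] - self._offsets[None, :], 0.0, None)
        vals = (self._signs[None, :] * rel**self.n).sum(axis=1)
        vals /= self.normalizer * self.n
        vals = np.clip(vals, 0.0, 1.0)
        vals = np.where(s_arr >= self.support_max, 1.0, vals)
        vals = np.where(s_arr <= 0.0, 0.0, vals)
        return float(vals[0]) if np.isscalar(s) or np.ndim(s) == 0 else vals

    @property
    def density(self) -> Callable[[np.ndarray | float], np.ndarray | float]:
        return self.pdf


@dataclass(frozen=True)
class NoiseTheory:
    """Combined noise on the weighted sum: N(0, σ_new²), σ_new = σ√Σwᵢ²."""

    sigma: float
    sigma_new: float

    def density(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.sigma_new == 0.0:
            raise ValueError("zero-noise limit has no density (point mass)")
        s = self.sigma_new
        return np.exp(-np.asarray(x, dtype=float) ** 2 / (2 * s**2)) / (
            s * np.sqrt(2 * np.pi)
        )


def weighted_sum_pdf(weights) -> WeightedSumPDF:
    """Density of the weighted sum of i.i.d. uniform(0,1) inputs.

    For n=2 with w₁<w₂ this is the trapezoidal density: rising s/(w₁w₂)
    on (0,w₁), flat 1/w₂ on (w₁,w₂), falling on (w₂,w₁+w₂); for equal
    weights it degenerates to the triangular density with peak 1/w.
    """
    return WeightedSumPDF(weights=tuple(np.atleast_1d(weights)))


def combined_noise(weights, sigma: float) -> NoiseTheory:
    """Fold per-input N(0, σ²) noise into one sum-level Gaussian."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    w = np.asarray(weights, dtype=float)
    return NoiseTheory(sigma=float(sigma), sigma_new=float(sigma * np.sqrt(np.sum(w**2))))


def _noiseless_accuracy(pdf: WeightedSumPDF, T1: float, T2: float) -> float:
    # erf((T2-x)/0+) -> sign(T2-x); the integrals collapse to CDF terms
    return 1.0 - abs(float(pdf.cdf(T2)) - float(pdf.cdf(T1)))


def total_accuracy(weights, T1: float, T2: float, sigma: float) -> float:
    """Population accuracy of the spoiled perceptron under input noise.

    Parameters
    ----------
    weights
        Positive input weights.
    T1, T2
        Unspoiled and spoiled thresholds; T1 must lie strictly inside
        the weighted-sum support (0, Σwᵢ).
    sigma
        Per-input noise standard deviation (σ, not σ²).

    σ=0 is evaluated as the exact indicator limit rather than through
    the erf, avoiding a 0/0.  For σ>0 the two erf integrals are done by
    adaptive quadrature split at the density's knots and at T₂, where
    the integrand is non-smooth.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    pdf = weighted_sum_pdf(weights)
    W = pdf.support_max
    if not (0.0 < T1 < W):
        raise ValueError(f"T1={T1} must lie in (0, {W})")
    if sigma == 0.0:
        return _noiseless_accuracy(pdf, T1, T2)

    sigma_new = combined_noise(weights, sigma).sigma_new
    scale = np.sqrt(2.0) * sigma_new

    def integrand(x: float) -> float:
        return float(pdf.pdf(x)) * float(erf((T2 - x) / scale))

    def integrate(a: float, b: float) -> float:
        pts = [p for p in list(pdf.knots) + [T2] if a < p < b]
        val, _ = quad(integrand, a, b, points=sorted(pts) or None,
                      epsabs=1e-8, limit=200)
        return val

    I1 = integrate(0.0, T1)
    I2 = integrate(T1, W)
    return float(np.clip(0.5 * (1.0 + I1 - I2), 0.0, 1.0))


@dataclass(frozen=True)
class ThresholdScanResult:
    """Accuracy-vs-spoiled-threshold curve with its refined argmax."""

    table: pd.DataFrame
    t2_opt: float
    accuracy_opt: float


def _golden_refine(fun, lo: float, hi: float, tol: float = 1e-4):
    """Bounded scalar maximization of ``fun`` on [lo, hi]."""
    res = minimize_scalar(
        lambda v: -fun(v), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    return float(res.x), float(-res.fun)


def accuracy_vs_threshold(
    weights, T1: float, sigma: float, T2_grid
) -> ThresholdScanResult:
    """Accuracy as a function of the spoiled threshold T₂ at fixed σ.

    Evaluates P(T₂; σ) on the grid and refines the maximizing T₂ by
    bounded scalar search around the best grid point.  At σ=0
    the maximum sits exactly at T₂ = T₁ (the unspoiled classifier is
    perfect); with increasing noise it moves to larger T₂.
    """
    T2_grid = np.sort(np.asarray(T2_grid, dtype=float))
    W = float(np.sum(np.asarray(weights, dtype=float)))
    if T2_grid[0] <= 0 or T2_grid[-1] >= W:
        raise ValueError(f"T2 grid must lie inside (0, {W})")
    acc = np.array([total_accuracy(weights, T1, t2, sigma) for t2 in T2_grid])
    table = pd.DataFrame({"T2": T2_grid, "accuracy": acc})
    i = int(np.argmax(acc))
    lo = T2_grid[max(i - 1, 0)]
    hi = T2_grid[min(i + 1, len(T2_grid) - 1)]
    if lo == hi:
        t2_opt, acc_opt = float(T2_grid[i]), float(acc[i])
    else:
        t2_opt, acc_opt = _golden_refine(
            lambda t2: total_accuracy(weights, T1, t2, sigma), lo, hi
        )
        if acc[i] > acc_opt:  # boundary maximum the bracketed search missed
            t2_opt, acc_opt = float(T2_grid[i]), float(acc[i])
    return ThresholdScanResult(table=table, t2_opt=t2_opt, accuracy_opt=acc_opt)


@dataclass(frozen=True)
class NoiseOptimum:
    """Noise intensity σ²* that maximizes accuracy, and the value there."""

    sigma2_opt: float
    accuracy_opt: float
    table: pd.DataFrame


def optimal_noise(
    weights, T1: float, T2: float, sigma2_range: tuple[float, float],
    grid_points: int = 101,
) -> NoiseOptimum:
    """Noise variance maximizing accuracy for a fixed spoiling T₂.

    Coarse deterministic grid (``grid_points`` points over the range)
    followed by bounded scalar refinement around the best grid point.  For an unspoiled classifier (T₂=T₁) the optimum is σ²=0:
    accuracy there is exactly 1 and noise can only hurt.
    """
    lo, hi = float(sigma2_range[0]), float(sigma2_range[1])
    if not (0.0 <= lo < hi):
        raise ValueError("sigma2_range must satisfy 0 <= lo < hi")
    grid = np.linspace(lo, hi, grid_points)
    acc = np.array(
        [total_accuracy(weights, T1, T2, np.sqrt(s2)) for s2 in grid]
    )
    table = pd.DataFrame({"sigma2": grid, "accuracy": acc})
    i = int(np.argmax(acc))
    glo = grid[max(i - 1, 0)]
    ghi = grid[min(i + 1, len(grid) - 1)]
    s2_opt, acc_opt = _golden_refine(
        lambda s2: total_accuracy(weights, T1, T2, np.sqrt(max(s2, 0.0))),
        glo, ghi, tol=1e-6,
    )
    if acc[i] > acc_opt:  # boundary maximum the bracketed search missed
        s2_opt, acc_opt = float(grid[i]), float(acc[i])
    span = hi - lo
    if s2_opt - lo < 1e-3 * span or hi - s2_opt < 1e-3 * span:
        warnings.warn(
            f"optimal noise sigma2={s2_opt:.4g} lies on the boundary of the "
            f"search range [{lo}, {hi}]",
            BoundaryOptimumWarning,
            stacklevel=2,
        )
    return NoiseOptimum(sigma2_opt=s2_opt, accuracy_opt=acc_opt, table=table)
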