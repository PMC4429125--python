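"""Linear threshold classifiers under extrinsic input noise.

A perceptron computes the weighted sum x̄ = Σᵢ wᵢxᵢ of its inputs and
outputs 1 iff x̄ exceeds a threshold T (ties go to 0).  A *spoiled*
perceptron uses a deliberately shifted threshold T₂ ≠ T₁, which
misclassifies points near the separating hyperplane in the absence of
noise.  The accuracy statistic compares the clean, unspoiled
classification O(i) of a uniform random test set against the noisy,
spoiled classification D(i) of the same inputs:

    accuracy = (|{i: O=D=1}| + |{i: O=D=0}|) / N

Noise is additive, zero-mean Gaussian on each input coordinate and is
deliberately *not* clipped to [0,1], so that the Gaussian closed-form
theory in :mod:`srclassify.analytic_theory` applies exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClassifierSpec:
    """Weights and (unspoiled, spoiled) thresholds of a perceptron.

    Parameters
    ----------
    w
        Positive weight vector (w₁..wₙ).
    T1
        Unspoiled (reference) threshold.
    T2
        Spoiled threshold actually used on noisy inputs.  Equal to ``T1``
        for an unspoiled classifier.
    """

    w: tuple[float, ...]
    T1: float
    T2: float

    def __post_init__(self) -> None:
        w = tuple(float(v) for v in self.w)
        object.__setattr__(self, "w", w)
        if len(w) == 0:
            raise ValueError("weight vector must be non-empty")
        if any(v <= 0 for v in w):
            raise ValueError(f"all weights must be positive, got {w}")
        wsum = sum(w)
        if not (0.0 < self.T1 < wsum):
            raise ValueError(
                f"T1={self.T1} must lie in (0, sum(w)={wsum}) for a "
                "non-degenerate classifier"
            )

    @property
    def n(self) -> int:
        """Input dimension."""
        return len(self.w)

    @property
    def w_array(self) -> np.ndarray:
        return np.asarray(self.w, dtype=float)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian input noise: mean 0, variance ``sigma2``."""

    sigma2: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be non-negative, got {self.sigma2}")


@dataclass(frozen=True)
class AccuracyResult:
    """Outcome of one Monte-Carlo accuracy estimate.

    ``O`` are the clean/unspoiled outputs, ``D`` the noisy/spoiled ones;
    ``n_pos``/``n_neg`` count the inputs on which both agree with value
    1 resp. 0, so ``accuracy = (n_pos + n_neg) / N`` exactly.
    """

    O: np.ndarray
    D: np.ndarray
    n_pos: int
    n_neg: int
    accuracy: float
    N: int


def weighted_sum(x: np.ndarray, w: np.ndarray) -> np.ndarray | float:
    """Weighted sum Σᵢ xᵢwᵢ of inputs against weights.

    ``x`` may be a single vector of length n or an (N, n) matrix; the
    latter returns one sum per row.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(
            f"input dimension {x.shape[-1]} does not match weight dimension "
            f"{w.shape[0]}"
        )
    s = x @ w
    return float(s) if s.ndim == 0 else s


def threshold_classify(xbar: np.ndarray | float, T: float) -> np.ndarray | int:
    """Binary threshold decision: 1 if x̄ > T, else 0 (ties map to 0)."""
    out = (np.asarray(xbar, dtype=float) > T).astype(np.int8)
    return int(out) if out.ndim == 0 else out


def normalize_threshold(spec: ClassifierSpec) -> ClassifierSpec:
    """Rescale weights so that the unspoiled threshold becomes 1.

    Division of w and both thresholds by T₁ leaves every classification
    decision unchanged (scale invariance of the threshold rule).
    """
    if spec.T1 <= 0:
        raise ValueError("T1 must be positive to normalize")
    scale = spec.T1
    return replace(
        spec,
        w=tuple(v / scale for v in spec.w),
        T1=1.0,
        T2=spec.T2 / scale,
    )


def sample_inputs(N: int, n: int, seed: int) -> np.ndarray:
    """Draw an (N, n) matrix of i.i.d. uniform[0,1] classifier inputs."""
    if N < 1 or n < 1:
        raise ValueError("N and n must be positive")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(N, n))


def perturb_inputs(x: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    """Add i.i.d. N(0, σ²) deviates to every entry of ``x``.

    Values are *not* clipped to [0,1]: the perceptron path keeps the
    exact Gaussian picture that the analytic theory assumes.  σ²=0
    returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if noise.sigma2 == 0.0:
        return x.copy()
    rng = np.random.default_rng(noise.seed)
    return x + rng.normal(0.0, np.sqrt(noise.sigma2), size=x.shape)


def accuracy_from_outputs(O: np.ndarray, D: np.ndarray) -> AccuracyResult:
    """Compile clean/unspoiled vs noisy/spoiled outputs into an accuracy.

    T⁺ = {i: O(i)=D(i)=1}, T⁻ = {i: O(i)=D(i)=0},
    accuracy = (|T⁺|+|T⁻|)/N.
    """
    O = np.asarray(O, dtype=np.int8)
    D = np.asarray(D, dtype=np.int8)
    if O.shape != D.shape:
        raise ValueError("output vectors must have equal length")
    n_pos = int(np.sum((O == 1) & (D == 1)))
    n_neg = int(np.sum((O == 0) & (D == 0)))
    N = O.size
    return AccuracyResult(
        O=O, D=D, n_pos=n_pos, n_neg=n_neg, accuracy=(n_pos + n_neg) / N, N=N
    )


def mc_accuracy(
    spec: ClassifierSpec, noise: NoiseSpec, N: int, seed: int
) -> AccuracyResult:
    """Monte-Carlo accuracy of the spoiled, noisy classifier.

    Samples ``N`` uniform input vectors (from ``seed``); O(i) classifies
    the clean inputs against T₁, D(i) classifies the noise-perturbed
    inputs (from ``noise.seed``) against T₂.
    """
    if N < 1:
        raise ValueError("N must be positive")
    x = sample_inputs(N, spec.n, seed)
    w = spec.w_array
    O = threshold_classify(weighted_sum(x, w), spec.T1)
    D = threshold_classify(weighted_sum(perturb_inputs(x, noise), w), spec.T2)
    return accuracy_from_outputs(O, D)


def sr_scan(
    spec: ClassifierSpec,
    sigma2_grid: np.ndarray,
    N: int,
    seed: int,
) -> pd.DataFrame:
    """Accuracy as a function of noise intensity σ² (paired design).

    One common clean input sample is reused at every grid point; the
    Gaussian noise is redrawn per σ² from independent child seeds.  The
    pairing removes input-sampling variance from the *shape* of the
    accuracy-vs-noise curve, which is what the stochastic-resonance
    statements are about.

    Returns a DataFrame with columns ``sigma2``, ``accuracy``, ``n``.
    """
    sigma2_grid = np.asarray(sigma2_grid, dtype=float)
    if np.any(sigma2_grid < 0):
        raise ValueError("noise variances must be non-negative")
    x = sample_inputs(N, spec.n, seed)
    w = spec.w_array
    O = threshold_classify(weighted_sum(x, w), spec.T1)
    child_seeds = np.random.SeedSequence(seed).spawn(len(sigma2_grid))
    rows = []
    for sigma2, child in zip(sigma2_grid, child_seeds):
        rng = np.random.default_rng(child)
        if sigma2 == 0.0:
            xn = x
        else:
            xn = x + rng.normal(0.0, np.sqrt(sigma2), size=x.shape)
        D = threshold_classify(weighted_sum(xn, w), spec.T2)
        res = accuracy_from_outputs(O, D)
        rows.append({"sigma2": float(sigma2), "accuracy": res.accuracy, "n": N})
    return pd.DataFrame(rows)
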