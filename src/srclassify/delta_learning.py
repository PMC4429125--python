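"""Delta-rule learning of perceptron weights through a noisy, spoiled unit.

A teacher perceptron with the true weights w and unspoiled threshold T
labels a fixed training set of clean uniform inputs.  The learner
observes *noise-perturbed* copies of those inputs (fresh Gaussian noise
at every presentation), classifies them against a spoiled threshold T₂
with its current weights, and nudges the weights by the delta rule

    wᵢ ← wᵢ + α (target − prediction) xᵢ

where xᵢ is the input the learner actually observed (the noisy one).
Performance is measured as the Euclidean distance of the learned
weights from the true ones.

*Learning resonance*: against a spoiled threshold, an intermediate
input-noise intensity minimizes that weight error.  At zero noise the
spoiled boundary pulls the stationary weights up to (T₂/T)·w; the
correlation between the noise and the resulting prediction errors
shrinks the weights back, and at an intermediate σ² the two biases
cancel; far beyond it the noise swamps the signal and the error rises
again.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LearningConfig:
    """Hyperparameters of one delta-rule training run.

    ``error_threshold`` applies to the mean absolute per-pass delta;
    with 0/1 targets it stops training on the first error-free pass.
    """

    alpha: float = 0.01
    T_unspoiled: float = 1.0
    T_spoiled: float = 1.0
    error_threshold: float = 0.001
    max_passes: int = 2000
    train_size: int = 100
    sigma2: float = 0.0
    seed: int = 0
    init_weights: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.max_passes < 1:
            raise ValueError("max_passes must be at least 1")
        if self.train_size < 1:
            raise ValueError("train_size must be at least 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass(frozen=True)
class LearningResult:
    """Learned weights with the error trace of one training run."""

    w_learned: np.ndarray
    weight_error: float
    passes_used: int
    error_history: np.ndarray


def delta_update(
    w: np.ndarray, x: np.ndarray, target: int, prediction: int, alpha: float
) -> np.ndarray:
    """One delta-rule step: w + α(target − prediction)·x."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weight and input vectors must have equal length")
    return w + alpha * (float(target) - float(prediction)) * x


def weight_error(w_true: np.ndarray, w_learned: np.ndarray) -> float:
    """Euclidean distance √Σ(wᵢ − wᵢ,new)² between weight vectors."""
    w_true = np.asarray(w_true, dtype=float)
    w_learned = np.asarray(w_learned, dtype=float)
    if w_true.shape != w_learned.shape:
        raise ValueError("weight vectors must have equal length")
    return float(np.linalg.norm(w_true - w_learned))


def _train_batch(
    true_weights: np.ndarray,
    config: LearningConfig,
    sigma2s: np.ndarray,
    rng: np.random.Generator,
    training_inputs: np.ndarray | None = None,
):
    """Vectorized delta-rule training of many independent runs.

    Each batch element has its own training set, noise stream and weight
    trajectory; runs that reach the stopping error freeze their weights
    while the rest continue.  Returns (w (B,n), passes_used (B,),
    error_history (B, max_passes) with NaN beyond each run's stop).
    """
    true_weights = np.asarray(true_weights, dtype=float)
    n = true_weights.size
    B = sigma2s.size
    sigma = np.sqrt(sigma2s)[:, None]

    if training_inputs is None:
        X = rng.uniform(0.0, 1.0, size=(B, config.train_size, n))
    else:
        X = np.broadcast_to(
            np.asarray(training_inputs, dtype=float), (B,) + np.shape(
                training_inputs
            )
        ).copy()
        if X.shape[1] != config.train_size:
            raise ValueError("training_inputs must match config.train_size")
    targets = (
        np.einsum("bjn,n->bj", X, true_weights) > config.T_unspoiled
    ).astype(float)

    w = np.tile(np.asarray(config.init_weights, dtype=float), (B, 1))
    if w.shape[1] != n:
        raise ValueError("init_weights length must match true_weights")
    active = np.ones(B, dtype=bool)
    passes_used = np.full(B, config.max_passes, dtype=int)
    history = np.full((B, config.max_passes), np.nan)

    for pss in range(config.max_passes):
        noise = rng.standard_normal((config.train_size, B, n))
        abs_delta = np.zeros(B)
        for j in range(config.train_size):
            x = X[:, j, :]
            x_seen = x + sigma * noise[j]
            pred = (np.einsum("bn,bn->b", x_seen, w) > config.T_spoiled)
            delta = targets[:, j] - pred
            # the observed (noisy) input multiplies the update; frozen
            # runs get delta 0
            w += config.alpha * np.where(active, delta, 0.0)[:, None] * x_seen
            abs_delta += np.abs(delta)
        mean_abs = abs_delta / config.train_size
        history[active, pss] = mean_abs[active]
        stopping = active & (mean_abs < config.error_threshold)
        passes_used[stopping] = pss + 1
        active &= ~stopping
        if not active.any():
            break
    return w, passes_used, history


def train(
    true_weights,
    config: LearningConfig,
    training_inputs: np.ndarray | None = None,
) -> LearningResult:
    """Run one delta-rule training loop against the noisy spoiled unit.

    The training set (``config.train_size`` uniform inputs) and every
    noise draw derive from ``config.seed``, so identical configs give
    identical results; ``training_inputs`` (shape ``(train_size, n)``)
    overrides the generated set.  Non-convergence is a valid outcome,
    reported via ``passes_used == max_passes``.
    """
    true_weights = np.asarray(true_weights, dtype=float)
    rng = np.random.default_rng(config.seed)
    w, passes, history = _train_batch(
        true_weights, config, np.asarray([config.sigma2]), rng,
        training_inputs=training_inputs,
    )
    hist = history[0]
    hist = hist[~np.isnan(hist)]
    return LearningResult(
        w_learned=w[0],
        weight_error=weight_error(true_weights, w[0]),
        passes_used=int(passes[0]),
        error_history=hist,
    )


@dataclass(frozen=True)
class ResonanceScanResult:
    """Mean weight error per noise intensity and the minimizing σ²."""

    table: pd.DataFrame
    sigma2_opt: float
    min_error: float


def learning_resonance_scan(
    true_weights,
    base_config: LearningConfig,
    sigma2_grid,
    replicates: int = 20,
) -> ResonanceScanResult:
    """Scan the learned-weight error over input-noise intensities.

    Runs ``replicates`` independent training runs (fresh training set
    and noise per run, all derived from ``base_config.seed``) at every
    σ² grid value and reports the mean and standard error of the
    Euclidean weight error, plus the grid σ² minimizing the mean.

    Returns a :class:`ResonanceScanResult` whose table has columns
    ``sigma2``, ``mean_error``, ``se_error``, ``n``.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    true_weights = np.asarray(true_weights, dtype=float)
    grid = np.asarray(sigma2_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("noise variances must be non-negative")
    sigma2s = np.repeat(grid, replicates)
    rng = np.random.default_rng(base_config.seed)
    w, _, _ = _train_batch(true_weights, base_config, sigma2s, rng)
    errors = np.linalg.norm(w - true_weights[None, :], axis=1)
    errors = errors.reshape(len(grid), replicates)
    mean = errors.mean(axis=1)
    se = errors.std(axis=1, ddof=1) / np.sqrt(replicates) if replicates > 1 \
        else np.zeros(len(grid))
    table = pd.DataFrame(
        {"sigma2": grid, "mean_error": mean, "se_error": se,
         "n": replicates}
    )
    i = int(np.argmin(mean))
    return ResonanceScanResult(
        table=table, sigma2_opt=float(grid[i]), min_error=float(mean[i])
    )
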