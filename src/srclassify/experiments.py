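"""Reproducible experiment drivers with CSV/JSON output.

Each driver reruns one result surface — a stochastic-resonance scan, an
analytic/Monte-Carlo comparison, a threshold scan, the spoiled-vs-
unspoiled crossover, the learning-resonance scan, or the GRN/perceptron
agreement map — from a seed and a parameter map, and writes a CSV curve
plus a JSON metadata sidecar so that every output file can be
regenerated from its own metadata.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from srclassify import analytic_theory, delta_learning, grn_circuit, perceptron
from srclassify.grn_circuit import (
    BoundaryFit,
    DegenerateClassifierWarning,
    GRNTopology,
    IntegrationSettings,
)
from srclassify.perceptron import ClassifierSpec

EXPERIMENT_IDS = (
    "sr_grn",
    "sr_perceptron",
    "analytic_match",
    "threshold_scan",
    "crossover",
    "learning_resonance",
    "grn_agreement",
)


class ConfigError(ValueError):
    """An experiment configuration is malformed."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Dispatchable experiment description (id, parameters, seed, output)."""

    experiment_id: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    output_path: str | Path = "experiment.csv"

    def __post_init__(self) -> None:
        if self.experiment_id not in EXPERIMENT_IDS:
            raise ConfigError(
                f"unknown experiment_id {self.experiment_id!r}; expected one "
                f"of {EXPERIMENT_IDS}"
            )


def _require(params: dict, *keys):
    for key in keys:
        if key not in params:
            raise ConfigError(f"missing required parameter {key!r}")
    return [params[k] for k in keys]


@dataclass(frozen=True)
class CrossoverResult:
    """Per-spoiling accuracy curves and crossover noise intensities.

    ``crossovers`` maps each spoiled threshold to the smallest grid σ²
    from which its curve dominates the unspoiled curve for the rest of
    the grid (None if it never does).  Dominance-to-the-end, rather than
    a single crossing, keeps the detection robust to Monte-Carlo jitter.
    """

    curves: pd.DataFrame
    crossovers: dict


def run_crossover(
    weights,
    T1: float,
    spoilings,
    sigma2_grid,
    N: int = 10000,
    seed: int = 0,
) -> CrossoverResult:
    """Compare spoiled against unspoiled accuracy over a noise grid.

    Fully paired design: one clean input sample and one noisy copy per
    σ² are shared by *all* spoiled thresholds, so curve differences
    reflect only the threshold change.
    """
    w = np.asarray(weights, dtype=float)
    spoilings = [float(s) for s in np.atleast_1d(spoilings)]
    grid = np.asarray(sigma2_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sigma2_grid must be strictly increasing")
    if T1 not in spoilings:
        raise ValueError("spoilings must include the unspoiled value T1")
    x = perceptron.sample_inputs(N, w.size, seed)
    O = perceptron.threshold_classify(x @ w, T1)
    child_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    acc = {t2: np.empty(len(grid)) for t2 in spoilings}
    for gi, (sigma2, child) in enumerate(zip(grid, child_seeds)):
        rng = np.random.default_rng(child)
        xn = x if sigma2 == 0 else x + rng.normal(
            0.0, np.sqrt(sigma2), size=x.shape
        )
        sn = xn @ w
        for t2 in spoilings:
            D = perceptron.threshold_classify(sn, t2)
            a = perceptron.accuracy_from_outputs(O, D).accuracy
            acc[t2][gi] = a
            rows.append(
                {"sigma2": float(sigma2), "spoiling": t2, "accuracy": a,
                 "n": N}
            )
    unspoiled = acc[T1]
    crossovers = {}
    for t2 in spoilings:
        if t2 == T1:
            crossovers[t2] = float(grid[0])
            continue
        dominated = acc[t2] >= unspoiled
        cross = None
        for gi in range(len(grid)):
            if dominated[gi:].all():
                cross = float(grid[gi])
                break
        crossovers[t2] = cross
    return CrossoverResult(curves=pd.DataFrame(rows), crossovers=crossovers)


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between circuit and linear-rule classification."""

    fraction_overall: float
    fraction_outside_band: float
    band_width: float
    n_grid: int
    n_outside_band: int
    disagreement: pd.DataFrame  # grid points where the two disagree


def grn_perceptron_agreement(
    topology: GRNTopology,
    boundary: BoundaryFit,
    threshold_expression: float,
    grid_resolution: int = 50,
    band_width: float = 0.05,
    settings: IntegrationSettings | None = None,
) -> AgreementResult:
    """Fraction of an input grid where the circuit matches the linear rule.

    The linear rule is [w₁x₁ + w₂x₂ > T_eff] with T_eff taken from the
    calibrated ``boundary`` (run :func:`~srclassify.grn_circuit.
    empirical_boundary` first).  Agreement is reported overall and
    excluding a band of perpendicular width ``band_width`` around the
    separating line, where integration-time and grid effects dominate.
    """
    if boundary is None:
        raise ValueError(
            "topology is not calibrated: run empirical_boundary first and "
            "pass its BoundaryFit"
        )
    w1, w2 = topology.input_weights
    g = np.linspace(0.0, 1.0, grid_resolution)
    X1, X2 = np.meshgrid(g, g, indexing="ij")
    out, _, _ = grn_circuit.classify_grid(
        topology, X1.ravel(), X2.ravel(), threshold_expression, settings
    )
    s = w1 * X1.ravel() + w2 * X2.ravel()
    if boundary.is_degenerate:
        warnings.warn(
            "degenerate circuit classification: comparing against the "
            "constant classifier",
            DegenerateClassifierWarning,
            stacklevel=2,
        )
        constant = int(np.round(out.mean()))
        linear = np.full_like(out, constant)
        dist = np.full(out.shape, np.inf)
    else:
        linear = (s > boundary.t_eff).astype(np.int8)
        dist = np.abs(s - boundary.t_eff) / np.hypot(w1, w2)
    agree = out == linear
    outside = dist > band_width
    mask = ~agree
    disagreement = pd.DataFrame(
        {
            "x1": X1.ravel()[mask],
            "x2": X2.ravel()[mask],
            "grn": out[mask],
            "linear": linear[mask],
        }
    )
    return AgreementResult(
        fraction_overall=float(agree.mean()),
        fraction_outside_band=float(agree[outside].mean())
        if outside.any() else 1.0,
        band_width=band_width,
        n_grid=out.size,
        n_outside_band=int(outside.sum()),
        disagreement=disagreement,
    )


def _sr_grn_scan(params: dict, seed: int) -> pd.DataFrame:
    """Stochastic resonance in the circuit itself.

    Clean inputs are classified by the circuit at the unspoiled
    threshold-gene expression; the same inputs plus Gaussian noise
    (clipped to [0,1] — concentrations cannot leave the physical range)
    are classified at the spoiled expression.
    """
    w1, w2, expr, spoiled_expr, grid, N = _require(
        params, "w1", "w2", "threshold_expression",
        "spoiled_expression", "sigma2_grid", "n_samples",
    )
    topology = grn_circuit.build_toggle_classifier(w1, w2)
    settings = params.get("settings") or IntegrationSettings()
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(N, 2))
    O, done, _ = grn_circuit.classify_grid(
        topology, x[:, 0], x[:, 1], expr, settings
    )
    rows = []
    for sigma2 in np.asarray(grid, dtype=float):
        xn = x if sigma2 == 0 else np.clip(
            x + rng.normal(0.0, np.sqrt(sigma2), size=x.shape), 0.0, 1.0
        )
        D, _, _ = grn_circuit.classify_grid(
            topology, xn[:, 0], xn[:, 1], spoiled_expr, settings
        )
        res = perceptron.accuracy_from_outputs(O, D)
        rows.append({"sigma2": float(sigma2), "accuracy": res.accuracy,
                     "n": int(N)})
    return pd.DataFrame(rows)


def _dispatch(config: ExperimentConfig) -> pd.DataFrame:
    p = dict(config.parameters)
    seed = config.seed
    if config.experiment_id == "sr_perceptron":
        w, t1, t2, grid, N = _require(
            p, "weights", "t1", "t2", "sigma2_grid", "n_samples"
        )
        spec = ClassifierSpec(w=tuple(w), T1=t1, T2=t2)
        return perceptron.sr_scan(spec, np.asarray(grid, float), N, seed)
    if config.experiment_id == "analytic_match":
        w, t1, t2, grid, N = _require(
            p, "weights", "t1", "t2", "sigma2_grid", "n_samples"
        )
        spec = ClassifierSpec(w=tuple(w), T1=t1, T2=t2)
        mc = perceptron.sr_scan(spec, np.asarray(grid, float), N, seed)
        mc["analytic"] = [
            analytic_theory.total_accuracy(w, t1, t2, float(np.sqrt(s2)))
            for s2 in mc["sigma2"]
        ]
        return mc
    if config.experiment_id == "threshold_scan":
        w, t1, sigma2, grid = _require(p, "weights", "t1", "sigma2", "t2_grid")
        res = analytic_theory.accuracy_vs_threshold(
            w, t1, float(np.sqrt(sigma2)), np.asarray(grid, float)
        )
        table = res.table.copy()
        table.attrs["t2_opt"] = res.t2_opt
        table.attrs["accuracy_opt"] = res.accuracy_opt
        return table
    if config.experiment_id == "crossover":
        w, t1, spoilings, grid, N = _require(
            p, "weights", "t1", "spoilings", "sigma2_grid", "n_samples"
        )
        res = run_crossover(w, t1, spoilings, np.asarray(grid, float), N, seed)
        table = res.curves.copy()
        table.attrs["crossovers"] = {
            str(k): v for k, v in res.crossovers.items()
        }
        return table
    if config.experiment_id == "learning_resonance":
        w, t2, grid, reps = _require(
            p, "true_weights", "t_spoiled", "sigma2_grid", "replicates"
        )
        cfg = delta_learning.LearningConfig(
            alpha=p.get("alpha", 0.01),
            T_unspoiled=p.get("t_unspoiled", 1.0),
            T_spoiled=t2,
            max_passes=p.get("max_passes", 2000),
            train_size=p.get("train_size", 100),
            seed=seed,
        )
        res = delta_learning.learning_resonance_scan(
            w, cfg, np.asarray(grid, float), reps
        )
        table = res.table.copy()
        table.attrs["sigma2_opt"] = res.sigma2_opt
        table.attrs["min_error"] = res.min_error
        return table
    if config.experiment_id == "grn_agreement":
        w1, w2, expr, resolution = _require(
            p, "w1", "w2", "threshold_expression", "grid_resolution"
        )
        topology = grn_circuit.build_toggle_classifier(w1, w2)
        settings = p.get("settings") or IntegrationSettings()
        boundary = grn_circuit.empirical_boundary(
            topology, expr, resolution, settings
        )
        res = grn_perceptron_agreement(
            topology, boundary, expr, resolution,
            p.get("band_width", 0.05), settings,
        )
        table = pd.DataFrame(
            [{
                "fraction_overall": res.fraction_overall,
                "fraction_outside_band": res.fraction_outside_band,
                "band_width": res.band_width,
                "n_grid": res.n_grid,
                "t_eff": boundary.t_eff,
                "slope": boundary.slope,
                "intercept": boundary.intercept,
            }]
        )
        return table
    if config.experiment_id == "sr_grn":
        return _sr_grn_scan(p, seed)
    raise ConfigError(f"unknown experiment_id {config.experiment_id!r}")


def run_experiment(config: ExperimentConfig) -> Path:
    """Run one experiment and write its CSV plus a JSON metadata sidecar.

    The sidecar records the experiment id, seed, full parameter map and
    package version; re-running from that metadata reproduces the CSV
    byte for byte.  Returns the CSV path.
    """
    t0 = time.perf_counter()
    table = _dispatch(config)
    out = Path(config.output_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    meta = {
        "experiment_id": config.experiment_id,
        "seed": config.seed,
        "parameters": _jsonable(config.parameters),
        "derived": _jsonable(dict(table.attrs)),
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "n_rows": int(len(table)),
    }
    try:
        from srclassify import __version__
        meta["version"] = __version__
    except ImportError:  # pragma: no cover
        pass
    out.with_suffix(out.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, IntegrationSettings):
        return vars(obj).copy() if not hasattr(obj, "__dataclass_fields__") \
            else {k: _jsonable(getattr(obj, k))
                  for k in obj.__dataclass_fields__}
    return obj
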