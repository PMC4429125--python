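"""Five-node toggle-switch circuit performing linear classification.

The circuit couples a bistable toggle switch (output gene 3 and its
partner gene 4, mutually repressing and weakly self-promoting) to two
input genes (1, 2) and a constitutively expressed threshold gene (0).
The inputs activate the output gene with strengths w₁, w₂ and repress
the partner with the same strengths; the threshold gene does the
opposite, so its expression level sets where the separating line
w₁x₁ + w₂x₂ = T_eff sits in the input plane.

Per node i, mRNA m(i) and protein p(i) follow

    dm(i)/dt = γ (f(Σⱼ Aⱼᵢ p(j) − θᵢ) − m(i)),   dp(i)/dt = m(i) − p(i)

with the steep sigmoid f(x) = 1/(1+e^{−βx}) (β = 40 by default).  Since
f ∈ (0,1), the hypercube [0,1]¹⁰ is forward-invariant: concentrations
(relative to their maxima) never leave [0,1].

Inputs are delivered as *initial conditions*: input and threshold genes
receive no regulation and decay, and the toggle records which side won
during the transient.  Because nodes 0–2 share one decay profile, the
decision depends on the inputs only through w₁x₁ + w₂x₂ − (strength)·c₀,
which is what makes the classification exactly linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

N_NODES = 5

#: role of each node in the classifier circuit
NODE_ROLES = {
    0: "threshold gene",
    1: "input 1",
    2: "input 2",
    3: "output (toggle)",
    4: "toggle partner",
}


class IntegrationInstabilityError(RuntimeError):
    """The fixed-step integrator left the invariant [0,1] region."""


class NonConvergenceError(RuntimeError):
    """The output node failed to commit to ON or OFF within the duration."""

    def __init__(self, message: str, final_value: float):
        super().__init__(message)
        self.final_value = final_value


class DegenerateClassifierWarning(UserWarning):
    """The circuit classified every grid point identically."""


@dataclass(frozen=True)
class GRNTopology:
    """Regulatory topology: matrix A, sigmoid gain β, rate γ, offsets θ.

    ``A[j, i]`` is the regulation strength of protein j on gene i
    (row = source protein, column = target gene; positive = activation,
    negative = repression).
    """

    A: np.ndarray
    beta: float = 40.0
    gamma: float = 1.0
    theta: np.ndarray = field(
        default_factory=lambda: np.full(N_NODES, 0.5)
    )

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        theta = np.asarray(self.theta, dtype=float)
        if A.shape != (N_NODES, N_NODES):
            raise ValueError(f"A must be {N_NODES}x{N_NODES}, got {A.shape}")
        if theta.shape != (N_NODES,):
            raise ValueError(f"theta must have length {N_NODES}")
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "theta", theta)

    @property
    def input_weights(self) -> tuple[float, float]:
        """(w₁, w₂): activation strengths of the inputs on the output gene."""
        return float(self.A[1, 3]), float(self.A[2, 3])


@dataclass(frozen=True)
class GRNState:
    """Per-node mRNA and protein concentrations at one time point."""

    m: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if m.shape != (N_NODES,) or p.shape != (N_NODES,):
            raise ValueError(f"m and p must have length {N_NODES}")
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class IntegrationSettings:
    """Fixed-step RK4 settings and the convergence criterion.

    Convergence of the output node is declared once its protein has left
    the undecided band and its derivative magnitude |m₃−p₃| has fallen
    below ``derivative_tol``.
    """

    duration: float = 200.0
    dt: float = 0.01
    convergence_band: tuple[float, float] = (0.05, 0.95)
    derivative_tol: float = 1e-4
    check_interval: float = 5.0
    toggle_init: float = 0.5


def build_toggle_classifier(
    w1: float,
    w2: float,
    self_strength: float = 1.0,
    threshold_strength: float = 1.0,
    beta: float = 40.0,
    gamma: float = 1.0,
    theta: np.ndarray | None = None,
) -> GRNTopology:
    """Assemble the toggle-switch classifier topology.

    Inputs 1 and 2 activate output gene 3 with strengths w₁, w₂ and
    repress partner gene 4 with the same strengths; the threshold gene 0
    does the reverse (represses 3, activates 4) with
    ``threshold_strength``.  Genes 3 and 4 self-promote with
    ``self_strength`` (speeds convergence without changing the
    qualitative dynamics) and mutually repress with the same strength,
    forming the bistable switch.
    """
    for name, v in (
        ("w1", w1), ("w2", w2),
        ("self_strength", self_strength),
        ("threshold_strength", threshold_strength),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    A = np.zeros((N_NODES, N_NODES))
    A[0, 3], A[0, 4] = -threshold_strength, threshold_strength
    A[1, 3], A[1, 4] = w1, -w1
    A[2, 3], A[2, 4] = w2, -w2
    A[3, 3], A[3, 4] = self_strength, -self_strength
    A[4, 3], A[4, 4] = -self_strength, self_strength
    kwargs = {"beta": beta, "gamma": gamma}
    if theta is not None:
        kwargs["theta"] = np.asarray(theta, dtype=float)
    return GRNTopology(A=A, **kwargs)


def sigmoid_response(x, beta: float):
    """Sigmoid promoter response f(x) = 1/(1+e^{−βx}), overflow-safe."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    out = expit(beta * np.asarray(x, dtype=float))
    return float(out) if np.ndim(x) == 0 else out


def _derivatives(top: GRNTopology, m: np.ndarray, p: np.ndarray):
    # p @ A sums source proteins into each target gene (column of A)
    F = expit(top.beta * (p @ top.A - top.theta))
    return top.gamma * (F - m), m - p


def _rk4_step(top: GRNTopology, m, p, dt: float):
    k1m, k1p = _derivatives(top, m, p)
    k2m, k2p = _derivatives(top, m + 0.5 * dt * k1m, p + 0.5 * dt * k1p)
    k3m, k3p = _derivatives(top, m + 0.5 * dt * k2m, p + 0.5 * dt * k2p)
    k4m, k4p = _derivatives(top, m + dt * k3m, p + dt * k3p)
    return (
        m + dt / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m),
        p + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p),
    )


def _check_bounds(m, p, dt: float) -> None:
    tol = 10.0 * dt
    worst = max(
        float(np.max(np.abs(m - np.clip(m, 0.0, 1.0)))),
        float(np.max(np.abs(p - np.clip(p, 0.0, 1.0)))),
    )
    if worst > tol:
        raise IntegrationInstabilityError(
            f"state left [0,1] by {worst:.3g} (> tolerance {tol:.3g}); "
            "reduce dt"
        )


@dataclass(frozen=True)
class Trajectory:
    """Time-ordered RK4 trajectory of one circuit realization."""

    t: np.ndarray
    m: np.ndarray  # (n_times, N_NODES)
    p: np.ndarray

    def states(self):
        for i in range(len(self.t)):
            yield GRNState(m=self.m[i], p=self.p[i], t=float(self.t[i]))

    def final(self) -> GRNState:
        return GRNState(m=self.m[-1], p=self.p[-1], t=float(self.t[-1]))

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for i in range(N_NODES):
            data[f"m{i}"] = self.m[:, i]
        for i in range(N_NODES):
            data[f"p{i}"] = self.p[:, i]
        return pd.DataFrame(data)


def simulate(
    topology: GRNTopology,
    initial: GRNState,
    duration: float,
    dt: float = 0.01,
) -> Trajectory:
    """Integrate the circuit with classical fixed-step RK4.

    The fixed step keeps runs bit-reproducible for a given dt.  States
    are checked against the invariant [0,1] region every step; leaving
    it by more than 10·dt raises :class:`IntegrationInstabilityError`.
    """
    if dt <= 0 or dt >= duration:
        raise ValueError("need 0 < dt < duration")
    n_steps = int(round(duration / dt))
    m = initial.m.copy()
    p = initial.p.copy()
    ms = np.empty((n_steps + 1, N_NODES))
    ps = np.empty((n_steps + 1, N_NODES))
    ms[0], ps[0] = m, p
    for k in range(1, n_steps + 1):
        m, p = _rk4_step(topology, m, p, dt)
        _check_bounds(m, p, dt)
        ms[k], ps[k] = m, p
    t = initial.t + dt * np.arange(n_steps + 1)
    return Trajectory(t=t, m=ms, p=ps)


def classify_grid(
    topology: GRNTopology,
    x1: np.ndarray,
    x2: np.ndarray,
    threshold_expression: float,
    settings: IntegrationSettings | None = None,
):
    """Vectorized classification of many (x₁, x₂) input pairs.

    Every pair is integrated as an independent circuit copy from the
    initial condition m = p = (c₀, x₁, x₂, s, s) with s the symmetric
    toggle start.  Integration proceeds in chunks and stops once every
    copy has converged (output protein outside the undecided band with a
    small derivative) or the duration is exhausted.

    Returns ``(outputs, converged, p3_final)`` — int8 decisions
    (output protein > 0.5), a convergence mask, and the final output
    protein levels.
    """
    settings = settings or IntegrationSettings()
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have the same shape")
    if np.any((x1 < 0) | (x1 > 1) | (x2 < 0) | (x2 > 1)):
        raise ValueError("inputs must lie in [0,1]")
    if not (0.0 <= threshold_expression <= 1.0):
        raise ValueError("threshold_expression must lie in [0,1]")
    B = x1.size
    m = np.empty((B, N_NODES))
    m[:, 0] = threshold_expression
    m[:, 1] = x1
    m[:, 2] = x2
    m[:, 3] = settings.toggle_init
    m[:, 4] = settings.toggle_init
    p = m.copy()

    dt = settings.dt
    lo, hi = settings.convergence_band
    steps_per_chunk = max(int(round(settings.check_interval / dt)), 1)
    total_steps = int(round(settings.duration / dt))
    done = np.zeros(B, dtype=bool)
    step = 0
    while step < total_steps:
        n = min(steps_per_chunk, total_steps - step)
        for _ in range(n):
            m, p = _rk4_step(topology, m, p, dt)
        step += n
        _check_bounds(m, p, dt)
        p3, dp3 = p[:, 3], np.abs(m[:, 3] - p[:, 3])
        done = ((p3 < lo) | (p3 > hi)) & (dp3 < settings.derivative_tol)
        if done.all():
            break
    return (p[:, 3] > 0.5).astype(np.int8), done, p[:, 3].copy()


def classify_inputs(
    topology: GRNTopology,
    x1: float,
    x2: float,
    threshold_expression: float,
    settings: IntegrationSettings | None = None,
) -> int:
    """Binary decision of the circuit for one input pair.

    Returns 1 if the output gene's protein converges ON (> 0.5), else 0.
    Raises :class:`NonConvergenceError` if the output protein is still
    inside the undecided band when the integration duration runs out.
    """
    out, done, p3 = classify_grid(
        topology, [x1], [x2], threshold_expression, settings
    )
    if not done[0]:
        raise NonConvergenceError(
            f"output node did not converge (final protein {p3[0]:.4f})",
            final_value=float(p3[0]),
        )
    return int(out[0])


@dataclass(frozen=True)
class BoundaryFit:
    """Empirical decision boundary of the circuit in the input plane.

    ``slope``/``intercept`` describe the least-squares line
    x₂ = slope·x₁ + intercept through the per-column flip points;
    ``residual`` is the maximum perpendicular deviation of the flip
    points from that line.  ``t_eff`` is the effective linear threshold:
    the mean of w₁x₁ + w₂x₂ over the flip points.
    """

    points: np.ndarray  # (k, 2) flip locations
    slope: float
    intercept: float
    residual: float
    t_eff: float

    @property
    def is_degenerate(self) -> bool:
        return len(self.points) == 0


def empirical_boundary(
    topology: GRNTopology,
    threshold_expression: float,
    grid_resolution: int = 50,
    settings: IntegrationSettings | None = None,
) -> BoundaryFit:
    """Locate and fit the circuit's decision boundary on an input grid.

    For each x₁ grid column the flip point is the midpoint between the
    last OFF and first ON x₂ value (the decision is monotone in each
    input).  Columns whose classification never flips are skipped; if no
    column flips at all, a :class:`DegenerateClassifierWarning` is
    issued and a NaN fit returned.
    """
    if grid_resolution < 10:
        raise ValueError("grid_resolution must be at least 10")
    import warnings as _warnings

    g = np.linspace(0.0, 1.0, grid_resolution)
    X1, X2 = np.meshgrid(g, g, indexing="ij")
    out, _, _ = classify_grid(
        topology, X1.ravel(), X2.ravel(), threshold_expression, settings
    )
    out = out.reshape(grid_resolution, grid_resolution)
    pts = []
    for i in range(grid_resolution):
        col = out[i]
        ones = np.nonzero(col == 1)[0]
        if len(ones) == 0 or ones[0] == 0:
            continue  # all-OFF column, or ON from the edge: no interior flip
        j = ones[0]
        pts.append((g[i], 0.5 * (g[j - 1] + g[j])))
    if not pts:
        _warnings.warn(
            "no classification flip found on the grid (all-0 or all-1 "
            "output): degenerate classifier",
            DegenerateClassifierWarning,
            stacklevel=2,
        )
        return BoundaryFit(
            points=np.empty((0, 2)), slope=np.nan, intercept=np.nan,
            residual=np.nan, t_eff=np.nan,
        )
    pts = np.asarray(pts)
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    perp = np.abs(slope * pts[:, 0] - pts[:, 1] + intercept) / np.hypot(
        slope, 1.0
    )
    w1, w2 = topology.input_weights
    t_eff = float(np.mean(w1 * pts[:, 0] + w2 * pts[:, 1]))
    return BoundaryFit(
        points=pts,
        slope=float(slope),
        intercept=float(intercept),
        residual=float(np.max(perp)),
        t_eff=t_eff,
    )
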