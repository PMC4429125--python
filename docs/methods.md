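# Methods

## The circuit model

The classifier is a five-node gene circuit in the Kaneko-style
continuous framework: each gene i carries an mRNA level m(i) and a
protein level p(i), both *relative* concentrations in [0, 1], with

    dm(i)/dt = γ ( f( Σⱼ A[j,i] p(j) − θᵢ ) − m(i) )
    dp(i)/dt = m(i) − p(i)
    f(x)     = 1 / (1 + e^(−βx))

`A[j,i]` is the strength of protein j's regulation of gene i (positive
activation, negative repression).  Because f ∈ (0, 1), the hypercube
[0,1]¹⁰ is forward-invariant: trajectories started inside never leave
it, which is what lets "relative concentration" be taken literally.

The topology couples a toggle switch to three unregulated nodes:

| node | role | outgoing regulation |
|---|---|---|
| 0 | threshold gene | represses output 3, activates partner 4 (strength 1) |
| 1, 2 | inputs | activate 3 with w₁, w₂; repress 4 with the same |
| 3 | output | self-promotes (+1), represses 4 (−1) |
| 4 | toggle partner | self-promotes (+1), represses 3 (−1) |

Genes 3 and 4 form the bistable memory; their self-promotion only
speeds convergence.  Inputs are delivered as *initial conditions*:
nodes 0–2 receive no regulation, so (with θ = 0.5 and β = 40 their
production term is ≈ 0) they decay, and the toggle records which side
won during the transient.  Crucially, nodes 0–2 share one decay
profile, so the entire drive on the toggle depends on the inputs only
through the single number w₁x₁ + w₂x₂ − c₀ (c₀ the threshold gene's
initial level).  The circuit's decision is therefore *exactly* a linear
rule [w₁x₁ + w₂x₂ > T_eff], with T_eff an increasing function of c₀;
`empirical_boundary` measures T_eff rather than asserting a formula
(fitted boundary lines have maximum perpendicular residual < 0.01 at
default parameters, e.g. T_eff ≈ 0.99 at c₀ = 0.5 with unit weights).

Parameter defaults, with the reasoning where a choice was open:

- **β = 40** (sigmoid gain): steep, nearly a step — the regulatory
  switching regime the model assumes.
- **γ = 1** (mRNA relaxation rate): no value is dictated by the model;
  γ rescales time only, not steady states, so the neutral choice makes
  the mRNA and protein timescales equal.
- **θ = 0.5 for every node** (activation offsets): centers each
  sigmoid.  For the toggle genes this balances self-activation against
  repression, which is what makes the switch bistable (verified by the
  bistability test); for the unregulated nodes it makes them decay,
  implementing pulse-style input delivery.
- **Toggle initial state m = p = 0.5** on nodes 3 and 4: unbiased
  symmetric start, configurable.
- **Integration**: classical fixed-step RK4, dt = 0.01, duration up to
  200 time units.  Fixed step (rather than adaptive) keeps runs
  bit-reproducible for a given dt.  The integrator's measured
  convergence order on smooth stretches is 4.0.  States are checked
  against [0,1] every step with tolerance 10·dt; violations raise an
  instability error rather than silently clipping.
- **Convergence**: the output protein must leave the band [0.05, 0.95]
  with |dp₃/dt| < 10⁻⁴.  "Long enough" is not otherwise defined; at
  these parameters decisions resolve by t ≈ 15–30.

Noisy inputs entering the circuit are clipped to [0, 1] (concentrations
cannot be negative or exceed the relative maximum).  The abstract
perceptron path does **not** clip, so the Gaussian closed-form theory
applies exactly there; the clipped/unclipped discrepancy matters only
within ~2σ of the domain edges.

## The perceptron statistic

Accuracy compares the clean, unspoiled classification O(i) of N
uniform[0,1]ⁿ inputs with the noisy, spoiled classification D(i) of the
*same* inputs: accuracy = (|{O=D=1}| + |{O=D=0}|)/N.  Ties x̄ = T
classify as 0.  N defaults to 10 000.  Noise is added to inputs only,
never to the threshold.  Gaussian deviates come from numpy's PCG64
generator (the algorithm generating the normals is immaterial; their
distribution is the model).  Noise-intensity scans reuse one clean
input sample across the σ² grid with fresh noise per point (paired
design, seeded): this removes input-sampling variance from the curve's
shape, which is what the resonance statements are about.  Whether the
original study re-drew inputs per σ² point is unknown; pairing is this
package's choice and is recorded in every output file's metadata.

## Closed-form accuracy

The weighted sum S = Σ wᵢUᵢ of i.i.d. uniform inputs has the weighted
Irwin–Hall-type density (inclusion–exclusion over weight subsets J)

    fₙ(s) = [ Σ_J (−1)^|J| ((s − Σ_{j∈J} wⱼ)₊)^(n−1) ] / (Πᵢwᵢ (n−1)!)

a piecewise polynomial of degree n−1 with knots at the 2ⁿ subset sums.
The exponent is n−1: that is the unique exponent for which the n = 2
case reproduces the trapezoidal two-weight density (rising s/(w₁w₂),
flat 1/w₂, falling edge) and the density integrates to one.  Equal
weights give the triangular density s/w² with peak 1/w.  The formula is
cross-validated against brute-force numerical convolution (n = 2, 3, 4,
sup-norm < 10⁻³).

Per-input noise N(0, σ²) folds into sum-level noise N(0, σ_new²) with
σ_new² = σ² Σwᵢ² (equal weights: σ_new = √2·wσ).  The population
accuracy is then

    P = ½ [ 1 + ∫₀^{T₁} fₙ(x) erf((T₂−x)/(√2 σ_new)) dx
              − ∫_{T₁}^{W} fₙ(x) erf((T₂−x)/(√2 σ_new)) dx ]

evaluated by adaptive quadrature (absolute tolerance 10⁻⁸) split at the
density's knots and at T₂, where the integrand is non-smooth.  σ = 0 is
evaluated as the exact indicator limit, P = 1 − |Fₙ(T₂) − Fₙ(T₁)|,
avoiding a 0/0 in the erf argument.  The curve matches the Monte-Carlo
estimate within binomial error at every tested configuration.

Optimizers (`accuracy_vs_threshold`, `optimal_noise`) use a coarse
deterministic grid followed by bounded scalar maximization around the
best grid point (no randomness); if the refined value is worse than the
best grid point — possible when the maximum sits on an interval
boundary or on the kink at T₂ = T₁ — the grid point wins.  Boundary
optima trigger a warning.

A structural fact worth knowing: when T₁ sits at the symmetry point of
fₙ (equal weights with T₁ = W/2, e.g. w = (1,1), T₁ = 1), the optimal
T₂ is pinned at T₁ for *every* noise level, because the two erf
integrals shift identically.  The characteristic rightward drift of the
optimal threshold with noise — and a resonance bell strong enough to
clear Monte-Carlo error at N = 10 000 — requires an off-center
threshold.  The package's headline configurations therefore use
w = (0.7, 0.7) with T₁ = 1 (where F(T₁) ≈ 0.84): there the 1 → 1.3
spoiling shows a bell rising from 0.847 to 0.868 at σ² ≈ 0.044, the
optimal T₂ moves 1.026 → 1.313 → 1.395 as σ² goes 0.01 → 0.1 → 0.2, and
a 1.1-spoiled classifier overtakes the unspoiled one at σ² ≈ 0.02–0.03
and dominates thereafter.  With w = (1,1), T₁ = 1 the same spoiling
yields a maximal gain of only +0.009 at σ² ≈ 0.015 — real, but below
3 binomial SE at N = 10 000.

## Delta-rule learning and learning resonance

A teacher with weights w* and threshold T = 1 labels a fixed training
set of `train_size` clean uniform inputs.  Each presentation, the
learner observes the input plus fresh N(0, σ²) noise, classifies it
against the spoiled threshold T₂ with its current weights, and updates

    w ← w + α (target − prediction) · x_observed

with α = 0.01.  The update uses the input the learner actually observed
(the noisy one) — the only input a physical learner has access to.  Two
alternative readings were examined and rejected because they destroy
the resonance phenomenon itself: updating with the clean input produces
no detectable error minimum (flat curve at 120 replicates), and
freezing one noisy copy of the training set across passes makes error
increase monotonically with σ².

Training stops after 2000 passes or on the first pass whose mean
absolute delta falls below 0.001 (with 0/1 targets: an error-free
pass).  A signed mean delta would cancel under symmetric noise and stop
training spuriously, so the absolute value is used.  Performance is the
Euclidean distance ‖w* − w‖ of the final weights from the truth;
resonance scans report the mean over 20 independent replicates per σ²
(fresh training set and noise per replicate) with its standard error.
Unstated details fixed once: initial weights (0.5, 0.5), training-set
size 100.

Mechanism: at σ² = 0 the stationary weights are inflated to (T₂/T)·w*
(error ≈ 0.1 for the 0.7/0.7, 1 → 1.1 configuration) because scaling is
the only way to reconcile the spoiled threshold with the teacher's
boundary.  Noise correlates with the prediction errors it causes, and
through the noisy-input update this shrinks the weights; the two biases
cancel at an intermediate σ².  Under this package's protocol the mean
weight-error curve has its minimum at σ² ≈ 0.05 (0.065 there vs 0.095
at σ² = 0, rising again beyond ≈ 0.10; located with 120 replicates per
point).  A single unreplicated scan — each point one draw with
standard deviation ≈ 0.03–0.04 — can place its apparent minimum
anywhere in the flat dip and beyond, which is worth keeping in mind
when comparing reported resonance locations; the replicated protocol
here is the package's own addition for testability.

## Synthetic data

All inputs are generated internally: uniform[0,1]ⁿ input vectors and
Gaussian noise deviates from seeded PCG64 streams.  This emulates the
idealized assay the model defines — independent, uniformly distributed
input concentrations and purely extrinsic, additive, unclipped input
noise.  It does not emulate intrinsic expression noise (no stochastic
chemical kinetics; noise never enters the ODE right-hand side),
correlated or non-uniform inputs, or parameter drift.  Passing tests
therefore validate the model's internal consistency and its theory—
simulation agreement, not the behaviour of any wet system.

## Problem sizes

Defaults were chosen so every scan is exact enough to resolve the
effects it measures: Monte-Carlo scans use N = 10 000 (binomial SE
≈ 0.004, an order below the resonance amplitudes studied); resonance
scans use 20 replicates (SE of the mean error ≈ 0.01); circuit grids
are 50×50 with dt = 0.01.  The vectorized integrator and trainer run
all grid points or replicates as one batch, so the complete test suite
and the acceptance script each finish in well under a minute on one
core.

## Known limitations

- The map from threshold-gene expression c₀ to T_eff is measured, not
  derived; it is monotone but mildly nonlinear in c₀.
- The closed-form theory covers unclipped Gaussian noise only; there is
  no truncated-noise analogue for the clipped circuit path.
- `optimal_noise` and `accuracy_vs_threshold` search bounded intervals;
  at large σ² the accuracy-maximizing T₂ can sit at (or beyond) the
  upper end of the admissible range (0, Σwᵢ), where the classifier
  degenerates toward the majority class, and the scan then reports the
  boundary with a warning.
- Learning is the single-layer delta rule only; no biochemical
  implementation of the learning loop, and no backpropagation.
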