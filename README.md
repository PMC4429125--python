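# srclassify

**Stochastic resonance in genetic linear classifiers.**

Single cells make yes/no decisions by weighing chemical inputs — a
computation equivalent to a *perceptron*: output 1 iff the weighted sum
of inputs exceeds a threshold, `F(x̄) = 1 if x̄ = Σᵢ wᵢxᵢ > T else 0`.
A small gene regulatory circuit can implement this: two input genes
push a bistable toggle switch (two mutually repressing genes) one way,
a constitutively expressed "threshold" gene pushes it the other way,
and the toggle's output gene latches the decision.

Gene expression is noisy.  This package studies — by ODE simulation,
Monte-Carlo sampling, and closed-form theory — a counterintuitive
consequence: when the decision threshold is *spoiled* (shifted from T₁
to T₂ ≠ T₁), an intermediate intensity of zero-mean Gaussian input
noise **restores** classification accuracy (stochastic resonance), and
a delta-rule learner facing a spoiled threshold learns the true weights
**best** under an intermediate noise level (learning resonance).

What's inside:

- `srclassify.grn_circuit` — the five-node toggle-switch classifier:
  mRNA/protein ODEs `dm/dt = γ(f(Σⱼ Aⱼᵢ pⱼ − θᵢ) − m)`, `dp/dt = m − p`
  with sigmoid regulation `f(x) = 1/(1+e^(−βx))`, fixed-step RK4
  integration, classification from the output gene's steady state, and
  empirical decision-boundary fitting.
- `srclassify.perceptron` — the abstract n-input threshold classifier,
  uniform input sampling, Gaussian noise injection, and the paired
  Monte-Carlo accuracy statistic
  `accuracy = (|{O=D=1}| + |{O=D=0}|)/N`.
- `srclassify.analytic_theory` — the weighted Irwin–Hall density
  `fₙ(s)` of `Σ wᵢUᵢ`, the combined sum-level noise
  `σ_new = σ√(Σwᵢ²)`, the erf-integral total accuracy
  `P = ½[1 + ∫₀^{T₁} fₙ erf((T₂−x)/(√2σ_new)) − ∫_{T₁}^{W} fₙ erf(·)]`,
  and deterministic optimizers over T₂ and σ².
- `srclassify.delta_learning` — delta-rule training
  `w ← w + α(target − prediction)·x` against a noisy, spoiled unit, and
  the learning-resonance scan.
- `srclassify.experiments` — seeded experiment drivers writing CSV
  curves with JSON metadata sidecars, plus a thin `srclassify` CLI.

## Worked example

```python
import numpy as np
from srclassify import ClassifierSpec, sr_scan, total_accuracy

spec = ClassifierSpec(w=(0.7, 0.7), T1=1.0, T2=1.3)   # spoiled 1 -> 1.3
table = sr_scan(spec, np.linspace(0, 0.5, 11), N=10_000, seed=42)
for s2, acc in zip(table["sigma2"], table["accuracy"]):
    print(f"{s2:4.2f}  {acc:.4f}  {total_accuracy(spec.w, 1.0, 1.3, np.sqrt(s2)):.4f}")
```

```
0.00  0.8523  0.8469
0.05  0.8721  0.8676
0.10  0.8600  0.8566
0.15  0.8379  0.8406
...
0.50  0.7622  0.7555
```

Columns: noise variance σ², Monte-Carlo accuracy (10 000 paired
samples), closed-form accuracy.  Without noise the spoiled classifier
misclassifies the band between the cut lines `Σwᵢxᵢ = 1` and `= 1.3`
(accuracy 0.85); at σ² ≈ 0.05 noise rescues part of that band (0.87)
before degrading everything at higher intensities — the stochastic-
resonance bell, with simulation and theory agreeing to Monte-Carlo
precision.

The `examples/` directory has one short script per capability: the gene
circuit as a linear classifier, the resonance bell, optimal spoiling
vs noise, the spoiled/unspoiled crossover, and learning resonance.
Each prints the numbers it computes and one line on what they mean.

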