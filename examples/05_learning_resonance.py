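"""Learning resonance: noise helps a learner see past a spoiled threshold.

A delta-rule learner receives noisy inputs and classifies them against
a spoiled threshold (1.1) while the teacher labels clean inputs with
the true threshold (1.0).  Without noise the learner settles on weights
inflated by the threshold mismatch; an intermediate noise intensity
cancels that bias and minimizes the Euclidean distance to the true
weights.  (Scaled down to a coarse grid and 8 replicates so it runs in
a few seconds; the full scan uses a 0.01-step grid and 20 replicates.)
"""

import numpy as np

from srclassify import LearningConfig, learning_resonance_scan, train

cfg = LearningConfig(
    alpha=0.01, T_unspoiled=1.0, T_spoiled=1.1,
    max_passes=2000, train_size=100, seed=123,
)

clean = train((0.7, 0.7), cfg)
print(f"no noise:  learned weights {np.round(clean.w_learned, 3)}, "
      f"error {clean.weight_error:.4f} "
      "(inflated toward 1.1x the true weights)")

grid = np.round(np.arange(0.0, 0.31, 0.03), 3)
res = learning_resonance_scan((0.7, 0.7), cfg, grid, replicates=8)
print("\nsigma^2   mean weight error   (se)")
for _, r in res.table.iterrows():
    print(f"  {r['sigma2']:5.2f}       {r['mean_error']:.4f}       "
          f"({r['se_error']:.4f})")
print(
    f"\nminimum error {res.min_error:.4f} at sigma^2 = {res.sigma2_opt} "
    "— an intermediate noise level learns the true weights best."
)
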