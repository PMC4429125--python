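"""Independent numerical oracles shared by the test modules."""

import numpy as np


def convolved_density(weights, resolution=1e-4):
    """Brute-force density of Σ wᵢUᵢ: iterated numerical convolution of
    the uniform(0, wᵢ) box densities on a regular grid."""
    ds = resolution
    W = float(np.sum(weights))
    n_pts = int(np.ceil(W / ds)) + 1
    grid = np.arange(n_pts) * ds
    dens = None
    for w in weights:
        box = np.where(grid <= w, 1.0 / w, 0.0)
        if dens is None:
            dens = box
        else:
            dens = np.convolve(dens, box)[: len(grid)] * ds
    return grid, dens
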