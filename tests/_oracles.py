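"""Independent brute-force oracles shared across test modules."""

import numpy as np


def grid_search_max_corr(X, Y, n_angles=3000):
    """First canonical correlation of two-column blocks by dense search
    over unit directions a = (cos t, sin t), b = (cos u, sin u)."""
    theta = np.linspace(0, np.pi, n_angles, endpoint=False)
    A = np.column_stack([np.cos(theta), np.sin(theta)])
    xa = X @ A.T
    yb = Y @ A.T
    xa = xa - xa.mean(axis=0)
    yb = yb - yb.mean(axis=0)
    xa /= np.linalg.norm(xa, axis=0)
    yb /= np.linalg.norm(yb, axis=0)
    return np.abs(xa.T @ yb).max()
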