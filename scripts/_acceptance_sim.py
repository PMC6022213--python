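"""Synthetic draws from a known Bernoulli-Gaussian mixture (acceptance runs)."""

import numpy as np

from preictal import LabelledPool

TRUE_PI = (0.15, 0.85)
TRUE_LAM = (0.35, 0.75)


def simulate_bgmm_pool(
    seed: int,
    n: int = 2000,
    d: int = 4,
    separation: float = 3.0,
    alpha1: float = 0.4,
    labelled_frac: float = 0.1,
    K: int = 3,
):
    """Pool drawn from the mixture model itself: unit-variance components
    ``separation`` standard deviations apart, Bernoulli crisp histories and
    Gaussian soft histories per class.  Returns (pool, true_mu, true_alpha)."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < alpha1).astype(int)
    offset = separation / (2.0 * np.sqrt(d))
    mu = np.vstack([-offset * np.ones(d), offset * np.ones(d)])
    X = rng.standard_normal((n, d)) + mu[y]
    U = (rng.random((n, K)) < np.asarray(TRUE_PI)[y][:, None]).astype(float)
    V = np.clip(rng.normal(np.asarray(TRUE_LAM)[y][:, None], 0.12, (n, K)), 0.0, 1.0)
    observed = np.where(rng.random(n) < labelled_frac, y, -1)
    for c in (0, 1):
        if not np.any(observed == c):
            observed[np.flatnonzero(y == c)[0]] = c
    pool = LabelledPool.create(X, observed, K=K)
    pool.U, pool.V, pool.H = U, V, np.ones((n, K), dtype=bool)
    return pool, mu, np.array([1.0 - alpha1, alpha1])
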