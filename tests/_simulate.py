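"""Shared synthetic generators for the mixture-model tests."""

import numpy as np

from preictal import LabelledPool

TRUE_PI = (0.15, 0.85)  # crisp-label success probability per class
TRUE_LAM = (0.35, 0.75)  # soft-label mean per class (any crisp value)


def simulate_bgmm_pool(
    seed: int,
    n: int = 2000,
    d: int = 4,
    separation: float = 3.0,
    alpha1: float = 0.4,
    labelled_frac: float = 0.1,
    K: int = 3,
):
    """Draw a pool from a known two-component Bernoulli-Gaussian mixture.

    Component means sit ``separation`` standard deviations apart (unit
    isotropic covariance); crisp histories are Bernoulli draws with the
    per-class success probabilities, soft histories Gaussian around the
    per-class means.  Returns (pool, true_mu, true_alpha).
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < alpha1).astype(int)
    offset = separation / (2.0 * np.sqrt(d))
    mu = np.vstack([-offset * np.ones(d), offset * np.ones(d)])
    X = rng.standard_normal((n, d)) + mu[y]
    U = (rng.random((n, K)) < np.asarray(TRUE_PI)[y][:, None]).astype(float)
    V = np.clip(
        rng.normal(np.asarray(TRUE_LAM)[y][:, None], 0.12, (n, K)), 0.0, 1.0
    )
    observed = np.where(rng.random(n) < labelled_frac, y, -1)
    # guarantee the semi-supervised preconditions
    for c in (0, 1):
        if not np.any(observed == c):
            observed[np.flatnonzero(y == c)[0]] = c
    pool = LabelledPool.create(X, observed, K=K)
    pool.U, pool.V, pool.H = U, V, np.ones((n, K), dtype=bool)
    alpha = np.array([1.0 - alpha1, alpha1])
    return pool, mu, alpha


def make_history_pool(seed=0, n=40, d=3, sep=3.0, labelled_frac=0.3, K=4):
    """Small blob pool with two rounds of noisy classifier-output history."""
    rng = np.random.default_rng(seed)
    n1 = n // 2
    X = np.vstack(
        [rng.normal(-sep / 2, 1.0, (n - n1, d)), rng.normal(sep / 2, 1.0, (n1, d))]
    )
    y_true = np.array([0] * (n - n1) + [1] * n1)
    observed = np.where(rng.random(n) < labelled_frac, y_true, -1)
    for c in (0, 1):
        if not np.any(observed == c):
            observed[np.flatnonzero(y_true == c)[0]] = c
    pool = LabelledPool.create(X, observed, K=K)
    for _ in range(2):
        crisp = np.where(rng.random(n) < 0.2, 1 - y_true, y_true).astype(float)
        pool.record_outputs(crisp, rng.uniform(0.5, 1.0, n))
    return pool, y_true
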