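"""Independent brute-force reference implementations used only by tests.

These deliberately use plain Python loops and scipy.stats densities, not the
package's vectorized code paths, so they can serve as oracles for the
windowed feature statistics and the mixture-model E/M updates.
"""

import math

import numpy as np
from scipy.stats import multivariate_normal, norm

_PI_EPS = 1e-4


def naive_time_features(x, fs):
    """Loop-based reimplementation of the eight time-domain features."""
    x = [float(v) for v in x]
    n = len(x)
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]

    area = sum(abs(v) for v in x) / n
    if diffs:
        frac_dec = sum(1 for d in diffs if d < 0) / len(diffs)
    else:
        frac_dec = 0.5
    decay = max(-1.0, min(1.0, (frac_dec - 0.5) * 2.0))
    line_length = sum(abs(d) for d in diffs)
    energy = sum(v * v for v in x) / n

    peaks, valleys = [], []
    for i in range(1, len(diffs)):
        if diffs[i - 1] < 0 and diffs[i] > 0:
            peaks.append(i)
        if diffs[i - 1] > 0 and diffs[i] < 0:
            valleys.append(i)

    def log_ms(indices):
        if not indices:
            return -12.0
        ms = sum(x[i] ** 2 for i in indices) / len(indices)
        return math.log10(ms) if ms > 0 else -12.0

    peak_amp = log_ms(peaks)
    valley_amp = log_ms(valleys)
    mean_step = sum(abs(d) for d in diffs) / len(diffs) if diffs else 0.0
    peak_number = len(peaks) / (mean_step + 1e-12)

    extrema = sorted(peaks + valleys)
    if len(extrema) < 2:
        peak_variation = 0.0
    else:
        swings = [x[extrema[i + 1]] - x[extrema[i]] for i in range(len(extrema) - 1)]
        mean_sw = sum(swings) / len(swings)
        var_sw = sum((s - mean_sw) ** 2 for s in swings) / len(swings)
        peak_variation = math.sqrt(var_sw) / (n / fs)

    return np.array(
        [area, decay, line_length, energy, peak_amp, valley_amp, peak_number, peak_variation]
    )


def naive_log_obs(state, pool, j, c):
    """log [alpha_c * N(x_j) * prod_k B(u_jk) * prod_k N(v_jk)] for one sample."""
    if state.cov_type == "diag":
        lg = sum(
            norm.logpdf(pool.X[j, i], state.mu[c, i], math.sqrt(state.var[c, i]))
            for i in range(pool.d)
        )
    else:
        lg = multivariate_normal.logpdf(pool.X[j], state.mu[c], state.var[c])
    total = lg + math.log(state.alpha[c])
    for k in range(pool.K):
        if not pool.H[j, k]:
            continue
        p = min(max(state.pi[c, k], _PI_EPS), 1 - _PI_EPS)
        u = pool.U[j, k]
        total += u * math.log(p) + (1 - u) * math.log(1 - p)
        if state.use_soft:
            m = int(u)
            total += norm.logpdf(
                pool.V[j, k], state.lam[c, m, k], math.sqrt(state.sigma2[c, m, k])
            )
    return total


def naive_e_step(state, pool):
    resp = np.zeros((pool.N, 2))
    for j in range(pool.N):
        if pool.y[j] >= 0:
            resp[j, pool.y[j]] = 1.0
            continue
        logs = [naive_log_obs(state, pool, j, c) for c in range(2)]
        mx = max(logs)
        w = [math.exp(v - mx) for v in logs]
        resp[j] = np.array(w) / sum(w)
    return resp


def naive_weighted_moments(resp, pool):
    """Loop-based M-step moments: alpha, mu, diagonal variances, pi."""
    N, d, K = pool.N, pool.d, pool.K
    alpha = np.zeros(2)
    mu = np.zeros((2, d))
    var = np.zeros((2, d))
    pi = np.full((2, K), 0.5)
    for c in range(2):
        mass = sum(resp[j, c] for j in range(N))
        alpha[c] = mass / N
        for i in range(d):
            mu[c, i] = sum(resp[j, c] * pool.X[j, i] for j in range(N)) / mass
        for i in range(d):
            var[c, i] = (
                sum(resp[j, c] * (pool.X[j, i] - mu[c, i]) ** 2 for j in range(N)) / mass
            )
        for k in range(K):
            denom = sum(resp[j, c] for j in range(N) if pool.H[j, k])
            if denom > 0:
                num = sum(resp[j, c] * pool.U[j, k] for j in range(N) if pool.H[j, k])
                pi[c, k] = min(max(num / denom, _PI_EPS), 1 - _PI_EPS)
    return alpha, mu, var, pi
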