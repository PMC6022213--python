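"""Semi-supervised Bernoulli-Gaussian mixture active learner.

The learner models the joint density of window feature vectors x, hidden
class y ∈ {0, 1}, and the base classifier's outputs over up to K query
rounds: crisp labels u ∈ {0,1}^K (Bernoulli per class, success probability
π_ck) and soft labels v ∈ [0,1]^K (Gaussian per class and per crisp value
m ∈ {0,1}, parameters λ_cmk, σ_cmk).  Features follow a two-component
Gaussian mixture with proportions α_c, means μ_c and covariances Σ_c
(diagonal by default, since window feature dimension often exceeds the
desk-scale sample count).

Parameters are estimated by expectation-maximization with the labelled
samples held at indicator responsibilities (semi-supervised EM):

* E-step: labelled sample j gets γ_{j,c} = I(y_j = c); an unlabelled sample
  gets the posterior responsibility
  T_{j,c} ∝ α_c · N(x_j; μ_c, Σ_c) · Π_k B(u_jk; π_ck) · Π_k N(v_jk; λ, σ²),
  normalized over c.
* M-step: responsibility-weighted maximum-likelihood updates —
  α_c = Σ_j γ_{j,c} / N, μ_c and Σ_c the weighted moments,
  π_ck the weighted mean of crisp indicators, λ/σ the weighted soft-label
  moments split by crisp value.

The sample to query next is the least confident one,
argmax_j (1 − max_c γ_{j,c}); querying stops when the mean confidence stays
flat for consecutive iterations or the expert budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .classify import ClassifierModel, partition_ambiguous, predict, train

_LL_TOL = 1e-8  # slack for the monotone-likelihood assertion
_PI_EPS = 1e-4
_MIN_SIGMA2 = 1e-4


class ClassCollapseError(RuntimeError):
    """A mixture component lost all responsibility mass."""


@dataclass
class LabelledPool:
    """Features with partial labels and per-sample classifier-output history.

    ``y`` holds −1 for unknown labels.  ``U``/``V`` store up to K crisp/soft
    labels per sample (one column per completed query round); ``H`` masks
    the valid columns.  The pool is the semi-supervised regime: at least one
    label known, at least one hidden.
    """

    X: np.ndarray  # (N, d)
    y: np.ndarray  # (N,) in {-1, 0, 1}
    U: np.ndarray  # (N, K) crisp history
    V: np.ndarray  # (N, K) soft history
    H: np.ndarray  # (N, K) bool, valid history entries
    confidence_history: list[float] = field(default_factory=list)

    @classmethod
    def create(cls, X: np.ndarray, y: np.ndarray, K: int = 10) -> "LabelledPool":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        N = len(X)
        return cls(
            X=X,
            y=y.copy(),
            U=np.zeros((N, K)),
            V=np.zeros((N, K)),
            H=np.zeros((N, K), dtype=bool),
        )

    @property
    def N(self) -> int:
        return len(self.X)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return self.U.shape[1]

    @property
    def labelled(self) -> np.ndarray:
        return np.flatnonzero(self.y >= 0)

    @property
    def unlabelled(self) -> np.ndarray:
        return np.flatnonzero(self.y < 0)

    def record_outputs(
        self, crisp: np.ndarray, soft: np.ndarray, rows: np.ndarray | None = None
    ) -> None:
        """Append one round of classifier outputs (first free history column).

        ``crisp``/``soft`` align with ``rows`` (all samples when omitted);
        histories already K entries long are frozen.
        """
        if rows is None:
            rows = np.arange(self.N)
        rows = np.asarray(rows, dtype=int)
        H = self.H[rows]
        free = self.K - 1 - np.argmax(H[:, ::-1], axis=1)
        free = np.where(H.any(axis=1), free + 1, 0)
        keep = np.flatnonzero(free < self.K)
        r, f = rows[keep], free[keep]
        self.U[r, f] = np.asarray(crisp)[keep]
        self.V[r, f] = np.asarray(soft)[keep]
        self.H[r, f] = True


@dataclass
class BGMMState:
    alpha: np.ndarray  # (2,)
    mu: np.ndarray  # (2, d)
    var: np.ndarray  # (2, d) diagonal or (2, d, d) full
    pi: np.ndarray  # (2, K)
    lam: np.ndarray  # (2, 2, K) soft-label means, indexed [class, crisp m, k]
    sigma2: np.ndarray  # (2, 2, K) soft-label variances
    resp: np.ndarray  # (N, 2)
    loglik_trace: list[float] = field(default_factory=list)
    cov_type: str = "diag"
    use_soft: bool = True
    converged: bool = False
    var_floor: np.ndarray | float = 1e-12

    @property
    def K(self) -> int:
        return self.pi.shape[1]


def _variance_floor(X: np.ndarray, cov_type: str):
    """Constant per-fit covariance floor (keeps EM a constrained ascent).

    Diagonal mode floors each dimension at a small fraction of its pooled
    variance; full mode floors the eigenvalues at a fraction of the mean
    pooled variance.  Because the floor does not move between iterations,
    flooring is the constrained M-step argmax and the likelihood trace
    stays monotone.
    """
    global_var = X.var(axis=0)
    if cov_type == "diag":
        return 1e-8 * global_var + 1e-12
    return float(1e-8 * global_var.mean() + 1e-12)


def _regularize_var(var: np.ndarray, cov_type: str, floor) -> np.ndarray:
    if cov_type == "diag":
        return np.maximum(var, floor)
    var = 0.5 * (var + var.T)
    eigval, eigvec = np.linalg.eigh(var)
    eigval = np.maximum(eigval, floor)
    return (eigvec * eigval) @ eigvec.T


def _log_gauss(X: np.ndarray, mu: np.ndarray, var: np.ndarray, cov_type: str) -> np.ndarray:
    if cov_type == "diag":
        diff = X - mu
        return -0.5 * (
            np.sum(diff * diff / var, axis=1)
            + np.sum(np.log(2.0 * np.pi * var))
        )
    d = len(mu)
    diff = X - mu
    chol = np.linalg.cholesky(var)
    sol = np.linalg.solve(chol, diff.T)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (np.sum(sol * sol, axis=0) + logdet + d * np.log(2.0 * np.pi))


def _log_obs(state: BGMMState, pool: LabelledPool) -> np.ndarray:
    """Per-sample, per-class log of α_c · N(x) · Π B(u) [· Π N(v)]; shape (N, 2)."""
    N = pool.N
    out = np.empty((N, 2))
    for c in range(2):
        lg = _log_gauss(pool.X, state.mu[c], state.var[c], state.cov_type)
        p = np.clip(state.pi[c], _PI_EPS, 1.0 - _PI_EPS)
        bern = pool.H * (pool.U * np.log(p) + (1.0 - pool.U) * np.log1p(-p))
        total = lg + bern.sum(axis=1) + np.log(state.alpha[c] + 1e-300)
        if state.use_soft:
            m = pool.U.astype(int)
            lam = state.lam[c][m, np.arange(state.K)]
            s2 = state.sigma2[c][m, np.arange(state.K)]
            soft = pool.H * (
                -0.5 * ((pool.V - lam) ** 2 / s2 + np.log(2.0 * np.pi * s2))
            )
            total = total + soft.sum(axis=1)
        out[:, c] = total
    return out


def init_bgmm(
    pool: LabelledPool,
    seed: int = 0,
    cov_type: str = "diag",
    use_soft: bool = True,
) -> BGMMState:
    """Initialize from labelled per-class moments (deterministic given seed).

    Labelled proportions give α, labelled moments give μ and Σ, and the
    crisp-history agreement rates give π.  Classes lacking history fall
    back to uninformative defaults (π = 0.5, λ = 0.5, σ² = 1/12).
    """
    lab = pool.labelled
    if lab.size == 0:
        raise ValueError("pool has no labelled samples")
    y_lab = pool.y[lab]
    if len(np.unique(y_lab)) < 2:
        raise ValueError("both classes must be present among labelled samples")
    d, K = pool.d, pool.K
    rng = np.random.default_rng(seed)
    alpha = np.array([(y_lab == 0).mean(), (y_lab == 1).mean()])
    mu = np.empty((2, d))
    var = np.empty((2, d)) if cov_type == "diag" else np.empty((2, d, d))
    pi = np.full((2, K), 0.5)
    lam = np.full((2, 2, K), 0.5)
    sigma2 = np.full((2, 2, K), 1.0 / 12.0)
    global_var = pool.X.var(axis=0) + 1e-6
    floor = _variance_floor(pool.X, cov_type)
    for c in range(2):
        rows = lab[y_lab == c]
        Xc = pool.X[rows]
        mu[c] = Xc.mean(axis=0) + 1e-9 * rng.standard_normal(d)
        if cov_type == "diag":
            v = Xc.var(axis=0) if len(Xc) > 1 else global_var
            v = np.where(v < 1e-12, global_var, v)
            var[c] = _regularize_var(v, cov_type, floor)
        else:
            v = np.cov(Xc.T) if len(Xc) > d else np.diag(global_var)
            var[c] = _regularize_var(np.atleast_2d(v), cov_type, floor)
        Hc, Uc, Vc = pool.H[rows], pool.U[rows], pool.V[rows]
        denom = Hc.sum(axis=0)
        with np.errstate(invalid="ignore"):
            agree = np.where(denom > 0, (Hc * Uc).sum(axis=0) / np.maximum(denom, 1), 0.5)
        pi[c] = np.clip(agree, _PI_EPS, 1.0 - _PI_EPS)
        for m in range(2):
            sel = Hc & (Uc == m)
            nm = sel.sum(axis=0)
            vm = np.where(nm > 0, (sel * Vc).sum(axis=0) / np.maximum(nm, 1), 0.5)
            lam[c, m] = vm
            dev = sel * (Vc - vm) ** 2
            s2 = np.where(nm > 1, dev.sum(axis=0) / np.maximum(nm, 1), 1.0 / 12.0)
            sigma2[c, m] = np.maximum(s2, _MIN_SIGMA2)
    state = BGMMState(
        alpha=alpha,
        mu=mu,
        var=var,
        pi=pi,
        lam=lam,
        sigma2=sigma2,
        resp=np.zeros((pool.N, 2)),
        cov_type=cov_type,
        use_soft=use_soft,
        var_floor=floor,
    )
    return state


def e_step(state: BGMMState, pool: LabelledPool) -> np.ndarray:
    """Responsibilities: indicators for labelled rows, posteriors otherwise."""
    log_obs = _log_obs(state, pool)
    if not np.all(np.isfinite(log_obs)):
        raise FloatingPointError("non-finite component density in E-step")
    log_norm = logsumexp(log_obs, axis=1, keepdims=True)
    resp = np.exp(log_obs - log_norm)
    lab = pool.labelled
    resp[lab] = 0.0
    resp[lab, pool.y[lab]] = 1.0
    return resp


def m_step(state: BGMMState, pool: LabelledPool, resp: np.ndarray) -> BGMMState:
    """Responsibility-weighted ML updates of α, μ, Σ, π and the soft-label moments."""
    N, d, K = pool.N, pool.d, pool.K
    mass = resp.sum(axis=0)
    if np.any(mass <= 0):
        c = int(np.argmin(mass))
        raise ClassCollapseError(f"class {c} collapsed: zero responsibility mass")
    alpha = mass / N
    mu = (resp.T @ pool.X) / mass[:, None]
    if state.cov_type == "diag":
        var = np.empty((2, d))
        for c in range(2):
            diff = pool.X - mu[c]
            var[c] = _regularize_var(
                (resp[:, c] @ (diff * diff)) / mass[c], "diag", state.var_floor
            )
    else:
        var = np.empty((2, d, d))
        for c in range(2):
            diff = pool.X - mu[c]
            var[c] = _regularize_var(
                (diff.T * resp[:, c]) @ diff / mass[c], "full", state.var_floor
            )
    pi = np.empty((2, K))
    lam = state.lam.copy()
    sigma2 = state.sigma2.copy()
    for c in range(2):
        w = resp[:, c][:, None] * pool.H
        denom = w.sum(axis=0)
        pi[c] = np.clip(
            np.where(denom > 0, (w * pool.U).sum(axis=0) / np.maximum(denom, 1e-300), 0.5),
            _PI_EPS,
            1.0 - _PI_EPS,
        )
        for m in range(2):
            wm = resp[:, c][:, None] * (pool.H & (pool.U == m))
            nm = wm.sum(axis=0)
            vm = np.where(nm > 0, (wm * pool.V).sum(axis=0) / np.maximum(nm, 1e-300), 0.5)
            lam[c, m] = vm
            s2 = np.where(
                nm > 0,
                (wm * (pool.V - vm) ** 2).sum(axis=0) / np.maximum(nm, 1e-300),
                1.0 / 12.0,
            )
            sigma2[c, m] = np.maximum(s2, _MIN_SIGMA2)
    return BGMMState(
        alpha=alpha,
        mu=mu,
        var=var,
        pi=pi,
        lam=lam,
        sigma2=sigma2,
        resp=resp,
        loglik_trace=state.loglik_trace,
        cov_type=state.cov_type,
        use_soft=state.use_soft,
        converged=state.converged,
        var_floor=state.var_floor,
    )


def _observed_loglik(state: BGMMState, pool: LabelledPool) -> float:
    log_obs = _log_obs(state, pool)
    lab, unlab = pool.labelled, pool.unlabelled
    total = float(log_obs[lab, pool.y[lab]].sum())
    if unlab.size:
        total += float(logsumexp(log_obs[unlab], axis=1).sum())
    return total


def fit_bgmm(
    pool: LabelledPool,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    cov_type: str = "diag",
    use_soft: bool = True,
) -> BGMMState:
    """Run semi-supervised EM to convergence of the observed-data log-likelihood.

    The trace is non-decreasing (within 1e-8); hitting ``max_iter`` without
    convergence returns the state flagged ``converged=False`` rather than
    raising.
    """
    state = init_bgmm(pool, seed=seed, cov_type=cov_type, use_soft=use_soft)
    previous = -np.inf
    for _ in range(max_iter):
        resp = e_step(state, pool)
        state = m_step(state, pool, resp)
        current = _observed_loglik(state, pool)
        state.loglik_trace.append(current)
        if current < previous - _LL_TOL:
            raise FloatingPointError(
                f"EM log-likelihood decreased: {previous} -> {current}"
            )
        if current - previous < tol:
            state.converged = True
            break
        previous = current
    state.resp = e_step(state, pool)
    return state


def select_least_confident(
    state: BGMMState, candidates: np.ndarray, batch_size: int = 1
) -> np.ndarray:
    """Indices of the ``batch_size`` most ambiguous candidates.

    Ambiguity is 1 − max_c γ_{j,c}; ties break toward the lowest index.  An
    empty candidate set yields an empty selection; a batch larger than the
    candidate set returns all candidates, ambiguity-sorted.
    """
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return candidates
    candidates = np.sort(candidates)
    ambiguity = 1.0 - state.resp[candidates].max(axis=1)
    order = np.argsort(-ambiguity, kind="stable")
    return candidates[order[: min(batch_size, candidates.size)]]


def stopping_check(confidence_history: list[float], window: int = 2, tol: float = 1e-3) -> bool:
    """True when the last ``window`` successive confidence changes are all < tol."""
    if len(confidence_history) < window + 1:
        return False
    recent = np.asarray(confidence_history[-(window + 1) :])
    return bool(np.all(np.abs(np.diff(recent)) < tol))


@dataclass
class Oracle:
    """A label source (ground truth in tests) with a query budget and log."""

    labels: np.ndarray
    budget: int
    log: list[int] = field(default_factory=list)

    @property
    def remaining(self) -> int:
        return self.budget - len(self.log)

    def query(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=int)[: max(self.remaining, 0)]
        self.log.extend(int(i) for i in indices)
        return self.labels[indices]


def active_learning_round(
    pool: LabelledPool,
    model: ClassifierModel,
    oracle: Oracle,
    batch_size: int = 1,
    seed: int = 0,
    certainty_cutoff: float = 0.80,
    cov_type: str = "diag",
    use_soft: bool = True,
    stop_tol: float = 1e-3,
    stop_window: int = 2,
    max_iter: int = 100,
    output_noise: float = 0.0,
    noise_rng: np.random.Generator | None = None,
) -> tuple[LabelledPool, ClassifierModel, bool]:
    """One query round: classify, fit the BGMM, query the expert, retrain.

    Returns the updated pool, the (possibly retrained) model and a stop
    flag.  An exhausted budget or an empty ambiguous set stops immediately;
    otherwise the flat-confidence criterion decides.  ``output_noise``
    flips each crisp label feeding the mixture with that probability,
    emulating base-classifier misclassification noise.
    """
    if oracle.remaining <= 0:
        return pool, model, True
    out = predict(model, pool.X)
    crisp_in = out.crisp.astype(float)
    if output_noise > 0.0:
        rng = noise_rng if noise_rng is not None else np.random.default_rng(seed)
        flip = rng.random(len(crisp_in)) < output_noise
        crisp_in = np.where(flip, 1.0 - crisp_in, crisp_in)
    pool.record_outputs(crisp_in, out.soft)
    _, ambiguous = partition_ambiguous(out, certainty_cutoff)
    candidates = np.intersect1d(ambiguous, pool.unlabelled)
    if candidates.size < batch_size:
        # not enough classifier-ambiguous windows: rank the whole unlabelled
        # set by mixture ambiguity instead
        candidates = pool.unlabelled
    if candidates.size == 0:
        return pool, model, True
    state = fit_bgmm(
        pool, seed=seed, cov_type=cov_type, use_soft=use_soft, max_iter=max_iter
    )
    selected = select_least_confident(state, candidates, batch_size)
    answers = oracle.query(selected)
    pool.y[selected[: len(answers)]] = answers
    lab = pool.labelled
    if len(np.unique(pool.y[lab])) == 2:
        model = train(pool.X[lab], pool.y[lab], algorithm=model.algorithm, seed=model.seed)
    pool.confidence_history.append(float(state.resp.max(axis=1).mean()))
    stop = stopping_check(pool.confidence_history, window=stop_window, tol=stop_tol)
    return pool, model, stop


def run_learning_loop(
    X: np.ndarray,
    y_observed: np.ndarray,
    oracle: Oracle,
    algorithm: str = "svm",
    method: str = "bgmm",
    batch_size: int = 1,
    seed: int = 0,
    K: int = 10,
    max_rounds: int | None = None,
    output_noise: float = 0.0,
    **round_kwargs,
) -> tuple[ClassifierModel, LabelledPool]:
    """Drive query rounds until the budget is spent or the learner stops.

    ``method`` selects the query strategy: ``bgmm`` (least-confident under
    the mixture posterior), ``uncertainty`` (smallest classifier soft
    label) or ``random`` (passive baseline).  ``y_observed`` holds −1 for
    initially unlabelled samples.
    """
    if method not in ("bgmm", "uncertainty", "random"):
        raise ValueError(f"unknown selection method {method!r}")
    pool = LabelledPool.create(X, y_observed, K=K)
    lab = pool.labelled
    model = train(X[lab], pool.y[lab], algorithm=algorithm, seed=seed)
    rng = np.random.default_rng(seed)
    noise_rng = np.random.default_rng(seed + 77)
    rounds = 0
    limit = max_rounds if max_rounds is not None else int(np.ceil(oracle.budget / batch_size)) + 1
    while oracle.remaining > 0 and rounds < limit:
        rounds += 1
        if method == "bgmm":
            pool, model, stop = active_learning_round(
                pool,
                model,
                oracle,
                batch_size=batch_size,
                seed=seed,
                output_noise=output_noise,
                noise_rng=noise_rng,
                **round_kwargs,
            )
            if stop:
                break
            continue
        unlab = pool.unlabelled
        if unlab.size == 0:
            break
        if method == "random":
            pick = rng.choice(unlab, size=min(batch_size, unlab.size), replace=False)
        else:  # uncertainty sampling on the classifier's own soft labels
            out = predict(model, X[unlab])
            order = np.argsort(out.soft, kind="stable")
            pick = unlab[order[: min(batch_size, unlab.size)]]
        answers = oracle.query(pick)
        pool.y[pick[: len(answers)]] = answers
        lab = pool.labelled
        if len(np.unique(pool.y[lab])) == 2:
            model = train(X[lab], pool.y[lab], algorithm=algorithm, seed=seed)
    return model, pool
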