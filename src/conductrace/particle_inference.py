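"""Sequential Monte Carlo branch: per-trial particle filtering + EM (MtPF).

The particle filter replaces the Gaussian posterior of the Kalman branch by
a weighted particle ensemble, with the synaptic inputs proposed from
exponential priors p[N(t)] = (1/mu(t)) exp(-N(t)/mu(t)) — nonnegative by
construction, so no projection step is needed.  A bootstrap proposal
propagates each particle through the membrane recursion, weights are the
Gaussian observation likelihoods, and systematic resampling is triggered
when the effective sample size drops below half the ensemble.

The multiple-trial EM update for the particle branch is means-only: the
common input mean is the plain across-trial average of the per-trial
posterior input means (the exponential family has a single parameter), and
the noise variances stay fixed.  Smoothed expectations use fixed-lag
ancestral tracing: x(t) is averaged over the ensemble a fixed number of
steps ahead, far enough to exhaust the synaptic time constants but short
enough to avoid the path-coalescence degeneracy of full ancestral-path
averaging on long records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .em_multitrial import EMTrace, _pad_series
from .kalman_inference import ConductanceEstimate
from .passive_model import ModelParams, TrialSet

__all__ = [
    "ParticleEnsemble",
    "pf_forward",
    "update_common_means",
    "fit_mtpf",
    "baseline_avg_of_stpf",
    "baseline_stpf_of_avg",
]

MU_FLOOR = 1e-7  # μS; keeps the exponential input density proper


@dataclass
class ParticleEnsemble:
    """Particle representation of one trial's filtering distribution."""

    particles: np.ndarray  # (T, N_p, 3)
    weights: np.ndarray    # (T, N_p), normalized at every step
    ess: np.ndarray        # (T,)
    ancestry: np.ndarray   # (T, N_p): parent indices chosen at each step
    loglik: float


def _systematic_resample(W: np.ndarray, u: float) -> np.ndarray:
    """Systematic resampling indices for one weight vector."""
    N = W.size
    positions = (np.arange(N) + u) / N
    return np.searchsorted(np.cumsum(W), positions).clip(0, N - 1)


def _pf_batch(y, params: ModelParams, mu_E, mu_I, sigma_w2, sigma_eps,
              N_p, rng, input_dist="exponential", gamma_E=None, gamma_I=None,
              resample_threshold=0.5, store_ensemble=False,
              init_g_std=None, lag=15):
    """Bootstrap particle filter batched over trials.

    ``mu_E``/``mu_I`` are per-trial (L, T) mean-input series; entry t drives
    the transition t -> t+1.  In the default ``exponential`` mode inputs are
    drawn from exponentials with those means; the ``gaussian`` mode (used as
    a linear-Gaussian surrogate for cross-checking against the Kalman
    filter) draws from Normal(mu, gamma) without truncation.

    Returns a dict with per-trial loglik, filtered V means and their Monte
    Carlo standard errors, fixed-lag smoothed means of the state and
    inputs (``lag`` steps of look-ahead), and (optionally) the full
    ensemble of trial 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    L, T = y.shape
    if N_p < 2:
        raise ValueError("at least two particles are required")
    mu_E = np.maximum(np.asarray(mu_E, dtype=float), MU_FLOOR)
    mu_I = np.maximum(np.asarray(mu_I, dtype=float), MU_FLOOR)
    se2 = float(sigma_eps) ** 2
    sw = np.sqrt(float(sigma_w2))
    rows = np.arange(L)[:, None]

    X_store = np.empty((T, L, N_p, 3))
    NE_store = np.empty((max(T - 1, 0), L, N_p))
    NI_store = np.empty((max(T - 1, 0), L, N_p))
    anc = np.empty((T, L, N_p), dtype=np.intp)
    anc[0] = np.arange(N_p)
    W_hist = np.empty((T, L, N_p))
    ess_hist = np.empty((T, L))
    loglik = np.zeros(L)

    # initial ensemble around the first observation / stationary drive
    gE0 = mu_E[:, 0] * params.tau_E / params.dt
    gI0 = mu_I[:, 0] * params.tau_I / params.dt
    X = np.empty((L, N_p, 3))
    X[:, :, 0] = y[:, 0:1] + np.sqrt(se2 + 1.0) * rng.standard_normal((L, N_p))
    if init_g_std is not None:
        X[:, :, 1] = gE0[:, None] + init_g_std * rng.standard_normal((L, N_p))
        X[:, :, 2] = gI0[:, None] + init_g_std * rng.standard_normal((L, N_p))
    elif input_dist == "exponential":
        X[:, :, 1] = rng.exponential(1.0, (L, N_p)) * gE0[:, None]
        X[:, :, 2] = rng.exponential(1.0, (L, N_p)) * gI0[:, None]
    else:
        X[:, :, 1] = gE0[:, None] + (10.0 * gE0[:, None] + 1e-3) \
            * rng.standard_normal((L, N_p))
        X[:, :, 2] = gI0[:, None] + (10.0 * gI0[:, None] + 1e-3) \
            * rng.standard_normal((L, N_p))

    logW = np.full((L, N_p), -np.log(N_p))
    filt_V = np.empty((L, T))
    filt_V_se = np.empty((L, T))

    def _weight_and_record(t, X, logW):
        llt = -0.5 * ((y[:, t, None] - X[:, :, 0]) ** 2 / se2
                      + np.log(2.0 * np.pi * se2))
        m = np.max(logW + llt, axis=1, keepdims=True)
        incr = m[:, 0] + np.log(np.sum(np.exp(logW + llt - m), axis=1))
        logW = logW + llt
        mx = logW.max(axis=1, keepdims=True)
        W = np.exp(logW - mx)
        W /= W.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):   # zero weights are legitimate
            logW = np.log(W)
        return W, logW, incr

    W, logW, incr = _weight_and_record(0, X, logW)
    loglik += incr
    X_store[0] = X
    W_hist[0] = W
    ess_hist[0] = 1.0 / np.sum(W ** 2, axis=1)
    filt_V[:, 0] = np.sum(W * X[:, :, 0], axis=1)
    var0 = np.sum(W * (X[:, :, 0] - filt_V[:, 0:1]) ** 2, axis=1)
    filt_V_se[:, 0] = np.sqrt(var0 / ess_hist[0])

    k = params.dt / params.C_m
    for t in range(1, T):
        # resample trial rows whose ESS fell below the threshold
        a = np.broadcast_to(np.arange(N_p), (L, N_p)).copy()
        ess = 1.0 / np.sum(W ** 2, axis=1)
        for i in np.flatnonzero(ess < resample_threshold * N_p):
            a[i] = _systematic_resample(W[i], rng.uniform())
            W[i] = 1.0 / N_p
            logW[i] = -np.log(N_p)
        anc[t] = a
        Xp = X[rows, a]

        if input_dist == "exponential":
            NE = rng.exponential(1.0, (L, N_p)) * mu_E[:, t - 1][:, None]
            NI = rng.exponential(1.0, (L, N_p)) * mu_I[:, t - 1][:, None]
        else:
            NE = mu_E[:, t - 1][:, None] + np.sqrt(gamma_E[:, t - 1])[:, None] \
                * rng.standard_normal((L, N_p))
            NI = mu_I[:, t - 1][:, None] + np.sqrt(gamma_I[:, t - 1])[:, None] \
                * rng.standard_normal((L, N_p))
        w = sw * rng.standard_normal((L, N_p))

        V, gE, gI = Xp[:, :, 0], Xp[:, :, 1], Xp[:, :, 2]
        Xn = np.empty_like(Xp)
        Xn[:, :, 0] = V + k * (params.g_L * (params.E_L - V)
                               + gE * (params.E_E - V)
                               + gI * (params.E_I - V) + params.I_inj) + w
        Xn[:, :, 1] = gE * params.decay_E + NE
        Xn[:, :, 2] = gI * params.decay_I + NI
        X = Xn
        NE_store[t - 1] = NE
        NI_store[t - 1] = NI

        W, logW, incr = _weight_and_record(t, X, logW)
        loglik += incr
        X_store[t] = X
        W_hist[t] = W
        ess_hist[t] = 1.0 / np.sum(W ** 2, axis=1)
        filt_V[:, t] = np.sum(W * X[:, :, 0], axis=1)
        var_t = np.sum(W * (X[:, :, 0] - filt_V[:, t][:, None]) ** 2, axis=1)
        filt_V_se[:, t] = np.sqrt(var_t / ess_hist[t])

    # fixed-lag smoothing: condition x(t) on observations up to t+lag by
    # tracing ancestral paths back from the ensemble at s = t+lag.  A full
    # ancestral-path average under the final weights degenerates over long
    # records (path coalescence), whereas the synaptic time constants make
    # observations more than a few tens of ms ahead uninformative anyway.
    sm_x = np.empty((L, T, 3))
    sm_g_var = np.empty((L, T, 2))
    sm_NE = np.empty((L, max(T - 1, 0)))
    sm_NI = np.empty((L, max(T - 1, 0)))
    for t in range(T):
        s = min(t + lag, T - 1)
        idx = np.broadcast_to(np.arange(N_p), (L, N_p))
        for j in range(s, t, -1):
            idx = anc[j][rows, idx]
        Ws = W_hist[s]
        xs = X_store[t][rows, idx]
        sm_x[:, t] = np.einsum("lp,lpc->lc", Ws, xs)
        dev = xs[:, :, 1:] - sm_x[:, t, None, 1:]
        sm_g_var[:, t] = np.einsum("lp,lpc->lc", Ws, dev ** 2)
        if t >= 1:
            # N(t-1) is indexed like particles at time t: reuse idx
            sm_NE[:, t - 1] = np.sum(Ws * NE_store[t - 1][rows, idx], axis=1)
            sm_NI[:, t - 1] = np.sum(Ws * NI_store[t - 1][rows, idx], axis=1)

    out = {"loglik": loglik, "filt_V": filt_V, "filt_V_se": filt_V_se,
           "sm_x": sm_x, "sm_g_var": sm_g_var, "sm_NE": sm_NE,
           "sm_NI": sm_NI, "ess": ess_hist.T, "weights_final": W}
    if store_ensemble:
        out["ensemble"] = ParticleEnsemble(
            particles=X_store[:, 0], weights=W_hist[:, 0],
            ess=ess_hist[:, 0], ancestry=anc[:, 0], loglik=float(loglik[0]))
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def pf_forward(y, params: ModelParams, mu_E, mu_I, sigma_eps: float,
               N_p: int = 1000, seed=None, sigma_w2: float | None = None,
               resample_threshold: float = 0.5):
    """Particle filter one trial with exponential input priors.

    Returns ``(ParticleEnsemble, smoothed)`` where ``smoothed`` maps
    ``{"g_E", "g_I", "V"}`` to fixed-lag smoothed means (length T) and
    ``{"N_E", "N_I"}`` to smoothed input expectations (length T-1).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a single trial (1-D array)")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sw2 = params.sigma_w ** 2 if sigma_w2 is None else sigma_w2
    res = _pf_batch(y[None], params, np.atleast_2d(mu_E), np.atleast_2d(mu_I),
                    sw2, sigma_eps, N_p, rng,
                    resample_threshold=resample_threshold,
                    store_ensemble=True)
    smoothed = {"V": res["sm_x"][0, :, 0], "g_E": res["sm_x"][0, :, 1],
                "g_I": res["sm_x"][0, :, 2], "N_E": res["sm_NE"][0],
                "N_I": res["sm_NI"][0]}
    return res["ensemble"], smoothed


def update_common_means(per_trial_means) -> np.ndarray:
    """Means-only M-step: plain average of per-trial posterior input means."""
    stacked = np.stack([np.asarray(m, dtype=float) for m in per_trial_means])
    return stacked.mean(axis=0)


def _fit_pf_grouped(trials: TrialSet, params: ModelParams, mu0_E, mu0_I,
                    groups, sigma_eps, N_p, max_iter, rel_tol, seed,
                    sigma_w2, resample_threshold=0.5, lag=15):
    """Grouped particle-filter EM (shared engine for MtPF and baselines)."""
    y = trials.y
    L, T = y.shape
    groups = np.asarray(groups)
    gids = np.unique(groups)
    sw2 = params.sigma_w ** 2 if sigma_w2 is None else sigma_w2
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    mu0 = 0.1 * params.g_L * params.dt
    mu_E_group = {g: np.full(T, mu0) if mu0_E is None
                  else np.asarray(mu0_E, dtype=float).copy() for g in gids}
    mu_I_group = {g: np.full(T, mu0) if mu0_I is None
                  else np.asarray(mu0_I, dtype=float).copy() for g in gids}

    trace = EMTrace()
    mu_E = np.empty((L, T))
    mu_I = np.empty((L, T))
    res = None
    prev_ll = None
    for it in range(max_iter):
        for g in gids:
            sel = groups == g
            mu_E[sel] = mu_E_group[g]
            mu_I[sel] = mu_I_group[g]
        res = _pf_batch(y, params, mu_E, mu_I, sw2, sigma_eps, N_p, rng,
                        resample_threshold=resample_threshold, lag=lag)
        ll = float(res["loglik"].sum())
        if not np.isfinite(ll):
            err = RuntimeError(f"particle EM diverged at iteration {it}")
            err.last_stats = (mu_E_group, mu_I_group)
            raise err
        trace.loglik.append(ll)
        trace.n_iter = it + 1
        if prev_ll is not None:
            rel = (ll - prev_ll) / abs(prev_ll)
            if abs(rel) < rel_tol:
                trace.converged = True
                break
        prev_ll = ll
        for g in gids:
            sel = np.flatnonzero(groups == g)
            mu_E_group[g] = _pad_series(np.maximum(
                update_common_means([res["sm_NE"][i] for i in sel]), MU_FLOOR))
            mu_I_group[g] = _pad_series(np.maximum(
                update_common_means([res["sm_NI"][i] for i in sel]), MU_FLOOR))
        trace.theta_history.append({g: (mu_E_group[g].copy(),
                                        mu_I_group[g].copy()) for g in gids})

    est = ConductanceEstimate(
        g_E=res["sm_x"][:, :, 1], g_I=res["sm_x"][:, :, 2],
        std_E=np.sqrt(res["sm_g_var"][:, :, 0]),
        std_I=np.sqrt(res["sm_g_var"][:, :, 1]))
    return mu_E_group, mu_I_group, est, trace


def fit_mtpf(trials: TrialSet, params: ModelParams, mu0_E=None, mu0_I=None,
             sigma_eps: float = 1.0, N_p: int = 1000, max_iter: int = 10,
             rel_tol: float = 1e-3, seed=None, sigma_w2: float | None = None,
             resample_threshold: float = 0.5, lag: int = 15):
    """Multiple-trial particle-filter EM.

    Pools the per-trial smoothed input expectations into common mean series
    each iteration (means-only update).  Returns
    ``(mu_E, mu_I, ConductanceEstimate, EMTrace)``.
    """
    groups = np.zeros(trials.L, dtype=int)
    muE, muI, est, trace = _fit_pf_grouped(trials, params, mu0_E, mu0_I,
                                           groups, sigma_eps, N_p, max_iter,
                                           rel_tol, seed, sigma_w2,
                                           resample_threshold, lag)
    return muE[0], muI[0], est, trace


def fit_stpf_per_trial(trials: TrialSet, params: ModelParams, mu0_E=None,
                       mu0_I=None, sigma_eps: float = 1.0, N_p: int = 1000,
                       max_iter: int = 10, rel_tol: float = 1e-3, seed=None,
                       sigma_w2: float | None = None):
    """Independent single-trial particle-filter EM fits (StPF), one per trial."""
    groups = np.arange(trials.L)
    muE, muI, est, trace = _fit_pf_grouped(trials, params, mu0_E, mu0_I,
                                           groups, sigma_eps, N_p, max_iter,
                                           rel_tol, seed, sigma_w2)
    return muE, muI, est, trace


def baseline_avg_of_stpf(trials: TrialSet, params: ModelParams, **kw
                         ) -> ConductanceEstimate:
    """Average of independent StPF estimates (trial-average baseline)."""
    _, _, est, _ = fit_stpf_per_trial(trials, params, **kw)
    L = trials.L
    return ConductanceEstimate(
        g_E=np.tile(est.g_E.mean(axis=0), (L, 1)),
        g_I=np.tile(est.g_I.mean(axis=0), (L, 1)),
        std_E=np.tile(np.sqrt((est.std_E ** 2).mean(axis=0) / L), (L, 1)),
        std_I=np.tile(np.sqrt((est.std_I ** 2).mean(axis=0) / L), (L, 1)))


def baseline_stpf_of_avg(trials: TrialSet, params: ModelParams,
                         sigma_eps: float = 1.0, **kw) -> ConductanceEstimate:
    """StPF applied to the trial-averaged membrane potential."""
    avg = TrialSet(y=trials.y.mean(axis=0, keepdims=True), dt=trials.dt)
    _, _, est, _ = fit_mtpf(avg, params,
                            sigma_eps=sigma_eps / np.sqrt(trials.L), **kw)
    L = trials.L
    return ConductanceEstimate(g_E=np.tile(est.g_E[0], (L, 1)),
                               g_I=np.tile(est.g_I[0], (L, 1)),
                               std_E=np.tile(est.std_E[0], (L, 1)),
                               std_I=np.tile(est.std_I[0], (L, 1)))
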