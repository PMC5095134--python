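"""Multiple-trial EM for common synaptic-input statistics (MtKF).

Repeated current-clamp trials share the time-varying statistics of their
synaptic drive even though each trial receives a different realization.
The multiple-trial Kalman filter (MtKF) exploits this: an E-step runs the
extended Kalman filter/smoother independently on every trial under the
current common statistics θ = (mu_E, mu_I, gamma_E, gamma_I, sigma_w^2,
sigma_eps^2); the M-step pools the per-trial posterior input moments,

    mu(t)    = (1/L) Σ_i mu_i(t)
    gamma(t) = (1/L) Σ_i { gamma_i(t) + (mu(t) - mu_i(t))^2 }

(the law of total variance over trials), and — after a warm-up phase that
lets the means absorb the stimulus-locked structure — re-estimates the
observation noise variance.  Iteration stops when the relative change of
the total log-likelihood falls below a small tolerance.  No temporal
smoothing of the statistics is ever applied — pooling across trials
replaces it.

The single-trial estimator (StKF) is the L = 1 special case, and the two
simple-averaging baselines from the literature (average the per-trial StKF
estimates; run StKF on the trial-averaged trace) are provided for
comparison.  All of them route through one grouped batched engine, so
MtKF on a single trial and StKF are bit-identical by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kalman_inference import (ConductanceEstimate, StatePosterior,
                               run_batch)
from .passive_model import InputStats, ModelParams, TrialSet

__all__ = [
    "PerTrialInputStats",
    "EMTrace",
    "default_theta0",
    "extract_trial_input_stats",
    "update_common_stats",
    "update_noise_variances",
    "fit_mtkf",
    "fit_stkf_per_trial",
    "baseline_avg_of_stkf",
    "baseline_stkf_of_avg",
]

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12  # keeps the innovation variance strictly positive


@dataclass
class PerTrialInputStats:
    """Posterior moments of one trial's synaptic inputs (length T-1 series)."""

    mu_E: np.ndarray
    mu_I: np.ndarray
    gamma_E: np.ndarray
    gamma_I: np.ndarray
    n_clipped: int = 0  # negative posterior input variances clipped to 0


@dataclass
class EMTrace:
    """Per-iteration diagnostics of one EM run."""

    loglik: list = field(default_factory=list)
    theta_history: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    n_var_clips: int = 0
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# E-step plumbing: posterior input moments
# ---------------------------------------------------------------------------

def _extract_batch(m_s, P_s, P_lag, params: ModelParams):
    """Batched posterior input moments from smoothed state moments.

    Inverting the conductance recursion, N(t) = g(t+1) - a g(t) with
    a = 1 - dt/tau, so the posterior mean and variance of each input follow
    from the smoothed means, variances and lag-one cross-covariances of the
    conductance coordinates.  Per-trial means are left unfloored — clipping
    them before pooling would bias the common mean upward by the posterior
    noise; nonnegativity is imposed on the pooled common statistics instead.
    Numerically negative variances are clipped and counted.
    """
    out = {}
    clips = 0
    for name, idx, a in (("E", 1, params.decay_E), ("I", 2, params.decay_I)):
        g_next = m_s[:, 1:, idx]
        g_prev = m_s[:, :-1, idx]
        mu = g_next - a * g_prev
        var = (P_s[:, 1:, idx, idx] + a * a * P_s[:, :-1, idx, idx]
               - 2.0 * a * P_lag[:, :, idx, idx])
        clips += int(np.sum(var < 0))
        out["mu_" + name] = mu
        out["gamma_" + name] = np.maximum(var, 0.0)
    return out, clips


def extract_trial_input_stats(post: StatePosterior,
                              params: ModelParams) -> PerTrialInputStats:
    """Posterior mean/variance series of one trial's synaptic inputs."""
    d, clips = _extract_batch(post.m_smooth[None], post.P_smooth[None],
                              post.P_lag[None], params)
    if clips:
        logger.debug("clipped %d negative input variances", clips)
    return PerTrialInputStats(mu_E=d["mu_E"][0], mu_I=d["mu_I"][0],
                              gamma_E=d["gamma_E"][0], gamma_I=d["gamma_I"][0],
                              n_clipped=clips)


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------

def update_common_stats(per_trial):
    """Pool per-trial input moments into common statistics.

    Accepts a list of :class:`PerTrialInputStats`.  Returns
    ``(mu_E, gamma_E, mu_I, gamma_I)`` series of length T-1: the common mean
    is the across-trial average; the common variance is the average
    within-trial posterior variance plus the across-trial spread of the
    per-trial means.
    """
    if len(per_trial) < 1:
        raise ValueError("at least one trial is required")
    T1 = per_trial[0].mu_E.size
    for p in per_trial:
        if not (p.mu_E.size == p.mu_I.size == p.gamma_E.size
                == p.gamma_I.size == T1):
            raise ValueError("per-trial series lengths differ")
    out = []
    for mu_name, g_name in (("mu_E", "gamma_E"), ("mu_I", "gamma_I")):
        mus = np.stack([getattr(p, mu_name) for p in per_trial])
        gams = np.stack([getattr(p, g_name) for p in per_trial])
        mu = mus.mean(axis=0)
        gamma = (gams + (mu[None, :] - mus) ** 2).mean(axis=0)
        out += [mu, gamma]
    return out[0], out[1], out[2], out[3]


def update_noise_variances(trials: TrialSet, posteriors,
                           params: ModelParams):
    """EM update of the dynamics and observation noise variances.

    sigma_eps^2 is the average posterior expectation of (y - V)^2;
    sigma_w^2 the average posterior expectation of the squared V-row
    transition residual, both expanded through the smoothed means,
    variances and lag-one covariances.  Negative values (numerical) are
    clipped at a tiny floor.
    """
    y = trials.y
    se_terms = []
    sw_terms = []
    k = params.dt / params.C_m
    for i, post in enumerate(posteriors):
        m, P = post.m_smooth, post.P_smooth
        se_terms.append(np.mean((y[i] - m[:, 0]) ** 2 + P[:, 0, 0]))
        V, gE, gI = m[:-1, 0], m[:-1, 1], m[:-1, 2]
        f_V = V + k * (params.g_L * (params.E_L - V) + gE * (params.E_E - V)
                       + gI * (params.E_I - V) + params.I_inj)
        r = m[1:, 0] - f_V
        a = np.empty((V.size, 3))
        a[:, 0] = 1.0 - k * (params.g_L + gE + gI)
        a[:, 1] = k * (params.E_E - V)
        a[:, 2] = k * (params.E_I - V)
        quad = np.einsum("ti,tij,tj->t", a, P[:-1], a)
        cross = np.einsum("ti,ti->t", post.P_lag[:, 0, :], a)
        sw_terms.append(np.mean(r * r + P[1:, 0, 0] + quad - 2.0 * cross))
    sigma_eps2 = max(float(np.mean(se_terms)), _VAR_FLOOR)
    sigma_w2 = max(float(np.mean(sw_terms)), 0.0)
    return sigma_w2, sigma_eps2


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def default_theta0(trials: TrialSet, params: ModelParams) -> InputStats:
    """Data-scaled starting statistics for the EM loop.

    The tonic drive implied by the observed mean depolarization fixes the
    overall input scale: assuming equal excitatory and inhibitory tonic
    conductances g0, the steady state of the membrane equation at the
    observed mean potential gives
    g0 = -(g_L (E_L - ybar) + I_inj) / ((E_E - ybar) + (E_I - ybar)).
    The inversion is singular when ybar approaches the midpoint of the two
    synaptic reversals, so it is only used while ybar is clearly
    hyperpolarized of that midpoint (and clamped to [0.02 g_L, 2 g_L]);
    otherwise the minimal-drive prior 0.02 g_L is used — a badly scaled
    starting drive is self-confirming because large opposing conductances
    explain a voltage trace almost as well as small ones.
    Input means start flat at the per-step increments sustaining g0;
    variances start at (2 mu0)^2 — generous, because the EM shrinks
    overestimated input variances far faster than it grows underestimated
    ones.  Starting the means small matters for excitation/inhibition
    disambiguation: with little tonic inhibition to remove, nonnegativity
    of the inputs forces depolarizing transients to be attributed to
    excitation rather than to a drop in inhibition.  The observation
    variance starts from the high-frequency variance of the traces (half
    the lag-1 differenced variance, which is sigma_eps^2 for white noise on
    a smooth signal); the dynamics noise starts small.
    """
    T = trials.T
    ybar = float(trials.y.mean())
    den = (params.E_E - ybar) + (params.E_I - ybar)
    if den > 5.0:
        g0 = -(params.g_L * (params.E_L - ybar) + params.I_inj) / den
        g0 = float(np.clip(g0, 0.02 * params.g_L, 2.0 * params.g_L))
    else:
        # near or beyond the midpoint of the synaptic reversals the
        # inversion is singular; fall back to the minimal-drive prior
        g0 = 0.02 * params.g_L
    mu0_E = g0 * params.dt / params.tau_E
    mu0_I = g0 * params.dt / params.tau_I
    if T > 1:
        se0 = max(float(np.mean(np.var(np.diff(trials.y, axis=1), axis=1))) / 2.0,
                  _VAR_FLOOR)
    else:
        se0 = 1.0
    return InputStats(mu_E=np.full(T, mu0_E), mu_I=np.full(T, mu0_I),
                      gamma_E=np.full(T, (2.0 * mu0_E) ** 2),
                      gamma_I=np.full(T, (2.0 * mu0_I) ** 2),
                      sigma_w2=1e-3, sigma_eps2=se0)


def _pad_series(series_T1: np.ndarray) -> np.ndarray:
    """Extend a length T-1 input series to the length-T grid (repeat last)."""
    return np.concatenate([series_T1, series_T1[-1:]])


# ---------------------------------------------------------------------------
# Grouped EM engine
# ---------------------------------------------------------------------------

def _fit_grouped(trials: TrialSet, params: ModelParams, theta0, groups,
                 max_iter: int = 60, rel_tol: float = 1e-3,
                 warmup: int = 15, update_sigma_w: bool = False):
    """Run EM with trials partitioned into parameter groups.

    ``groups[i]`` assigns trial i to a group; statistics are pooled within
    each group only.  MtKF uses one group for all trials; the per-trial
    baselines use one group per trial.  The E-step is batched across all
    trials regardless of grouping.

    The first ``warmup`` iterations update only the input statistics
    (mu, gamma) with the noise variances held at their starting values:
    until the means explain the stimulus-locked structure, a free noise
    update would absorb the unexplained evoked transients into the
    observation (or dynamics) variance and blind the filter.  After
    warm-up the observation variance is re-estimated each iteration; the
    dynamics noise stays fixed unless ``update_sigma_w`` is set, because a
    per-step variance on the observed coordinate is weakly identifiable
    against the conductance variances and acts as a sink for model misfit.

    Returns ``(stats_by_group, estimate, trace, posteriors_batched)``.
    """
    y = trials.y
    L, T = y.shape
    groups = np.asarray(groups)
    gids = np.unique(groups)
    if isinstance(theta0, InputStats):
        stats_by_group = {g: theta0.copy() for g in gids}
    else:
        stats_by_group = {g: theta0[g].copy() for g in gids}

    trace = EMTrace()
    mu_E = np.empty((L, T))
    mu_I = np.empty((L, T))
    gamma_E = np.empty((L, T))
    gamma_I = np.empty((L, T))
    sw2 = np.empty(L)
    se2 = np.empty(L)

    res = None
    prev_ll = None
    for it in range(max_iter):
        for g in gids:
            sel = groups == g
            st = stats_by_group[g]
            mu_E[sel] = st.mu_E
            mu_I[sel] = st.mu_I
            gamma_E[sel] = st.gamma_E
            gamma_I[sel] = st.gamma_I
            sw2[sel] = st.sigma_w2
            se2[sel] = st.sigma_eps2
        res = run_batch(y, params, mu_E, mu_I, gamma_E, gamma_I, sw2, se2)
        ll = float(res["loglik"].sum())
        if not np.isfinite(ll):
            err = RuntimeError(f"EM diverged (non-finite likelihood) at "
                               f"iteration {it}")
            err.last_stats = stats_by_group
            raise err
        trace.loglik.append(ll)
        trace.n_iter = it + 1
        if prev_ll is not None:
            rel = (ll - prev_ll) / abs(prev_ll)
            if rel < -rel_tol:
                msg = (f"log-likelihood decreased by {-100 * rel:.2f}% at "
                       f"iteration {it}")
                logger.warning(msg)
                trace.warnings.append(msg)
            if it > warmup and abs(rel) < rel_tol:
                trace.converged = True
                break
        prev_ll = ll

        # M-step per group
        moments, clips = _extract_batch(res["m_smooth"], res["P_smooth"],
                                        res["P_lag"], params)
        trace.n_var_clips += clips
        new_stats = {}
        for g in gids:
            sel = np.flatnonzero(groups == g)
            per = [PerTrialInputStats(mu_E=moments["mu_E"][i],
                                      mu_I=moments["mu_I"][i],
                                      gamma_E=moments["gamma_E"][i],
                                      gamma_I=moments["gamma_I"][i])
                   for i in sel]
            muE, gamE, muI, gamI = update_common_stats(per)
            muE = np.maximum(muE, 0.0)   # common inputs are nonnegative
            muI = np.maximum(muI, 0.0)
            posts = [StatePosterior(m_filt=res["m_filt"][i],
                                    P_filt=res["P_filt"][i],
                                    m_smooth=res["m_smooth"][i],
                                    P_smooth=res["P_smooth"][i],
                                    P_lag=res["P_lag"][i],
                                    loglik=float(res["loglik"][i]))
                     for i in sel]
            old = stats_by_group[g]
            sigma_w2, sigma_eps2 = old.sigma_w2, old.sigma_eps2
            if it >= warmup:
                sub = TrialSet(y=y[sel], dt=trials.dt)
                sw2_new, sigma_eps2 = update_noise_variances(sub, posts,
                                                             params)
                if update_sigma_w:
                    sigma_w2 = sw2_new
            new_stats[g] = InputStats(
                mu_E=_pad_series(muE), mu_I=_pad_series(muI),
                gamma_E=_pad_series(gamE), gamma_I=_pad_series(gamI),
                sigma_w2=sigma_w2, sigma_eps2=sigma_eps2)
        stats_by_group = new_stats
        trace.theta_history.append({g: s.copy()
                                    for g, s in stats_by_group.items()})

    est = ConductanceEstimate(
        g_E=res["m_smooth"][:, :, 1], g_I=res["m_smooth"][:, :, 2],
        std_E=np.sqrt(np.maximum(res["P_smooth"][:, :, 1, 1], 0.0)),
        std_I=np.sqrt(np.maximum(res["P_smooth"][:, :, 2, 2], 0.0)))
    return stats_by_group, est, trace, res


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def fit_mtkf(trials: TrialSet, params: ModelParams,
             theta0: InputStats | None = None, max_iter: int = 60,
             rel_tol: float = 1e-3, warmup: int = 15,
             update_sigma_w: bool = False):
    """Multiple-trial Kalman EM: pool input statistics across all trials.

    Returns ``(InputStats, ConductanceEstimate, EMTrace)``; the estimate
    holds the per-trial smoothed conductances under the final common
    statistics.  With a single trial this is exactly the StKF estimator.
    """
    theta0 = default_theta0(trials, params) if theta0 is None else theta0
    groups = np.zeros(trials.L, dtype=int)
    stats, est, trace, _ = _fit_grouped(trials, params, theta0, groups,
                                        max_iter, rel_tol, warmup,
                                        update_sigma_w)
    return stats[0], est, trace


def fit_stkf_per_trial(trials: TrialSet, params: ModelParams,
                       theta0: InputStats | None = None, max_iter: int = 60,
                       rel_tol: float = 1e-3, warmup: int = 15,
                       update_sigma_w: bool = False):
    """Independent single-trial (StKF) EM fits, one per trial.

    Returns ``(list of InputStats, ConductanceEstimate, EMTrace)`` with one
    statistics bundle per trial and per-trial conductance estimates.
    """
    theta0 = default_theta0(trials, params) if theta0 is None else theta0
    groups = np.arange(trials.L)
    stats, est, trace, _ = _fit_grouped(trials, params, theta0, groups,
                                        max_iter, rel_tol, warmup,
                                        update_sigma_w)
    return [stats[g] for g in range(trials.L)], est, trace


def baseline_avg_of_stkf(trials: TrialSet, params: ModelParams,
                         theta0: InputStats | None = None, max_iter: int = 60,
                         rel_tol: float = 1e-3) -> ConductanceEstimate:
    """Average of independent StKF estimates (trial-average baseline).

    Every trial receives the same averaged trajectory, so the estimate
    carries no trial-to-trial structure.
    """
    _, est, _ = fit_stkf_per_trial(trials, params, theta0, max_iter, rel_tol)
    L = trials.L
    gE = np.tile(est.g_E.mean(axis=0), (L, 1))
    gI = np.tile(est.g_I.mean(axis=0), (L, 1))
    sE = np.tile(np.sqrt((est.std_E ** 2).mean(axis=0) / L), (L, 1))
    sI = np.tile(np.sqrt((est.std_I ** 2).mean(axis=0) / L), (L, 1))
    return ConductanceEstimate(g_E=gE, g_I=gI, std_E=sE, std_I=sI)


def baseline_stkf_of_avg(trials: TrialSet, params: ModelParams,
                         theta0: InputStats | None = None, max_iter: int = 60,
                         rel_tol: float = 1e-3) -> ConductanceEstimate:
    """StKF applied to the trial-averaged membrane potential.

    Averaging L trials divides the observation-noise variance by L; when an
    explicit ``theta0`` is supplied its observation variance is rescaled
    accordingly (the default initializer estimates it from the averaged
    trace directly).
    """
    avg = TrialSet(y=trials.y.mean(axis=0, keepdims=True), dt=trials.dt)
    if theta0 is not None:
        theta0 = theta0.copy()
        theta0.sigma_eps2 = theta0.sigma_eps2 / trials.L
    _, est, _ = fit_mtkf(avg, params, theta0, max_iter, rel_tol)
    L = trials.L
    return ConductanceEstimate(g_E=np.tile(est.g_E[0], (L, 1)),
                               g_I=np.tile(est.g_I[0], (L, 1)),
                               std_E=np.tile(est.std_E[0], (L, 1)),
                               std_I=np.tile(est.std_I[0], (L, 1)))
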