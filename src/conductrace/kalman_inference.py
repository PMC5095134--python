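"""Extended Kalman forward filter and RTS backward smoother per trial.

State is x = [V, g_E, g_I]; only V is observed (C = [1, 0, 0]).  The
transition is linear in the conductances and bilinear in (V, g), so a
first-order linearization at the current estimate makes the classic
predict/update recursion applicable.  The process noise has mean
[0, mu_E(t), mu_I(t)] and covariance diag(sigma_w^2, gamma_E(t), gamma_I(t)):
the synaptic inputs enter the filter as state noise with known (or, in the
EM loop, currently-estimated) time-varying statistics.

Nonnegativity of the conductances is enforced by projection: posterior and
smoothed conductance means are floored at zero after each update.  All
internal routines are batched over trials (leading axis L) so that the EM
loop pays one Python-level time loop per pass regardless of trial count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .passive_model import InputStats, ModelParams

__all__ = [
    "NumericalError",
    "StatePosterior",
    "ConductanceEstimate",
    "ekf_forward",
    "rts_backward",
    "infer_trial",
    "default_init",
]

logger = logging.getLogger(__name__)

_JITTER = 1e-12


class NumericalError(RuntimeError):
    """Raised when the filter encounters a non-positive innovation variance."""


@dataclass
class StatePosterior:
    """Filtered and smoothed moments of one trial's latent trajectory."""

    m_filt: np.ndarray    # (T, 3)
    P_filt: np.ndarray    # (T, 3, 3)
    m_smooth: np.ndarray  # (T, 3)
    P_smooth: np.ndarray  # (T, 3, 3)
    P_lag: np.ndarray     # (T-1, 3, 3): Cov(x(t+1), x(t) | all data)
    loglik: float


@dataclass
class ConductanceEstimate:
    """Inferred conductance time courses with pointwise posterior std."""

    g_E: np.ndarray    # (L, T) μS
    g_I: np.ndarray    # (L, T)
    std_E: np.ndarray  # (L, T)
    std_I: np.ndarray  # (L, T)

    @property
    def L(self) -> int:
        return self.g_E.shape[0]


# ---------------------------------------------------------------------------
# Batched per-trial statistics container used by the engine
# ---------------------------------------------------------------------------

def _broadcast_stats(stats: InputStats, L: int):
    """Expand common InputStats into per-trial (L, T) / (L,) arrays."""
    T = stats.T
    return (np.broadcast_to(stats.mu_E, (L, T)),
            np.broadcast_to(stats.mu_I, (L, T)),
            np.broadcast_to(stats.gamma_E, (L, T)),
            np.broadcast_to(stats.gamma_I, (L, T)),
            np.full(L, stats.sigma_w2),
            np.full(L, stats.sigma_eps2))


def default_init(y: np.ndarray, params: ModelParams, mu_E0, mu_I0,
                 sigma_eps2):
    """Heuristic initial state distribution for a batch of trials.

    Mean: [y(0), mu_E(0)*tau_E/dt, mu_I(0)*tau_I/dt] — the observed first
    sample and the stationary conductance levels implied by the initial
    input means.  Covariance: broad diagonal so the data dominate quickly.
    """
    L = y.shape[0]
    gE0 = np.asarray(mu_E0) * params.tau_E / params.dt
    gI0 = np.asarray(mu_I0) * params.tau_I / params.dt
    m0 = np.empty((L, 3))
    m0[:, 0] = y[:, 0]
    m0[:, 1] = gE0
    m0[:, 2] = gI0
    P0 = np.zeros((L, 3, 3))
    P0[:, 0, 0] = np.asarray(sigma_eps2) + 1.0
    P0[:, 1, 1] = (10.0 * gE0 + 1e-3) ** 2
    P0[:, 2, 2] = (10.0 * gI0 + 1e-3) ** 2
    return m0, P0


# ---------------------------------------------------------------------------
# Engine: batched forward filter
# ---------------------------------------------------------------------------

def _predict(m, P, params, mu_E_t, mu_I_t, gamma_E_t, gamma_I_t, sigma_w2):
    """One batched predict step from posterior (m, P) at t to prior at t+1."""
    k = params.dt / params.C_m
    V, gE, gI = m[:, 0], m[:, 1], m[:, 2]
    m_pred = np.empty_like(m)
    m_pred[:, 0] = V + k * (params.g_L * (params.E_L - V) + gE * (params.E_E - V)
                            + gI * (params.E_I - V) + params.I_inj)
    m_pred[:, 1] = gE * params.decay_E + mu_E_t
    m_pred[:, 2] = gI * params.decay_I + mu_I_t

    A = np.zeros((m.shape[0], 3, 3))
    A[:, 0, 0] = 1.0 - k * (params.g_L + gE + gI)
    A[:, 0, 1] = k * (params.E_E - V)
    A[:, 0, 2] = k * (params.E_I - V)
    A[:, 1, 1] = params.decay_E
    A[:, 2, 2] = params.decay_I

    P_pred = A @ P @ A.transpose(0, 2, 1)
    P_pred[:, 0, 0] += sigma_w2
    P_pred[:, 1, 1] += gamma_E_t
    P_pred[:, 2, 2] += gamma_I_t
    P_pred = 0.5 * (P_pred + P_pred.transpose(0, 2, 1))
    return m_pred, P_pred, A


def _update(m_pred, P_pred, y_t, sigma_eps2, step: int):
    """Batched measurement update with Joseph-form covariance."""
    S = P_pred[:, 0, 0] + sigma_eps2
    if np.any(S <= 0):
        bad = int(np.argmax(S <= 0))
        raise NumericalError(
            f"non-positive innovation variance at step {step} (trial {bad})")
    e = y_t - m_pred[:, 0]
    K = P_pred[:, :, 0] / S[:, None]                     # (L, 3)
    m = m_pred + K * e[:, None]
    m[:, 1:] = np.maximum(m[:, 1:], 0.0)                 # conductance floor
    M = np.zeros_like(P_pred)
    M[:, 0, 0] = 1.0
    M[:, 1, 1] = 1.0
    M[:, 2, 2] = 1.0
    M[:, :, 0] -= K
    P = M @ P_pred @ M.transpose(0, 2, 1) \
        + sigma_eps2[:, None, None] * (K[:, :, None] @ K[:, None, :])
    P = 0.5 * (P + P.transpose(0, 2, 1))
    ll = -0.5 * (np.log(2.0 * np.pi * S) + e * e / S)
    return m, P, ll


def _forward_batch(y, params, mu_E, mu_I, gamma_E, gamma_I,
                   sigma_w2, sigma_eps2, init_mean, init_cov):
    """Forward EKF over a batch of trials; returns filtered moments + loglik."""
    L, T = y.shape
    m_filt = np.empty((L, T, 3))
    P_filt = np.empty((L, T, 3, 3))
    loglik = np.zeros(L)

    m, P, ll = _update(init_mean.copy(), init_cov.copy(), y[:, 0],
                       sigma_eps2, 0)
    m_filt[:, 0], P_filt[:, 0] = m, P
    loglik += ll
    for t in range(1, T):
        m_pred, P_pred, _ = _predict(m, P, params, mu_E[:, t - 1],
                                     mu_I[:, t - 1], gamma_E[:, t - 1],
                                     gamma_I[:, t - 1], sigma_w2)
        m, P, ll = _update(m_pred, P_pred, y[:, t], sigma_eps2, t)
        m_filt[:, t], P_filt[:, t] = m, P
        loglik += ll
    return m_filt, P_filt, loglik


def _solve_spd(Ppred, B):
    """Batched solve Ppred X = B with escalating jitter on failure."""
    jitter = _JITTER
    for _ in range(6):
        try:
            return np.linalg.solve(Ppred, B)
        except np.linalg.LinAlgError:
            logger.warning("singular predicted covariance; adding jitter %g",
                           jitter)
            Ppred = Ppred.copy()
            Ppred[:, 0, 0] += jitter
            Ppred[:, 1, 1] += jitter
            Ppred[:, 2, 2] += jitter
            jitter *= 1e3
    raise NumericalError("predicted covariance remained singular after jitter")


def _smooth_batch(y, params, mu_E, mu_I, gamma_E, gamma_I, sigma_w2,
                  m_filt, P_filt):
    """Batched fixed-interval RTS smoother with lag-one cross-covariances.

    Predicted moments and Jacobians are recomputed from the stored filtered
    moments (they are deterministic functions of them), so the forward pass
    only needs to persist the posterior sequence.
    """
    L, T, _ = m_filt.shape
    m_s = np.empty_like(m_filt)
    P_s = np.empty_like(P_filt)
    P_lag = np.empty((L, T - 1, 3, 3)) if T > 1 else np.empty((L, 0, 3, 3))
    m_s[:, -1] = m_filt[:, -1]
    P_s[:, -1] = P_filt[:, -1]
    for t in range(T - 2, -1, -1):
        m_pred, P_pred, A = _predict(m_filt[:, t], P_filt[:, t], params,
                                     mu_E[:, t], mu_I[:, t], gamma_E[:, t],
                                     gamma_I[:, t], sigma_w2)
        # G = P_filt A^T P_pred^{-1}; with symmetric matrices
        # G^T = P_pred^{-1} A P_filt
        Gt = _solve_spd(P_pred, A @ P_filt[:, t])
        G = Gt.transpose(0, 2, 1)
        m_s[:, t] = m_filt[:, t] + (G @ (m_s[:, t + 1]
                                         - m_pred)[:, :, None])[:, :, 0]
        m_s[:, t, 1:] = np.maximum(m_s[:, t, 1:], 0.0)
        Pt = P_filt[:, t] + G @ (P_s[:, t + 1] - P_pred) @ Gt
        P_s[:, t] = 0.5 * (Pt + Pt.transpose(0, 2, 1))
        # exact lag-one identity: Cov(x(t+1), x(t) | Y) = P_s(t+1) G^T
        P_lag[:, t] = P_s[:, t + 1] @ Gt
    return m_s, P_s, P_lag


def run_batch(y, params, mu_E, mu_I, gamma_E, gamma_I, sigma_w2, sigma_eps2,
              init_mean=None, init_cov=None):
    """Full forward+backward pass over a batch of trials with per-trial stats.

    All statistics arguments are per-trial arrays ((L, T) series, (L,) noise
    variances).  Returns a dict of batched moments plus per-trial loglik.
    This is the shared engine behind the public single-trial API and the
    multi-trial EM loop.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if init_mean is None or init_cov is None:
        m0, P0 = default_init(y, params, mu_E[:, 0], mu_I[:, 0], sigma_eps2)
        init_mean = m0 if init_mean is None else init_mean
        init_cov = P0 if init_cov is None else init_cov
    m_filt, P_filt, loglik = _forward_batch(
        y, params, mu_E, mu_I, gamma_E, gamma_I, sigma_w2, sigma_eps2,
        np.asarray(init_mean, dtype=float), np.asarray(init_cov, dtype=float))
    m_s, P_s, P_lag = _smooth_batch(y, params, mu_E, mu_I, gamma_E, gamma_I,
                                    sigma_w2, m_filt, P_filt)
    return {"m_filt": m_filt, "P_filt": P_filt, "m_smooth": m_s,
            "P_smooth": P_s, "P_lag": P_lag, "loglik": loglik}


# ---------------------------------------------------------------------------
# Public single-trial API
# ---------------------------------------------------------------------------

def _as_single(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a single trial (1-D array)")
    return y[None, :]


def ekf_forward(y, params: ModelParams, stats: InputStats,
                init_mean=None, init_cov=None):
    """Forward extended Kalman filter for one trial.

    Returns ``(m_filt (T,3), P_filt (T,3,3), loglik)`` where ``loglik`` is the
    innovation-form Gaussian log-likelihood of the trace under the model.
    """
    yb = _as_single(y)
    if yb.shape[1] != stats.T:
        raise ValueError("trace length and statistics length differ")
    mu_E, mu_I, gE, gI, sw2, se2 = _broadcast_stats(stats, 1)
    if init_mean is None or init_cov is None:
        m0, P0 = default_init(yb, params, mu_E[:, 0], mu_I[:, 0], se2)
        init_mean = m0 if init_mean is None else np.asarray(init_mean)[None]
        init_cov = P0 if init_cov is None else np.asarray(init_cov)[None]
    else:
        init_mean = np.asarray(init_mean, dtype=float)[None]
        init_cov = np.asarray(init_cov, dtype=float)[None]
    m_filt, P_filt, ll = _forward_batch(yb, params, mu_E, mu_I, gE, gI,
                                        sw2, se2, init_mean, init_cov)
    return m_filt[0], P_filt[0], float(ll[0])


def rts_backward(m_filt, P_filt, params: ModelParams, stats: InputStats,
                 y=None):
    """Fixed-interval smoother from a completed forward pass.

    Returns ``(m_smooth, P_smooth, P_lag)``; ``P_lag[t]`` is the smoothed
    cross-covariance Cov(x(t+1), x(t) | all observations).
    """
    mb = np.asarray(m_filt, dtype=float)[None]
    Pb = np.asarray(P_filt, dtype=float)[None]
    mu_E, mu_I, gE, gI, sw2, _ = _broadcast_stats(stats, 1)
    m_s, P_s, P_lag = _smooth_batch(None, params, mu_E, mu_I, gE, gI, sw2,
                                    mb, Pb)
    return m_s[0], P_s[0], P_lag[0]


def infer_trial(y, params: ModelParams, stats: InputStats,
                init_mean=None, init_cov=None):
    """Filter + smooth one trial under given input statistics.

    Returns ``(StatePosterior, ConductanceEstimate)``.  With statistics from
    a single-trial EM fit this is exactly the single-trial (StKF) estimator.
    """
    m_filt, P_filt, ll = ekf_forward(y, params, stats, init_mean, init_cov)
    m_s, P_s, P_lag = rts_backward(m_filt, P_filt, params, stats)
    post = StatePosterior(m_filt=m_filt, P_filt=P_filt, m_smooth=m_s,
                          P_smooth=P_s, P_lag=P_lag, loglik=ll)
    est = ConductanceEstimate(
        g_E=m_s[None, :, 1], g_I=m_s[None, :, 2],
        std_E=np.sqrt(np.maximum(P_s[None, :, 1, 1], 0.0)),
        std_I=np.sqrt(np.maximum(P_s[None, :, 2, 2], 0.0)))
    return post, est
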