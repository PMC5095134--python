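"""Scoring of conductance estimates against simulated ground truth.

Three levels of error are used.  Per-trial RMSE measures absolute accuracy
in μS.  The normalized error compares, at each time point, the across-trial
variance of the estimation residual to the across-trial variance of the true
conductance — it is 1 when the estimate carries no trial-to-trial
information beyond the trial mean, and 0 for a perfect estimate — averaged
over time and then over the excitatory and inhibitory channels with equal
weight.  The total error log{exp(Err_E) + exp(Err_I)} (a softmax-style
aggregate dominated by the larger of the two) summarizes both channels when
sweeping the injected current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ErrorReport",
    "rmse_per_trial",
    "normalized_error",
    "total_error",
    "score_estimates",
]


@dataclass
class ErrorReport:
    """Bundle of all error measures for one estimate."""

    rmse_E: np.ndarray   # (L,) per-trial RMSE of g_E (μS)
    rmse_I: np.ndarray   # (L,)
    err_bar_E: float     # normalized excitatory error
    err_bar_I: float     # normalized inhibitory error
    err_norm: float      # (err_bar_E + err_bar_I) / 2
    err_total: float     # log{exp(err_bar_E) + exp(err_bar_I)}
    n_excluded_E: int    # zero-signal-variance time points excluded
    n_excluded_I: int


def rmse_per_trial(g_true: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    """Root-mean-square error over time, one value per trial."""
    g_true = np.atleast_2d(np.asarray(g_true, dtype=float))
    g_hat = np.atleast_2d(np.asarray(g_hat, dtype=float))
    if g_true.shape != g_hat.shape:
        raise ValueError("shape mismatch between truth and estimate")
    return np.sqrt(np.mean((g_true - g_hat) ** 2, axis=1))


def _channel_error(g_true: np.ndarray, g_hat: np.ndarray):
    """Time-averaged ratio of residual trial variance to signal trial
    variance; returns (error, number of excluded zero-variance points).

    Time points whose signal variance is numerically zero (absolutely, or
    relative to the largest variance in the trace) are excluded from the
    average rather than producing infinities.
    """
    var_sig = np.var(g_true, axis=0)          # population (1/L) convention
    var_res = np.var(g_true - g_hat, axis=0)
    keep = var_sig > 1e-10 * var_sig.max() if var_sig.max() > 0 \
        else np.zeros_like(var_sig, dtype=bool)
    n_excl = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("true conductance has zero trial variance at every "
                         "time point; normalized error undefined")
    return float(np.mean(var_res[keep] / var_sig[keep])), n_excl


def normalized_error(g_true_E, g_hat_E, g_true_I, g_hat_I):
    """Trial-variance-normalized error of both channels.

    Requires L >= 2 trials (the across-trial variance must exist).  Time
    points where the true conductance has zero trial variance are excluded.
    Returns ``(err_bar_E, err_bar_I, err_norm)``.
    """
    arrs = [np.atleast_2d(np.asarray(a, dtype=float))
            for a in (g_true_E, g_hat_E, g_true_I, g_hat_I)]
    if arrs[0].shape[0] < 2:
        raise ValueError("normalized error requires at least two trials")
    err_E, _ = _channel_error(arrs[0], arrs[1])
    err_I, _ = _channel_error(arrs[2], arrs[3])
    return err_E, err_I, 0.5 * (err_E + err_I)


def total_error(err_bar_E: float, err_bar_I: float) -> float:
    """Softmax-style aggregate log{exp(Err_E) + exp(Err_I)}.

    Numerically stable; dominated by (always at least) the larger channel
    error and never exceeds it by more than log 2.
    """
    if not (np.isfinite(err_bar_E) and np.isfinite(err_bar_I)):
        raise ValueError("channel errors must be finite")
    return float(logsumexp([err_bar_E, err_bar_I]))


def score_estimates(truth, estimate) -> ErrorReport:
    """Full error report for a ConductanceEstimate against GroundTruth."""
    eE, nE = _channel_error(np.atleast_2d(truth.g_E),
                            np.atleast_2d(estimate.g_E))
    eI, nI = _channel_error(np.atleast_2d(truth.g_I),
                            np.atleast_2d(estimate.g_I))
    return ErrorReport(
        rmse_E=rmse_per_trial(truth.g_E, estimate.g_E),
        rmse_I=rmse_per_trial(truth.g_I, estimate.g_I),
        err_bar_E=eE, err_bar_I=eI, err_norm=0.5 * (eE + eI),
        err_total=total_error(eE, eI), n_excluded_E=nE, n_excluded_I=nI)
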