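"""Brute-force Gaussian oracles used to validate the filtering recursions.

The extended Kalman filter is the exact Kalman filter of the model
linearized along its filtered trajectory.  Given the Jacobian/offset
sequence actually used by a forward pass, the joint distribution of all
states and observations is one big Gaussian that can be assembled densely
and conditioned by textbook formulas — an independent check of every
recursion (filter, smoother, lag-one covariances, likelihood).
"""

import numpy as np

from conductrace import ModelParams
from conductrace.passive_model import transition_jacobian, transition_mean


def assemble_joint(m0, P0, A_seq, b_seq, Q_seq, C, R, T):
    """Dense joint Gaussian of (x(0..T-1), y(0..T-1)) for a linear system.

    x(t+1) = A_t x(t) + b_t + v_t,  v_t ~ N(0, Q_t)
    y(t)   = C x(t) + eps_t,        eps_t ~ N(0, R)
    """
    n = m0.size
    mean_x = np.zeros(T * n)
    cov_x = np.zeros((T * n, T * n))
    mean_x[:n] = m0
    cov_x[:n, :n] = P0
    for t in range(T - 1):
        sl = slice(t * n, (t + 1) * n)
        sn = slice((t + 1) * n, (t + 2) * n)
        mean_x[sn] = A_seq[t] @ mean_x[sl] + b_seq[t]
        # propagate covariance blocks
        for s in range(t + 1):
            blk = cov_x[slice(s * n, (s + 1) * n), sl] @ A_seq[t].T
            cov_x[slice(s * n, (s + 1) * n), sn] = blk
            cov_x[sn, slice(s * n, (s + 1) * n)] = blk.T
        cov_x[sn, sn] = A_seq[t] @ cov_x[sl, sl] @ A_seq[t].T + Q_seq[t]
    H = np.kron(np.eye(T), C[None, :])
    mean_y = H @ mean_x
    cov_y = H @ cov_x @ H.T + R * np.eye(T)
    cov_xy = cov_x @ H.T
    return mean_x, cov_x, mean_y, cov_y, cov_xy


def condition_on_y(mean_x, cov_x, mean_y, cov_y, cov_xy, y):
    """Posterior mean/cov of the stacked states given all observations."""
    sol = np.linalg.solve(cov_y, y - mean_y)
    post_mean = mean_x + cov_xy @ sol
    post_cov = cov_x - cov_xy @ np.linalg.solve(cov_y, cov_xy.T)
    return post_mean, post_cov


def gaussian_loglik(y, mean_y, cov_y):
    d = y - mean_y
    sign, logdet = np.linalg.slogdet(cov_y)
    assert sign > 0
    return float(-0.5 * (d @ np.linalg.solve(cov_y, d)
                         + logdet + y.size * np.log(2.0 * np.pi)))


def linearized_system(m_filt, params: ModelParams, stats):
    """Jacobian/offset/noise sequence of the model linearized along the
    filtered trajectory (the system whose exact KF is the EKF)."""
    T = m_filt.shape[0]
    A_seq, b_seq, Q_seq = [], [], []
    for t in range(T - 1):
        A = transition_jacobian(m_filt[t], params)
        f = transition_mean(m_filt[t], params)
        f = f + np.array([0.0, stats.mu_E[t], stats.mu_I[t]])
        b_seq.append(f - A @ m_filt[t])
        A_seq.append(A)
        Q_seq.append(np.diag([stats.sigma_w2, stats.gamma_E[t],
                              stats.gamma_I[t]]))
    return A_seq, b_seq, Q_seq
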