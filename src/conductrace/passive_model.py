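"""Passive conductance-based membrane model and synthetic-trial generation.

The generative model is a discrete-time (forward-Euler) passive neuron with
three dynamic variables: the membrane potential ``V`` and the excitatory and
inhibitory synaptic conductances ``g_E``, ``g_I``::

    V(t+1)   = V(t) + (dt/C_m)[g_L(E_L - V) + g_E(E_E - V) + g_I(E_I - V) + I_inj] + w(t)
    g_E(t+1) = g_E(t)(1 - dt/tau_E) + N_E(t)
    g_I(t+1) = g_I(t)(1 - dt/tau_I) + N_I(t)

``w`` is white Gaussian dynamics noise and ``N_E``, ``N_I`` are nonnegative
per-step synaptic-input increments.  Trials share the time-varying input
statistics (the "common" synaptic input) but differ in realization; only the
membrane potential is observed, corrupted by Gaussian noise.

Units: mV, ms, μS, nA, nF throughout; conductance increments are μS per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "InputStats",
    "TrialSet",
    "GroundTruth",
    "step_state",
    "transition_mean",
    "transition_jacobian",
    "generate_nonstructured_mean",
    "generate_structured_mean",
    "sample_synaptic_inputs",
    "simulate_trials",
    "save_ground_truth",
    "load_ground_truth",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Fixed biophysical constants of the passive membrane equation.

    Defaults reproduce the standard simulation protocol: reversal potentials
    E_E = 0 mV, E_I = -80 mV, E_L = -60 mV, membrane time constant
    tau_m = C_m/g_L = 12.5 ms, synaptic time constants tau_E = 3 ms and
    tau_I = 10 ms, sampling step 2 ms, 2 s per trial.

    The cell's input resistance is 1/g_L = 200 MΩ, so a +50 pA holding
    current depolarizes the quiescent membrane by 10 mV (to -50 mV), and
    +130 pA holds it near -34 mV — matching the current-clamp baselines the
    method targets.
    """

    E_L: float = -60.0      # leak reversal (mV)
    E_E: float = 0.0        # excitatory reversal (mV)
    E_I: float = -80.0      # inhibitory reversal (mV)
    g_L: float = 0.005      # leak conductance (μS)
    C_m: float = 0.0625     # membrane capacitance (nF)
    tau_E: float = 3.0      # excitatory synaptic time constant (ms)
    tau_I: float = 10.0     # inhibitory synaptic time constant (ms)
    dt: float = 2.0         # time step (ms)
    T: int = 1000           # number of steps (grid covers T*dt ms)
    I_inj: float = 0.0      # injected (holding) current (nA)
    sigma_w: float = 0.05   # membrane dynamics noise std (mV per step)

    def __post_init__(self) -> None:
        if not (self.g_L > 0 and self.C_m > 0 and self.tau_E > 0
                and self.tau_I > 0 and self.dt > 0):
            raise ValueError("g_L, C_m, tau_E, tau_I and dt must be positive")
        if not self.dt < min(self.tau_E, self.tau_I):
            raise ValueError(
                f"dt={self.dt} must be smaller than min(tau_E, tau_I)="
                f"{min(self.tau_E, self.tau_I)} for Euler stability")
        if not (self.E_I < self.E_L < self.E_E):
            raise ValueError("reversal potentials must satisfy E_I < E_L < E_E")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be nonnegative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m/g_L (ms)."""
        return self.C_m / self.g_L

    @property
    def decay_E(self) -> float:
        """Per-step excitatory conductance decay factor 1 - dt/tau_E."""
        return 1.0 - self.dt / self.tau_E

    @property
    def decay_I(self) -> float:
        """Per-step inhibitory conductance decay factor 1 - dt/tau_I."""
        return 1.0 - self.dt / self.tau_I

    @property
    def v_rest(self) -> float:
        """Quiescent steady-state potential E_L + I_inj/g_L (mV)."""
        return self.E_L + self.I_inj / self.g_L

    def with_current(self, I_inj: float) -> "ModelParams":
        return replace(self, I_inj=I_inj)


@dataclass
class InputStats:
    """Time-varying common synaptic-input statistics (the EM parameter θ).

    ``mu_*`` are mean conductance increments per step (μS), ``gamma_*`` their
    variances (μS²); entry ``t`` governs the transition from step ``t`` to
    ``t+1`` (the last entry of each series pads the grid to length T and is
    never consumed by a transition).
    """

    mu_E: np.ndarray
    mu_I: np.ndarray
    gamma_E: np.ndarray
    gamma_I: np.ndarray
    sigma_w2: float
    sigma_eps2: float

    def __post_init__(self) -> None:
        self.mu_E = np.asarray(self.mu_E, dtype=float)
        self.mu_I = np.asarray(self.mu_I, dtype=float)
        self.gamma_E = np.asarray(self.gamma_E, dtype=float)
        self.gamma_I = np.asarray(self.gamma_I, dtype=float)
        n = len(self.mu_E)
        if not (len(self.mu_I) == len(self.gamma_E) == len(self.gamma_I) == n):
            raise ValueError("all input-statistics series must share one length")
        if np.any(self.mu_E < 0) or np.any(self.mu_I < 0):
            raise ValueError("mean synaptic inputs must be nonnegative")
        if np.any(self.gamma_E < 0) or np.any(self.gamma_I < 0):
            raise ValueError("input variances must be nonnegative")
        if self.sigma_w2 < 0 or self.sigma_eps2 < 0:
            raise ValueError("noise variances must be nonnegative")

    @property
    def T(self) -> int:
        return len(self.mu_E)

    def copy(self) -> "InputStats":
        return InputStats(self.mu_E.copy(), self.mu_I.copy(),
                          self.gamma_E.copy(), self.gamma_I.copy(),
                          self.sigma_w2, self.sigma_eps2)


@dataclass
class TrialSet:
    """Observed membrane-potential traces for L trials on a shared grid."""

    y: np.ndarray            # (L, T) observed potentials (mV)
    dt: float                # step (ms)
    trial_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[0] < 1:
            raise ValueError("at least one trial is required")
        if not self.trial_ids:
            self.trial_ids = [f"trial_{i}" for i in range(self.y.shape[0])]
        if len(self.trial_ids) != self.y.shape[0]:
            raise ValueError("trial_ids length must match number of trials")

    @property
    def L(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.T) * self.dt


@dataclass
class GroundTruth:
    """Latent trajectories retained from simulation for scoring estimates."""

    V: np.ndarray     # (L, T) membrane potential (mV)
    g_E: np.ndarray   # (L, T) excitatory conductance (μS)
    g_I: np.ndarray   # (L, T) inhibitory conductance (μS)
    N_E: np.ndarray   # (L, T) excitatory inputs (μS per step; last column 0)
    N_I: np.ndarray   # (L, T) inhibitory inputs


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def step_state(x, params: ModelParams, N_E: float = 0.0, N_I: float = 0.0,
               w: float = 0.0) -> np.ndarray:
    """Advance the state [V, g_E, g_I] one Euler step.

    Vectorized over leading axes of ``x`` (last axis holds the state).
    """
    x = np.asarray(x, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite([N_E, N_I, w]))):
        raise ValueError("non-finite state or inputs")
    V, gE, gI = x[..., 0], x[..., 1], x[..., 2]
    dVdt = (params.g_L * (params.E_L - V) + gE * (params.E_E - V)
            + gI * (params.E_I - V) + params.I_inj)
    out = np.empty_like(x)
    out[..., 0] = V + (params.dt / params.C_m) * dVdt + w
    out[..., 1] = gE * params.decay_E + N_E
    out[..., 2] = gI * params.decay_I + N_I
    return out


def transition_mean(x, params: ModelParams) -> np.ndarray:
    """Noise-free, zero-input transition F(x) (the state-space drift)."""
    return step_state(x, params)


def transition_jacobian(x, params: ModelParams) -> np.ndarray:
    """Jacobian of F evaluated at ``x``; batched over leading axes.

    Only the membrane-potential row depends on the state:
    [1 - (dt/C_m)(g_L + g_E + g_I), (dt/C_m)(E_E - V), (dt/C_m)(E_I - V)];
    the conductance rows are the constant decays.
    """
    x = np.asarray(x, dtype=float)
    k = params.dt / params.C_m
    A = np.zeros(x.shape[:-1] + (3, 3))
    A[..., 0, 0] = 1.0 - k * (params.g_L + x[..., 1] + x[..., 2])
    A[..., 0, 1] = k * (params.E_E - x[..., 0])
    A[..., 0, 2] = k * (params.E_I - x[..., 0])
    A[..., 1, 1] = params.decay_E
    A[..., 2, 2] = params.decay_I
    return A


# ---------------------------------------------------------------------------
# Synaptic-input mean generators
# ---------------------------------------------------------------------------

def generate_nonstructured_mean(params: ModelParams, scale: float, tau: float,
                                T: int | None = None,
                                seed=None) -> np.ndarray:
    """Random nonnegative mean input: low-pass-filtered absolute white noise.

    The absolute value of unit white Gaussian noise is passed through a
    first-order filter with time constant ``tau`` and rescaled so the series
    mean equals ``scale`` (μS per step).  This yields a slowly wandering,
    Ornstein–Uhlenbeck-like nonnegative drive.
    """
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    T = params.T if T is None else int(T)
    if T <= 0:
        raise ValueError("T must be positive")
    rng = np.random.default_rng(seed)
    z = np.abs(rng.standard_normal(T))
    a = np.exp(-params.dt / tau)
    out = np.empty(T)
    # start the filter at its stationary mean to avoid an onset ramp
    acc = np.sqrt(2.0 / np.pi) / (1.0 - a)
    for t in range(T):
        acc = a * acc + z[t]
        out[t] = acc
    if scale == 0.0:
        return np.zeros(T)
    return out * (scale / out.mean())


def _doe_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel, peak-normalized to 1, zero for t<0."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def generate_structured_mean(params: ModelParams, stim_times, amp_E: float,
                             amp_I: float, adaptation: float = 1.0,
                             kernel_tau_rise: float = 1.0,
                             kernel_tau_decay: float = 8.0,
                             T: int | None = None):
    """Stimulus-locked mean input: a pulse train mimicking evoked responses.

    Each stimulus at ``stim_times`` (ms) contributes a difference-of-
    exponentials bump; successive pulses are attenuated by
    ``adaptation**pulse_index``, emulating the sensory adaptation seen in
    whisker-evoked cortical responses.  Returns ``(mu_E, mu_I)`` with peak
    first-pulse amplitudes ``amp_E`` and ``amp_I`` (μS per step).
    """
    if amp_E < 0 or amp_I < 0:
        raise ValueError("amplitudes must be nonnegative")
    if not (0.0 < adaptation <= 1.0):
        raise ValueError("adaptation must lie in (0, 1]")
    T = params.T if T is None else int(T)
    tgrid = np.arange(T) * params.dt
    horizon = T * params.dt
    mu = np.zeros(T)
    for j, ts in enumerate(stim_times):
        if not (0.0 <= ts < horizon):
            raise ValueError(f"stimulus time {ts} outside [0, {horizon}) ms")
        mu += adaptation ** j * _doe_kernel(tgrid - ts, kernel_tau_rise,
                                           kernel_tau_decay)
    return amp_E * mu, amp_I * mu


# ---------------------------------------------------------------------------
# Sampling and simulation
# ---------------------------------------------------------------------------

def sample_synaptic_inputs(mu: np.ndarray, unit_amplitude: float, L: int = 1,
                           seed=None) -> np.ndarray:
    """Draw Poisson shot-noise inputs N(t) = q * Poisson(mu(t)/q) per trial.

    ``unit_amplitude`` (q, μS) is the conductance quantum of one synaptic
    event, so E[N] = mu and Var[N] = q*mu.  Trials share the mean series but
    are independent realizations.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mean input series must be nonnegative")
    if unit_amplitude <= 0:
        raise ValueError("unit amplitude q must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return unit_amplitude * rng.poisson(mu / unit_amplitude,
                                        size=(L, mu.size)).astype(float)


def simulate_trials(params: ModelParams, mu_E, mu_I, q_E: float, q_I: float,
                    L: int = 10, sigma_eps: float = 1.0, seed=None):
    """Simulate L noisy current-clamp trials driven by common input statistics.

    Synaptic inputs are Poisson with quantum ``q_E``/``q_I`` around the common
    means; conductances and potential follow the Euler recursion; the
    observation is V plus i.i.d. Gaussian noise of std ``sigma_eps`` (mV).
    Each trial uses its own child seed of a splittable master seed, so
    results are independent of trial ordering.

    Returns ``(TrialSet, GroundTruth)``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be nonnegative")
    mu_E = np.asarray(mu_E, dtype=float)
    mu_I = np.asarray(mu_I, dtype=float)
    T = mu_E.size
    if mu_I.size != T:
        raise ValueError("mu_E and mu_I must share length")

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(L)

    V = np.empty((L, T))
    gE = np.zeros((L, T))
    gI = np.zeros((L, T))
    NE = np.zeros((L, T))
    NI = np.zeros((L, T))
    y = np.empty((L, T))

    v0 = params.v_rest
    for i in range(L):
        rng = np.random.default_rng(children[i])
        NE[i, :-1] = sample_synaptic_inputs(mu_E[:-1], q_E, 1, rng)[0] \
            if T > 1 else 0.0
        NI[i, :-1] = sample_synaptic_inputs(mu_I[:-1], q_I, 1, rng)[0] \
            if T > 1 else 0.0
        w = params.sigma_w * rng.standard_normal(T)
        eps = sigma_eps * rng.standard_normal(T)
        x = np.array([v0, 0.0, 0.0])
        V[i, 0], gE[i, 0], gI[i, 0] = x
        for t in range(T - 1):
            x = step_state(x, params, NE[i, t], NI[i, t], w[t])
            V[i, t + 1], gE[i, t + 1], gI[i, t + 1] = x
        y[i] = V[i] + eps

    return (TrialSet(y=y, dt=params.dt),
            GroundTruth(V=V, g_E=gE, g_I=gI, N_E=NE, N_I=NI))


# ---------------------------------------------------------------------------
# Ground-truth persistence (hierarchical binary container)
# ---------------------------------------------------------------------------

def save_ground_truth(path, truth: GroundTruth, dt: float,
                      meta: dict | None = None) -> None:
    """Store a GroundTruth bundle in an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        for key, arr in (("V", truth.V), ("gE", truth.g_E), ("gI", truth.g_I),
                         ("NE", truth.N_E), ("NI", truth.N_I)):
            f.create_dataset(key, data=arr)
        g = f.create_group("meta")
        g.attrs["dt"] = dt
        for k, v in (meta or {}).items():
            g.attrs[k] = v


def load_ground_truth(path):
    """Load a GroundTruth bundle saved by :func:`save_ground_truth`."""
    import h5py

    with h5py.File(path, "r") as f:
        truth = GroundTruth(V=f["V"][()], g_E=f["gE"][()], g_I=f["gI"][()],
                            N_E=f["NE"][()], N_I=f["NI"][()])
        meta = dict(f["meta"].attrs)
    return truth, meta
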