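# Methods

## The estimation problem

A neuron recorded in current-clamp mode shows a sub-threshold membrane
potential V(t) driven by two opposing synaptic conductances: excitatory
g_E(t) (reversal E_E = 0 mV) and inhibitory g_I(t) (reversal E_I = −80 mV).
Only V is observed, through additive Gaussian noise.  The task is to
recover both conductance time courses — in every individual trial — from
repeated presentations of the same stimulus.

The generative model is a passive (no active channels) membrane discretized
by forward Euler at step dt:

    V(t+1)   = V(t) + (dt/C_m)[g_L(E_L−V) + g_E(E_E−V) + g_I(E_I−V) + I_inj] + w(t)
    g_E(t+1) = g_E(t)(1 − dt/τ_E) + N_E(t)
    g_I(t+1) = g_I(t)(1 − dt/τ_I) + N_I(t)
    y(t)     = V(t) + ε(t)

with w ~ N(0, σ_w²), ε ~ N(0, σ_ε²), and nonnegative synaptic input
increments N_E, N_I whose time-varying mean and variance
θ = (μ_E(t), μ_I(t), Γ_E(t), Γ_I(t), σ_w², σ_ε²) are **common across
trials** while the realizations differ.  That shared structure is the
method's whole leverage: L repeated trials inform the common θ, and a good
θ in turn lets a per-trial filter track each trial's individual conductance
fluctuations.

## Units and membrane constants

Voltages in mV, time in ms, conductances in μS, currents in nA,
capacitance in nF.  Defaults: E_L = −60, E_E = 0, E_I = −80 mV,
τ_E = 3 ms, τ_I = 10 ms, dt = 2 ms, T = 1000 (2 s per trial),
g_L = 5 nS and C_m = 62.5 pF, i.e. τ_m = C_m/g_L = 12.5 ms and input
resistance 1/g_L = 200 MΩ.  This pairing was chosen so that the membrane
time constant and the current-clamp operating points are simultaneously
consistent: a +50 pA holding current depolarizes the quiescent cell by
10 mV (baseline −50 mV) and +130 pA holds it near −34 mV, the operating
range in which this recording protocol is used.  A nominally larger
capacitance with the same τ_m would make the baseline essentially
insensitive to the holding current (±200 pA would move it ±2.5 mV), which
contradicts how the protocol behaves.

## Multiple-trial Kalman filtering (MtKF)

**E-step.** For each trial an extended Kalman filter runs over the state
x = [V, g_E, g_I].  The dynamics are linear except the bilinear g·V terms
in the V row; the Jacobian row is
[1 − (dt/C_m)(g_L+g_E+g_I), (dt/C_m)(E_E−V), (dt/C_m)(E_I−V)].
The synaptic inputs enter as process noise with mean [0, μ_E(t), μ_I(t)]
and covariance diag(σ_w², Γ_E(t), Γ_I(t)); the observation matrix is
C = [1, 0, 0].  A fixed-interval (RTS) smoother follows, with lag-one
cross-covariances Cov(x(t+1), x(t) | Y) = P_smooth(t+1) G(t)ᵀ — the exact
identity for the RTS gain G(t), verified in the test suite against dense
joint-Gaussian conditioning.  Covariance updates use the Joseph form and
symmetrization; smoothed and filtered conductance means are floored at 0
(projection handling of the nonnegativity constraint that the Gaussian
filter cannot represent).

**M-step.** Inverting the conductance recursion, N(t) = g(t+1) − a·g(t)
with a = 1 − dt/τ, so each trial yields posterior input moments
μ_i(t), Γ_i(t) from the smoothed means, variances and lag-one covariances.
Pooling over trials:

    μ(t) = (1/L) Σ_i μ_i(t)
    Γ(t) = (1/L) Σ_i { Γ_i(t) + (μ(t) − μ_i(t))² }

— the law of total variance: average posterior uncertainty plus the spread
of the per-trial means.  No temporal smoothing is applied anywhere; pooling
across trials is what regularizes the per-time-step statistics.  The
per-trial means are deliberately **not** floored at zero before pooling
(that would bias the common mean upward by the posterior noise, roughly
2× at realistic SNR); nonnegativity is imposed on the pooled mean.
The observation variance update is the posterior expectation of (y − V)²;
an analogous expression exists for σ_w².

**Single-trial estimator and baselines.** StKF is exactly the L = 1 case
and shares the code path, so MtKF on one trial is bit-identical to StKF.
The two classical baselines — averaging the per-trial StKF estimates, and
running StKF on the trial-averaged trace — are implemented through the
same grouped engine (each trial its own parameter group).

## EM schedule, initialization, convergence

Joint estimation of per-time-step input statistics and the two noise
variances from a single observed coordinate is delicately identifiable,
and the EM landscape has self-confirming bad basins.  Three choices matter;
all are defaults of `fit_mtkf` and were validated on simulation:

1. **Warm-up (15 iterations).** Only μ and Γ are updated at first, with
   σ_w², σ_ε² held at their starting values.  Until the means explain the
   stimulus-locked voltage transients, a free noise update absorbs those
   transients into σ_ε² (observed: σ_ε² → 8 mV² when the true value is 1),
   after which the filter is effectively blind and cannot recover.

2. **σ_w² held fixed (default 10⁻³ mV²).** A free per-step variance on the
   observed coordinate is weakly identifiable against the conductance
   variances and acts as a sink for any model misfit; with it released the
   EM explains evoked transients as voltage noise instead of synaptic
   input.  σ_ε² is re-estimated after warm-up (its recovery is tested);
   σ_w² updating can be enabled explicitly.

3. **Data-scaled starting point.** The observed mean depolarization is
   inverted for a balanced tonic conductance (clamped; minimal-drive
   fallback where the inversion is singular, i.e. mean potential near
   (E_E+E_I)/2).  Starting the input means *small* is essential for
   excitation/inhibition disambiguation: with little tonic inhibition to
   remove, the nonnegativity of inputs forbids explaining depolarizing
   transients as "inhibition dropping" — the anti-phase mode that large
   initial drives converge to.  Initial variances are set generously at
   (2 μ₀)² because the EM shrinks overestimated variances far faster than
   it grows underestimated ones.

Convergence uses the relative change of the total log-likelihood with a
default tolerance of 10⁻³ and a cap of 50–60 iterations.  A 1% relative
tolerance is far too loose here — |log L| grows like L·T, so a 1% band is
hundreds of nats and stops the iteration before the input variances have
learned the trial-to-trial variability at all.  Any log-likelihood
*decrease* beyond tolerance (possible because of the truncation
projection) is recorded in the EM trace as a warning, as are clipped
negative posterior input variances.

## Multiple-trial particle filtering (MtPF)

The sequential-Monte-Carlo branch replaces the Gaussian input model by
exponential priors p[N(t)] = (1/μ(t)) exp(−N(t)/μ(t)) — nonnegative by
construction — with a bootstrap proposal, Gaussian observation weights,
and systematic resampling when the effective sample size falls below half
the ensemble.  The multiple-trial M-step is means-only (the exponential
has one parameter): the common μ(t) is the plain average of the per-trial
posterior input means, floored at a small ε = 10⁻⁷ μS so the density stays
proper.  σ_ε and σ_w are inputs, not estimated, in this branch.

Smoothed expectations use **fixed-lag ancestral tracing** (default lag 15
steps = 30 ms ≈ 3 τ_I): x(t) is averaged under the ensemble 15 steps
ahead, traced back through the resampling ancestry.  Full ancestral-path
averaging under the final weights — the naive choice — degenerates on 2 s
records (all paths coalesce to a handful of ancestors), which we measured
as normalized errors above 1 even at 10⁴ particles; the fixed lag restores
proper smoothing at 200 particles because observations further ahead than
a few synaptic time constants carry no information about N(t) anyway.

## Synthetic data: what it emulates and what it does not

Two stimulation regimes generate the common input means:

* **Structured** (stimulus-locked): 18 deflection responses at 10 Hz
  starting at 200 ms, each a difference-of-exponentials input transient
  with 15% per-pulse adaptation, mimicking whisker-evoked responses in
  barrel cortex: inhibition ~3× excitation at the conductance level
  (peaks ≈ 3 nS / 9 nS), delayed 2 ms, slower kinetics (rise/decay 4/20 ms
  vs 2/12 ms for excitation), on a small tonic background (0.2/0.3 nS).
* **Non-structured**: each stream's mean is the absolute value of white
  noise low-pass filtered with that stream's synaptic time constant,
  scaled to mean conductances of ~1 nS (excitatory) and ~2 nS
  (inhibitory); a fresh mean is drawn per replicate seed.

Per trial and per step, inputs are Poisson shot noise
N = q·Poisson(μ/q) with quantum q = 0.5 nS (a plausible unitary synaptic
conductance), giving trial-to-trial conductance fluctuations of order
50% of the mean — the high-variability regime in which pooling trials
has something to gain.  Observation noise is 1 mV (or 0.1 mV for the
high-SNR condition); dynamics noise σ_w = 0.05 mV per step.

The generator deliberately omits: active channels and spikes, electrode
artifacts, correlated (non-white) recording noise, cross-correlation
between excitatory and inhibitory inputs beyond their shared mean, and
slow non-stationarities (run-down, state changes).  Passing tests
therefore demonstrate correct inference *under the model class*, with
moment-mismatched inputs (Poisson truth vs truncated-Gaussian/exponential
inference models) as the only deliberate misspecification — they say
nothing about robustness to active conductances or correlated noise.

## Scoring

Per-trial RMSE (μS); the trial-variance-normalized error
Err = (1/T) Σ_t var_trials(g − ĝ)/var_trials(g) per channel (population
1/L variances; time points with numerically zero signal variance are
excluded and counted), averaged over channels with equal weight; and the
softmax-style total error log{exp(Err_E) + exp(Err_I)}, which is dominated
by the worse channel.  A trial-constant estimate has normalized error
exactly 1, which is why the averaging baselines sit at 1 independent of L.

## Experiment design choices and problem sizes

The trials sweep fixes an evaluation set of max(L) = 20 simulated trials
per seed; each method learns its statistics from the first L and produces
per-trial estimates for the whole evaluation set (the averaging baselines
tile their average).  The fixed evaluation set keeps the score comparable
across L and well-defined at L = 1.  Sweeps default to: trial grid
{1, 2, 5, 10, 20}, current grid −200…200 pA in 25 pA steps (the
acceptance script uses 50 pA steps), 10 seeds, EM capped at 40 iterations,
and 200–400 particles for the particle branch — sizes chosen to keep a
full reproduction run in the tens of minutes on one core.  The baseline
membrane potential is measured on the pre-stimulus window (structured) or
after a 200 ms burn-in (non-structured).

## Known limitations

* The truncated-Gaussian input model is handled by projection (flooring
  conductance means at zero), not by moment-matched truncated updates; the
  projection can produce small likelihood decreases, which are surfaced in
  the EM trace rather than hidden.
* At strongly depolarized or hyperpolarized holding currents one channel's
  driving force is small; its per-trial fluctuations become unidentifiable
  and the estimator shrinks toward the trial mean (normalized error ≈ 1)
  instead of blowing up.  Consequently the total-error-vs-current curve is
  shallow: with a 1 mV observation noise it varies by only a few
  hundredths over −200…+200 pA, so the *location* of its minimum is
  fragile even though the qualitative channel asymmetries (inhibition
  poorly resolved when hyperpolarized, excitation when depolarized) are
  robust.
* With dt = 2 ms and τ_E = 3 ms the excitatory conductance has a memory of
  ~1.5 samples; at 1 mV noise its single-trial fluctuations are close to
  the resolvability limit at physiological amplitudes, which bounds how
  much of the excitatory trial-to-trial variance any estimator can
  recover in the low-SNR condition.
* The particle branch's fixed-lag smoother trades a small bias (ignoring
  observations > 30 ms ahead) for immunity to path degeneracy.
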