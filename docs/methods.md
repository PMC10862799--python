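# Methods

This note documents the models, algorithms and numerical choices behind
`npbddm`: what is computed, under which assumptions, and which knobs matter.

## The decision model

A trial presents random-dot motion with signed coherence `coh` drawn from
{0, ±3.2, ±6.4, ±12.8, ±25.6, ±51.2 %} (zero carries double weight, so the
mixture matches a 12-entry design list).  The decision variable follows a
Wiener process with drift

```
dx = kappa * coh * dt + dW,
```

unit diffusion standard deviation, starting at `x = 0`.  The diffusion
scale, `kappa`, and the bound height are jointly unidentifiable, so the
diffusion s.d. is fixed at 1 and `kappa` (units: evidence·s⁻¹ per unit
coherence) carries the signal-to-noise ratio.  Decisions terminate when
`x` first touches the symmetric, time-varying absorbing bounds `±B(t)`
(upper bound → rightward choice).  Reaction time adds a non-decision
latency `Tnd ~ N(mu_nd, sigma_nd²)`; negative draws are clamped to zero
(the model is silent there and the clamp keeps RT ≥ decision time).

The task economy: +1 point for a correct choice, −1 for an error, 0 for
aborts and cancellations; inter-trial interval 2.0 s; miscellaneous
latencies 0.7 s per completed trial and 0.4 s per canceled trial.  In the
deadline phase, half the trials carry a latent provisional deadline drawn
from a time-shifted Rayleigh distribution with shift `t0` and scale
`sigma_dl` (mean `t0 + sigma*sqrt(pi/2)`, s.d. `sigma*sqrt((4-pi)/2)`);
if no response has occurred by the deadline the trial is canceled.
Participants are instructed to maximize points per unit time, which makes
the earning rate the central quantity throughout.

## Forward simulation (`ddm_sim`)

Euler–Maruyama with step 0.5 ms by default.  Between grid points a
Brownian-bridge crossing test is applied (crossing probability
`exp(-2(B-x_k)(B-x_{k+1})/dt)` per side), so first-passage statistics are
those of the continuously monitored process rather than of the Euler grid;
without the bridge, the effective boundary sits ≈ `0.58*sqrt(dt)` outside
the nominal one, which is visible against closed-form flat-bound results.
Trials still undecided at the 5-s viewing limit are recorded as aborted
(rare under realistic bounds).  Spontaneous aborts (blinks, broken
fixation) are modeled, when enabled, as an independent Bernoulli event per
trial with a configurable time cost (default: the canceled-trial
miscellaneous time plus the inter-trial interval); they only affect the
earning rate.  The earning rate divides the point tally by the summed
trial times (misc + RT + ITI when completed; misc_cancel + deadline + ITI
when canceled).

## Fokker–Planck propagation (`fokker_planck`)

Per signed coherence the density obeys
`du/dt = d/dx(-mu u) + D d²u/dx²` with `D = 1/2`.  One step of the fully
implicit Chang–Cooper scheme advances the cell masses: fluxes
`F_{j+1/2} = a[(1-d) u_{j+1} + d u_j] + (D/dx)(u_{j+1}-u_j)` with
`a = -mu` and the exponential-fitting weight `d(w) = 1/w - 1/(e^w - 1)`,
`w = a dx / D`, assembled into a tridiagonal system `(I - dt L) u' = u`.
The flux form with zero-flux grid ends conserves mass to solver round-off
(tested at 1e-9), and the implicit step is positivity-preserving even from
a delta initial condition.

The absorbing bounds are imposed *inside* the solve: the cells straddling
`±B` couple to a zero-valued ghost point at the exact fractional distance
to the bound (cut-cell Dirichlet), and absorbed probability is tallied
from the two discrete boundary fluxes, which balances the interior mass
loss exactly.  Two properties motivated this over absorbing by zeroing
after the step: the scheme responds continuously to the bound height (no
staircase when bounds are derived by root finding), and it reproduces the
continuous-time flat-bound closed forms — choice probability
`1/(1+e^{-2 mu B})` to ~1e-9 and mean decision time `(B/mu) tanh(mu B)`
to ~2.5e-4 s at `dt = 0.5 ms`, `dx = 0.01` — whereas end-of-step zeroing
carries the same `0.58*sqrt(dt)` discrete-monitoring boundary offset as a
plain Euler simulation (≈1e-2 s errors in mean decision time at 0.5 ms).

Grid defaults: `dx = 0.01` evidence units, `dt = 0.5 ms`, extent set by
the caller to comfortably exceed the largest bound in play (the
convergence check in the test suite shows halving `dx` moves flat-bound
exit probabilities by < 1e-4).  The inner tridiagonal/boundary kernels are
compiled with numba when available, with an equivalent pure-NumPy
fallback.

## Nonparametric bound derivation (`npb_ddm`)

Given `theta = (kappa, mu_nd, sigma_nd)` the decision-time distribution
uniquely determines the bound shape; the inversion alternates two steps on
the 0.5-ms grid:

1. **Propagation** of each coherence's density one step (above).
2. **Match**: place `B(t)` so that the prior-weighted mass absorbed this
   step equals `p_Td(t) dt`, the empirical probability of a decision
   terminating now.  Absorbed mass is monotone in `B`, so the height is
   found by bisection over `[0, x_max]` (warm-started from the previous
   step's bound; tolerance 1e-7 in height).

`p_Td` is estimated from `Td_i = RT_i - mu_nd` by an Epanechnikov kernel
density with standard deviation 0.1 s (half-width `0.1*sqrt(5)` ≈ 0.224 s
— the s.d., not the support, is the specified quantity), truncated to
`t > 0` and renormalized.  Iteration stops when 1 − 1e-4 of the mass has
been absorbed or the 5-s horizon is reached.  If the smoothed density ever
demands more exit mass than remains unabsorbed, the bound is clamped to
zero from that step on and a warning is raised; the intended behavior in
that regime is not derivable from first principles, so the clamp simply
realizes "everything exits as soon as possible".

**Smoothing bias and deconvolution.**  First-passage densities rise very
steeply at onset (the strongest coherence terminates with an s.d. of
~0.05 s under participant-like parameters), and a 0.1-s kernel flattens
that structure; bounds derived from the smoothed density are biased
(too low just before the onset, too high on the rising flank).  Because
the kernel is known exactly, `estimate_decision_time_density` can undo
most of this with Van Cittert deconvolution (default 5 iterations,
positivity-clipped, truncated below the smallest observed decision time).
With it, recovery of a known linear collapse from 1e4 simulated trials is
accurate to ~6–7 % (max over the 5th–95th decision-time percentiles,
~2 % mean) versus ~17 % without; the residual is irreducible from the
smoothed data since the kernel's Fourier response crosses zero at the
onset scale.  Deriving from the *exact* model density recovers known
bounds to better than 0.1 %, which isolates the inversion itself from the
density-estimation error.  Deconvolution is off during maximum-likelihood
fitting: sharpening interacts with the candidate `mu_nd` through the
support truncation and measurably tilts the likelihood ordering across
`theta`, whereas the plain KDE ranks the generating parameters highest.

**Fitting.**  `NonparametricBoundDDM` maximizes the joint likelihood of
single-trial (RT, choice) pairs.  Inside every evaluation the bounds are
re-derived from the data with the candidate `(kappa, mu_nd)` — the bound
is data-determined, never a free parameter — and the per-coherence
first-passage densities are convolved with the (zero-censored) Gaussian
non-decision distribution to give the joint predictive, evaluated at the
trial RTs by linear interpolation with a 1e-10 likelihood floor.
Coherence weights default to the fitted dataset's empirical frequencies.
Optimization is Nelder–Mead over `(log kappa, mu_nd, log sigma_nd)` with
optional jittered restarts; `sigma_nd` is floored at 1 ms.  On 2000
simulated trials with a collapsing bound, the median recovery error over
ten seeds is ~4 % in `kappa` and ~20 ms in `mu_nd` (grid `dt = 5 ms`,
`dx = 0.02` inside the fit; those are the problem sizes used by the
validation suite, and finer grids change the optimum negligibly).

## Optimal policy (`optimal_policy`)

States are `<x, t>` on a grid (`dx = 0.02`, `dt = 0.5 ms` by default,
horizon 5 s, `|x| <= 4`); actions are left, right, fix.  Terminating earns
the expected points of the chosen side under the coherence posterior
`p(coh|x,t) ∝ N(x | kappa coh t, t) p(coh)` minus
`rho*(iti + misc + mu_nd)`; the posterior is valid under any bound shape
or deadline scheme because those factors are coherence-independent (a
property the test suite checks against surviving Monte-Carlo
trajectories).  Zero-coherence trials are scored correct with probability
one half.  Fixation costs `rho*dt` and moves `x` by the
posterior-weighted mixture of per-coherence Gaussian steps; the step
kernels are point-sampled Gaussians renormalized on the grid (bin
integration would inflate the per-step variance by `dx²/12`, which is
what stops the solved rate from converging as `dt` shrinks).  In the
deadline phase fixation additionally risks cancellation with hazard
`p(d+|t) * dt * (t - t0 + mu_nd)/sigma²` for `t > t0 - mu_nd`, where
`p(d+|t)` updates the deadline-carrying probability by Bayes' rule using
the Rayleigh survival function (the deadline acts on the stimulus clock,
hence the `mu_nd` shift onto the decision clock).

Backward induction runs from the horizon (forced choice) to zero; the
earning rate `rho*` is the root of `V(<0,0>; rho) = 0`, found by bisection
on [−0.5, 0.5] points/s to 1e-6.  The fix/terminate frontier, linearly
interpolated in `x`, is exported as the optimal bound curve.  At the
default task parameters the solution collapses over time after an early
transient (the frontier starts at the grid edge where information value
dominates), forward simulation under the exported bounds reproduces
`rho*` within Monte-Carlo error, and adding the deadline hazard lowers the
bounds pointwise across the span containing 98 % of decisions.  Late
beyond that span the ordering can invert by ~1 % of the bound height:
the hazard has decayed while the deadline phase's lower `rho*` cheapens
time; comparisons are therefore made over the 1st–99th percentile span of
decision times, which is also how bound curves are displayed.

## Bound scaling and the permutation test (`bound_scaling`)

`B'(t) = s_m B(t/s_t)` (holding the final value beyond the base support)
is fitted to trial data by maximum likelihood with `theta` held fixed,
via a 5×5 grid over the factors followed by Nelder–Mead in log-scale
coordinates.  Fit quality relative to the full nonparametric fit is
reported per trial.  One caveat the validation suite documents: because
the nonparametric bounds target the kernel-smoothed decision-time density,
they are not exactly likelihood-stationary, and rescaling a dataset's own
bounds can still gain ~0.015 nats/trial (at `s` within 10 % of unity).
The cross-fitting *ranking* is unaffected, since within a row it compares
scaled fits only.

The exact permutation test enumerates all `n^n` equally likely diagonal
rank patterns of the n×n cross-fitting rank matrix (256 for four
datasets) and reports the fraction whose rank sum does not exceed the
observed sum.  Within-row ranks order fits by descending quality; exact
ties raise an error (they are measure-zero for continuous likelihoods).

## Behavioral statistics (`behavior_stats`)

RT phase differences: ordinary least squares of RT on one indicator per
motion strength plus a phase indicator, fitted separately to correct and
error trials; the phase coefficient is t-tested.  Accuracy: intercept-free
logistic regression `logit(p) = beta1 |coh| + betaPhase I_phase` (per
participant, or with per-participant strength slopes when pooling), with
a likelihood-ratio test against the nested model; the missing intercept
pins chance accuracy at zero coherence.  Under a null generator the LR
test's type-I error is calibrated (checked at 200 replicates).  Both
models are computed by statsmodels and verified against normal-equation /
IRLS recomputation.  Time-dependent accuracy uses RT-sorted sliding
windows of 100 trials (stride 1) per motion strength.
Cancellation-aligned RTs are z-scored within motion strength, then
averaged at trial lags ±5 around each cancellation, truncating at session
boundaries; lags that cross a neighboring cancellation are included.

## Synthetic data

`simulate_phase` is the package's data generator and emulates the task as
modeled: the design coherence mixture, DDM decision times under a given
bound, Gaussian non-decision times, scoring, Rayleigh deadlines with
cancellation, and Bernoulli aborts.  Defaults follow the task constants
above; participant-like settings used throughout the tests are
`kappa ≈ 16.2`, `mu_nd ≈ 0.27 s`, `sigma_nd ≈ 0.02 s` with a linear
collapse `B(t) = 1 − 0.15 t`.  What it does not emulate: sequential
adaptation (bound adjustments after cancellations arise only if the caller
changes bounds between simulated blocks), learning or session drift,
lapses, and any asymmetry between leftward and rightward responses.
Passing tests therefore certify the computational pipeline under the
model's own assumptions, not the behavior of real observers.

## Known limitations

- Bound recovery from finite samples inherits the 0.1-s smoothing
  resolution; structure faster than the kernel (the onset flank) is
  attenuated, and the Van Cittert refinement recovers it only partially.
- The derived bounds are a density-matching construction, not an ML
  optimum; likelihood comparisons against more flexible families should
  use the scaled-fit machinery's conventions (fixed `theta`, per-trial
  normalization) to stay interpretable.
- The policy solver assumes the observer knows the task constants and the
  coherence prior exactly, and its action grid tie-breaks (`>=` toward
  terminating right) matter only on measure-zero ties at `x = 0`.
- Deadline cancellation in the simulator uses each trial's realized
  non-decision time, while the solver's hazard uses its mean; the
  difference is second order in `sigma_nd`.
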