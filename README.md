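# npbddm

Bounded drift-diffusion decision making with **data-derived stopping
bounds**: tools for analyzing (and simulating) reaction-time
random-dot-motion experiments in which observers trade speed against
accuracy to maximize their points earning rate.

The package is for computational/psychophysics researchers who want to

- simulate the full task economy — weighted coherence mixture
  {0, ±3.2, …, ±51.2 %}, ±1-point scoring, inter-trial costs, and
  surreptitious *provisional deadlines* (shifted-Rayleigh cancellation
  times) — under a drift-diffusion decision rule with arbitrary
  time-varying bounds;
- invert empirical RT distributions into the bound shape itself
  (the **nonparametric-bound DDM**, npb-DDM);
- compute the **reward-rate-optimal stopping policy** by dynamic
  programming and compare observed against optimal bounds;
- test whether bound *shape* is idiosyncratic via two-parameter bound
  scaling and an exact permutation test.

## The model in brief

The decision variable accumulates momentary evidence,
`dx = κ·coh·dt + dW` (unit diffusion), until it hits symmetric absorbing
bounds `±B(t)`; the crossing fixes choice and decision time, and RT adds a
Gaussian non-decision latency `N(μnd, σnd²)`.  For the npb-DDM, `B(t)` is
not a parametric form: at each time step the Fokker–Planck-propagated
density (fully implicit Chang–Cooper scheme, exact cut-cell absorbing
boundaries) is matched to the kernel-smoothed empirical decision-time
density `p_Td(t)`, placing the bound where the absorbed probability mass
equals the observed termination probability.  Only `θ = (κ, μnd, σnd)`
remains free and is fitted by maximizing
`∏_i P(RT_i, choice_i | θ, coh_i)`, re-deriving bounds from the data
inside every likelihood evaluation.  The optimal policy solves the Bellman
equations over states ⟨x, t⟩ with actions {left, right, fix}, coherence
posterior `p(coh|x,t) ∝ N(x | κ·coh·t, t)·p(coh)`, a Rayleigh cancellation
hazard in the deadline phase, and the earning rate ρ found by bisection on
`V(⟨0,0⟩; ρ) = 0`.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```python
import numpy as np
from npbddm import (BoundCurve, DDMParams, TaskConfig, DeadlineSpec,
                    simulate_phase, earning_rate, filter_standard_trials,
                    rayleigh_moments, solve_policy, permutation_rank_pvalue)

rng = np.random.default_rng(0)
theta = DDMParams(kappa=16.19, mu_nd=0.27, sigma_nd=0.02)
bounds = BoundCurve.linear_collapse(1.0, 0.15, 5.0)   # B(t) = 1 - 0.15 t
task = TaskConfig()

trials = simulate_phase(theta, bounds, task, 1000, rng, dt=0.001)
standard = filter_standard_trials(trials)
acc = np.mean([t.outcome == "correct" for t in standard])
print(f"{len(standard)} completed trials, accuracy {acc:.3f}, "
      f"earning rate {earning_rate(trials, task):.2f} points/min")

sol = solve_policy(theta.kappa, theta.mu_nd, task, dt=0.0025, dx=0.02)
print(f"optimal earning rate rho* = {sol.rho * 60:.2f} points/min; "
      f"optimal bound at t = 0.5 s: {sol.bounds(0.5):.3f}")

mean, sd = rayleigh_moments(DeadlineSpec(t0=0.6, sigma_dl=0.7))
print(f"provisional deadlines: mean {mean:.2f} s, s.d. {sd:.2f} s")
print(f"cross-fitting permutation test, diagonal ranks [1, 2, 1, 1]: "
      f"p = {permutation_rank_pvalue([1, 2, 1, 1]):.3f}")
```

prints

```
1000 completed trials, accuracy 0.838, earning rate 11.68 points/min
optimal earning rate rho* = 11.91 points/min; optimal bound at t = 0.5 s: 0.936
provisional deadlines: mean 1.48 s, s.d. 0.46 s
cross-fitting permutation test, diagonal ranks [1, 2, 1, 1]: p = 0.020
```

The simulated observer, using a plausible hand-set collapsing bound, earns
11.68 points/min — within 2 % of the 11.91 points/min the
dynamic-programming solution identifies as optimal for the same
sensitivity and non-decision time.  A deadline design with shift 0.6 s and
scale 0.7 s cancels trials at a mean latency of 1.48 s, and a
cross-fitting rank diagonal of [1, 2, 1, 1] is as extreme or more under
the uniform null with probability 5/256 ≈ 0.020.

Fitting the npb-DDM to a trial table is one estimator call
(scikit-learn conventions: parameters in the constructor, fitted
attributes with trailing underscores):

```python
from npbddm import NonparametricBoundDDM
est = NonparametricBoundDDM(dt=0.005, dx=0.02, random_state=0).fit(standard)
est.kappa_, est.mu_nd_, est.sigma_nd_, est.bounds_   # fitted θ and B(t)
```

A `npbddm` command-line tool exposes the same pipelines
(`simulate`, `fit-npb`, `optimal`, `scale-fit`, `stats`); every subcommand
reads/writes CSV tables and honors a global `--seed`.

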