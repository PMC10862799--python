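"""Reward-rate-optimal stopping policy by dynamic programming.

The decision problem is a Markov decision process over states ``<x, t>``
(accumulated evidence, elapsed decision time) with actions left / right /
fix.  Terminating yields the expected points of the chosen side (correct
+1, error -1) minus the opportunity cost ``rho * (iti + misc + mu_nd)``;
fixating accrues ``rho * dt`` and diffuses the evidence under the
coherence-marginal transition kernel, with the coherence posterior updated
by Bayes' rule.  In the deadline phase, fixating additionally risks trial
cancellation with the shifted-Rayleigh hazard.  The optimal earning rate
``rho*`` is the root of ``V(<0, 0>; rho) = 0``, located by bisection; the
fix/terminate frontier of the optimal policy is the implied time-varying
decision bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .bounds import BoundCurve
from .trial_data import COHERENCES, COHERENCE_WEIGHTS, DeadlineSpec, TaskConfig


@dataclass(frozen=True)
class PolicySolution:
    """Optimal earning rate, implied bounds and diagnostics."""

    rho: float                      # points per second
    bounds: BoundCurve
    v0: float                       # V(<0,0>) at rho (residual, ~0)
    n_bisections: int
    action_map: np.ndarray | None = field(default=None, repr=False)
    value: np.ndarray | None = field(default=None, repr=False)
    x_grid: np.ndarray | None = field(default=None, repr=False)


def coherence_posterior(x, t: float, kappa: float, coherences=COHERENCES,
                        priors=COHERENCE_WEIGHTS) -> np.ndarray:
    """Posterior over signed coherences given evidence ``x`` at time ``t``.

    ``p(coh_i | x, t) ~ N(x | kappa*coh_i*t, t) * p(coh_i)``.  The ratio
    between any two coherences is unaffected by the presence of absorbing
    bounds or provisional deadlines (those factors are coherence
    independent), so this expression is valid during deliberation under any
    stopping policy.  At ``t = 0`` the posterior equals the priors.

    Returns an array of shape ``(n_coh,) + shape(x)``.
    """
    coherences = np.asarray(coherences, dtype=float)
    priors = np.asarray(priors, dtype=float)
    x = np.asarray(x, dtype=float)
    if t <= 0:
        out = np.broadcast_to(priors.reshape((-1,) + (1,) * x.ndim),
                              priors.shape + x.shape)
        return np.array(out, dtype=float)
    means = kappa * coherences * t
    # subtract the max exponent for numerical stability
    z = -((x[None, ...] - means.reshape((-1,) + (1,) * x.ndim)) ** 2) / (2.0 * t)
    z -= z.max(axis=0, keepdims=True)
    w = np.exp(z) * priors.reshape((-1,) + (1,) * x.ndim)
    return w / w.sum(axis=0, keepdims=True)


def _step_kernels(kappa: float, coherences, dx: float, dt: float) -> np.ndarray:
    """Per-coherence discretized Gaussian step kernels.

    Row i is the probability of a displacement of ``j*dx`` (j centred) in
    one step under coherence i: the ``N(kappa*coh_i*dt, dt)`` density
    sampled at the grid offsets and renormalized.  Point sampling (rather
    than bin integration) keeps the kernel variance at ``dt`` to within an
    exponentially small aliasing error for ``sqrt(dt) >~ dx``, which is
    what makes the solved earning rate converge as ``dt`` shrinks.
    """
    coherences = np.asarray(coherences, dtype=float)
    sd = math.sqrt(dt)
    w = max(1, int(math.ceil(5.0 * sd / dx)))
    offsets = np.arange(-w, w + 1) * dx
    kernels = np.empty((coherences.size, offsets.size))
    for i, coh in enumerate(coherences):
        k = norm.pdf(offsets, loc=kappa * coh * dt, scale=sd)
        kernels[i] = k / k.sum()
    return kernels


def transition_kernel(x: float, t: float, kappa: float,
                      coherences=COHERENCES, priors=COHERENCE_WEIGHTS,
                      dx: float = 0.02, dt: float = 0.0005) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the next evidence value after one ``fix`` step.

    Marginalizes the per-coherence Gaussian displacement over the coherence
    posterior at ``<x, t>``.  Returns ``(next_x_values, probabilities)``.
    """
    post = coherence_posterior(np.asarray(x, dtype=float), t, kappa,
                               coherences, priors)
    kernels = _step_kernels(kappa, coherences, dx, dt)
    probs = post.reshape(-1, 1) * kernels
    probs = probs.sum(axis=0)
    w = (kernels.shape[1] - 1) // 2
    next_x = x + np.arange(-w, w + 1) * dx
    return next_x, probs / probs.sum()


def cancel_hazard(t: float, spec: DeadlineSpec, mu_nd: float, dt: float,
                  deadline_fraction: float = 0.5) -> float:
    """Probability that the trial is canceled in ``[t, t + dt)``.

    ``t`` is on the decision clock, hence the deadline distribution is
    shifted by the mean non-decision time.  The hazard combines the
    Rayleigh hazard with the posterior probability that this trial carries
    a deadline given that none has occurred yet (Bayes over the mixing
    fraction of deadline trials; survival on no-deadline trials is 1).
    """
    ts = t - spec.t0 + mu_nd
    if ts <= 0:
        return 0.0
    s2 = spec.sigma_dl ** 2
    surv = math.exp(-0.5 * ts * ts / s2)
    f = deadline_fraction
    p_dplus = f * surv / (f * surv + (1.0 - f))
    return p_dplus * dt * ts / s2


def solve_policy(
    kappa: float,
    mu_nd: float,
    task: TaskConfig,
    coherences=COHERENCES,
    priors=COHERENCE_WEIGHTS,
    dt: float = 0.0005,
    dx: float = 0.02,
    x_max: float = 4.0,
    horizon: float = 5.0,
    rho_bracket: tuple[float, float] = (-0.5, 0.5),
    rho_tol: float = 1e-6,
    keep_grids: bool = False,
) -> PolicySolution:
    """Optimal stopping policy maximizing the points earning rate.

    Backward induction over ``t`` from the viewing horizon (where the only
    actions are left/right) to 0 for a candidate rate ``rho``; the optimal
    ``rho*`` makes the initial-state value zero and is found by bisection
    on ``rho_bracket``.  With a deadline phase (``task.deadline`` set and
    ``task.deadline_fraction > 0``), fixation carries the cancellation
    hazard and its time cost.

    Returns the solution with the fix/terminate frontier as a
    :class:`BoundCurve` (linear interpolation of the value crossover).
    """
    coherences = np.asarray(coherences, dtype=float)
    priors = np.asarray(priors, dtype=float)
    n_half = int(round(x_max / dx))
    x = np.arange(-n_half, n_half + 1) * dx
    nx = x.size
    n_steps = int(round(horizon / dt))
    kernels = _step_kernels(kappa, coherences, dx, dt)
    w = (kernels.shape[1] - 1) // 2
    pos = coherences > 0
    zero = coherences == 0

    term_time = task.iti_s + task.misc_s + mu_nd
    cancel_time = task.iti_s + task.misc_cancel_s + mu_nd
    has_deadline = task.deadline is not None and task.deadline_fraction > 0
    if has_deadline:
        haz = np.array([
            cancel_hazard(k * dt, task.deadline, mu_nd, dt,
                          task.deadline_fraction)
            for k in range(n_steps)
        ])

    # p(correct | right choice) at every (t, x): independent of rho
    def p_right_correct(t: float) -> np.ndarray:
        post = coherence_posterior(x, t, kappa, coherences, priors)
        return post[pos].sum(axis=0) + 0.5 * post[zero].sum(axis=0)

    prc = [p_right_correct(k * dt) for k in range(n_steps + 1)]

    def backward(rho: float, keep: bool = False):
        pR = prc[n_steps]
        q_right = pR * task.reward_correct + (1 - pR) * task.reward_error \
            - rho * term_time
        q_left = (1 - pR) * task.reward_correct + pR * task.reward_error \
            - rho * term_time
        v = np.maximum(q_left, q_right)
        bound_vals = np.empty(n_steps + 1)
        bound_vals[n_steps] = 0.0
        actions = np.empty((n_steps + 1, nx), dtype=np.int8) if keep else None
        values = np.empty((n_steps + 1, nx)) if keep else None
        if keep:
            actions[n_steps] = np.where(q_right >= q_left, 1, -1)
            values[n_steps] = v
        for k in range(n_steps - 1, -1, -1):
            t = k * dt
            vp = np.concatenate([np.full(w, v[0]), v, np.full(w, v[-1])])
            post = coherence_posterior(x, t, kappa, coherences, priors)
            ev = np.zeros(nx)
            for i in range(coherences.size):
                ev += post[i] * np.convolve(vp, kernels[i][::-1], mode="valid")
            if has_deadline and haz[k] > 0:
                pc = haz[k]
                q_fix = (1 - pc) * (ev - rho * dt) + pc * (
                    task.reward_cancel - rho * cancel_time)
            else:
                q_fix = ev - rho * dt
            pR = prc[k]
            q_right = pR * task.reward_correct + (1 - pR) * task.reward_error \
                - rho * term_time
            q_left = (1 - pR) * task.reward_correct + pR * task.reward_error \
                - rho * term_time
            q_term = np.maximum(q_left, q_right)
            v = np.maximum(q_term, q_fix)
            bound_vals[k] = _frontier(x, q_fix - q_term)
            if keep:
                actions[k] = np.where(q_fix >= q_term, 0,
                                      np.where(q_right >= q_left, 1, -1))
                values[k] = v
        v0 = float(v[n_half])
        return v0, bound_vals, actions, values

    lo, hi = rho_bracket
    f_lo, _, _, _ = backward(lo)
    f_hi, _, _, _ = backward(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(
            f"rho bracket does not straddle the root: V(s0)={f_lo:.4f} at "
            f"rho={lo}, {f_hi:.4f} at rho={hi}")
    n_iter = 0
    while hi - lo > rho_tol:
        mid = 0.5 * (lo + hi)
        f_mid, _, _, _ = backward(mid)
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
        n_iter += 1
    rho = 0.5 * (lo + hi)
    v0, bound_vals, actions, values = backward(rho, keep=keep_grids)
    return PolicySolution(
        rho=rho,
        bounds=BoundCurve(dt=dt, values=bound_vals),
        v0=v0,
        n_bisections=n_iter,
        action_map=actions,
        value=values,
        x_grid=x if keep_grids else None,
    )


def _frontier(x: np.ndarray, margin: np.ndarray) -> float:
    """Positive-x crossover of the fix-vs-terminate margin, interpolated.

    ``margin >= 0`` means fixation is (weakly) preferred.  Scans outward
    from x = 0; returns 0 when terminating is preferred everywhere.
    """
    c = x.size // 2
    if margin[c] < 0:
        return 0.0
    for j in range(c, x.size - 1):
        if margin[j + 1] < 0:
            # linear interpolation of the sign change
            frac = margin[j] / (margin[j] - margin[j + 1])
            return float(x[j] + frac * (x[j + 1] - x[j]))
    return float(x[-1])
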