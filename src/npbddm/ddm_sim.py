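"""Forward simulation of bounded drift-diffusion decisions and task sessions.

The decision variable follows ``dx = kappa * coh * dt + dW`` (unit diffusion)
between symmetric absorbing bounds ``+-B(t)``; the first crossing fixes the
choice and the decision time.  Reaction time adds a Gaussian non-decision
latency truncated at zero.  Sessions add the task economy: weighted coherence
sampling, scoring (+1 / -1 / 0), optional provisional deadlines drawn from a
time-shifted Rayleigh distribution (Phase II), aborts, and the earning rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .bounds import BoundCurve
from .trial_data import DeadlineSpec, TaskConfig, TrialRecord


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters: drift sensitivity and non-decision time.

    Drift for a trial with signed coherence ``coh`` is ``kappa * coh``; the
    diffusion standard deviation is fixed at 1 (jointly unidentifiable with
    ``kappa`` and the bound height).  Non-decision time is Gaussian
    ``N(mu_nd, sigma_nd^2)``, truncated at zero when realized.
    """

    kappa: float
    mu_nd: float
    sigma_nd: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.mu_nd <= 0:
            raise ValueError("mu_nd must be positive")
        if self.sigma_nd < 0:
            raise ValueError("sigma_nd must be non-negative")


class SimulatedTrial(NamedTuple):
    choice: str | None          # "left" / "right"; None if unterminated
    decision_time_s: float
    rt_s: float


def sample_deadline(spec: DeadlineSpec, rng: np.random.Generator, size=None):
    """Draw provisional deadlines from the time-shifted Rayleigh distribution."""
    return spec.t0 + rng.rayleigh(scale=spec.sigma_dl, size=size)


def rayleigh_moments(spec: DeadlineSpec) -> tuple[float, float]:
    """Mean and s.d. of the shifted Rayleigh deadline distribution.

    mean = t0 + sigma * sqrt(pi / 2);  sd = sigma * sqrt((4 - pi) / 2).
    """
    mean = spec.t0 + spec.sigma_dl * math.sqrt(math.pi / 2.0)
    sd = spec.sigma_dl * math.sqrt((4.0 - math.pi) / 2.0)
    return mean, sd


def simulate_decision_times(
    drifts: np.ndarray,
    bounds: BoundCurve,
    rng: np.random.Generator,
    dt: float = 0.0005,
    t_max: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama first-passage simulation for a batch of trials.

    Parameters
    ----------
    drifts : array of per-trial drift rates (kappa * signed coherence).

    Between grid points a Brownian-bridge crossing test corrects for
    discrete monitoring, so first-passage statistics are those of the
    continuous-time process rather than of the Euler grid.

    Returns
    -------
    sign : int array; +1 upper bound (right), -1 lower (left), 0 unterminated.
    decision_time_s : float array; NaN where unterminated.
    """
    drifts = np.asarray(drifts, dtype=float)
    n = drifts.size
    sign = np.zeros(n, dtype=int)
    dec_t = np.full(n, np.nan)

    if bounds(0.0) <= 0.0:
        # Degenerate bound: decisions terminate immediately with a coin flip.
        sign[:] = np.where(rng.random(n) < 0.5, 1, -1)
        dec_t[:] = 0.0
        return sign, dec_t

    x = np.zeros(n)
    alive = np.arange(n)
    sqdt = math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for k in range(1, n_steps + 1):
        t = k * dt
        xa_prev = x[alive].copy()
        x[alive] += drifts[alive] * dt + sqdt * rng.standard_normal(alive.size)
        b = float(bounds(t))
        xa = x[alive]
        hit = np.abs(xa) >= b
        # Brownian-bridge crossing probabilities for paths ending inside
        inside = ~hit
        if inside.any() and b > 0:
            xp, xn = xa_prev[inside], xa[inside]
            p_up = np.exp(np.minimum(0.0, -2.0 * (b - xp) * (b - xn) / dt))
            p_lo = np.exp(np.minimum(0.0, -2.0 * (b + xp) * (b + xn) / dt))
            u = rng.random(xp.size)
            bridge_up = u < p_up
            bridge_lo = (~bridge_up) & (u < p_up + p_lo)
            sub = np.flatnonzero(inside)
            hit[sub[bridge_up]] = True
            xa = xa.copy()
            xa[sub[bridge_up]] = b
            hit[sub[bridge_lo]] = True
            xa[sub[bridge_lo]] = -b
        if hit.any():
            idx = alive[hit]
            xh = xa[hit]
            s = np.sign(xh)
            zero = s == 0
            if zero.any():
                s[zero] = np.where(rng.random(int(zero.sum())) < 0.5, 1, -1)
            sign[idx] = s.astype(int)
            dec_t[idx] = t
            alive = alive[~hit]
            if alive.size == 0:
                break
    return sign, dec_t


def simulate_trial(
    params: DDMParams,
    bounds: BoundCurve,
    coh: float,
    rng: np.random.Generator,
    dt: float = 0.0005,
    t_max: float = 5.0,
) -> SimulatedTrial:
    """Simulate a single decision; RT = decision time + truncated Tnd draw."""
    sign, dec_t = simulate_decision_times(
        np.array([params.kappa * coh]), bounds, rng, dt=dt, t_max=t_max
    )
    if sign[0] == 0:
        return SimulatedTrial(None, math.nan, math.nan)
    tnd = max(0.0, rng.normal(params.mu_nd, params.sigma_nd)) if params.sigma_nd > 0 \
        else params.mu_nd
    choice = "right" if sign[0] > 0 else "left"
    return SimulatedTrial(choice, float(dec_t[0]), float(dec_t[0]) + tnd)


def simulate_phase(
    params: DDMParams,
    bounds: BoundCurve,
    task: TaskConfig,
    n_trials: int,
    rng: np.random.Generator,
    *,
    participant: str = "sim",
    phase: str = "I",
    session: int = 1,
    dt: float = 0.0005,
) -> list[TrialRecord]:
    """Simulate a session of the three-phase task as validated trial records.

    Coherences are drawn from the weighted design mixture.  On deadline
    trials (Phase II) a provisional deadline is drawn from the shifted
    Rayleigh; if the response would land after it, the trial is canceled with
    no choice and zero points.  Aborts (blinks, broken fixation) occur as an
    independent Bernoulli event; trials unterminated at the viewing limit are
    recorded as aborted as well.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    if n_trials == 0:
        return []
    cohs = np.asarray(task.coherences, dtype=float)
    idx = rng.choice(len(cohs), size=n_trials, p=np.asarray(task.weights, dtype=float))
    coh = cohs[idx]

    correct_sign = np.sign(coh).astype(int)
    zero = correct_sign == 0
    if zero.any():
        correct_sign[zero] = np.where(rng.random(int(zero.sum())) < 0.5, 1, -1)

    aborted_pre = rng.random(n_trials) < task.abort_rate
    has_deadline = rng.random(n_trials) < task.deadline_fraction
    deadline = np.full(n_trials, np.nan)
    if has_deadline.any():
        deadline[has_deadline] = sample_deadline(
            task.deadline, rng, size=int(has_deadline.sum())
        )

    sign, dec_t = simulate_decision_times(
        params.kappa * coh, bounds, rng, dt=dt, t_max=task.max_viewing_s
    )
    tnd = np.maximum(0.0, rng.normal(params.mu_nd, params.sigma_nd, size=n_trials)) \
        if params.sigma_nd > 0 else np.full(n_trials, params.mu_nd)
    rt = dec_t + tnd

    records: list[TrialRecord] = []
    for i in range(n_trials):
        hd = bool(has_deadline[i])
        dl = float(deadline[i]) if hd else None
        terminated = sign[i] != 0 and rt[i] <= task.max_viewing_s
        if aborted_pre[i]:
            outcome, choice, rt_i = "aborted", None, None
        elif hd and (not terminated or rt[i] > deadline[i]):
            outcome, choice, rt_i = "canceled", None, None
        elif not terminated:
            outcome, choice, rt_i = "aborted", None, None
        else:
            choice = "right" if sign[i] > 0 else "left"
            side = 1 if choice == "right" else -1
            outcome = "correct" if side == correct_sign[i] else "error"
            rt_i = float(rt[i])
        records.append(
            TrialRecord(
                participant=participant,
                phase=phase,
                session=session,
                trial_index=i + 1,
                coherence=float(coh[i]),
                correct_side="right" if correct_sign[i] > 0 else "left",
                has_deadline=hd,
                deadline_s=dl,
                choice=choice,
                rt_s=rt_i,
                outcome=outcome,
                points_delta={"correct": 1, "error": -1}.get(outcome, 0),
            )
        )
    return records


def earning_rate(records: Sequence[TrialRecord], task: TaskConfig) -> float:
    """Points per minute over a session.

    Elapsed time per trial: ``misc + rt + iti`` when completed,
    ``misc_cancel + deadline + iti`` when canceled, and the configured abort
    cost for aborted trials.
    """
    points = 0
    elapsed = 0.0
    for r in records:
        points += r.points_delta
        if r.completed:
            elapsed += task.misc_s + r.rt_s + task.iti_s
        elif r.outcome == "canceled":
            elapsed += task.misc_cancel_s + r.deadline_s + task.iti_s
        else:
            elapsed += task.abort_elapsed_s
    if elapsed <= 0:
        raise ValueError("cannot compute an earning rate over zero elapsed time")
    return points / (elapsed / 60.0)


def flat_bound_choice_probability(kappa: float, coh: float, b: float) -> float:
    """Closed-form P(upper) for a flat bound: ``1 / (1 + exp(-2 kappa coh b))``."""
    return 1.0 / (1.0 + math.exp(-2.0 * kappa * coh * b))


def flat_bound_mean_decision_time(kappa: float, coh: float, b: float) -> float:
    """Closed-form mean first-passage time between flat bounds ``+-b``.

    ``(b / mu) * tanh(mu * b)`` with ``mu = kappa * coh``; the drift-free
    limit is ``b ** 2``.
    """
    mu = kappa * coh
    if abs(mu) < 1e-12:
        return b * b
    return (b / mu) * math.tanh(mu * b)
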