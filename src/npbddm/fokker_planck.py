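"""Density propagation for drift-diffusion with time-varying absorbing bounds.

Per signed coherence, the decision-variable density ``u(x, t)`` obeys the
Fokker-Planck equation ``du/dt = d/dx(-mu * u) + D * d2u/dx2`` with drift
``mu = kappa * coh`` and diffusion ``D = 1/2`` (unit diffusion s.d.).  Each
time step advances the density with a fully implicit Chang-Cooper scheme
(flux form, exponentially fitted weights, positivity-preserving).  The
symmetric absorbing bounds ``+-B(t)`` are imposed *inside* the implicit
solve as Dirichlet conditions at the exact bound position: the cells
straddling the bounds couple to a zero-valued ghost point at fractional
spacing, so the scheme responds continuously to bound height and carries no
staircase artifacts.  Absorbed probability is tallied from the discrete
boundary fluxes, which makes the step exactly mass-conserving.

This module is the computational core shared by the nonparametric bound
inversion (npb_ddm) and by forward predictions of choice/RT distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solve_banded

DIFFUSION = 0.5  # D = sigma^2 / 2 with unit diffusion s.d.


class GridExtentError(ValueError):
    """A bound or state fell outside the spatial grid."""


@dataclass(frozen=True)
class FPState:
    """Per-coherence probability mass on the x-grid plus absorbed tallies.

    ``mass[i, j]`` is the probability (not density) in the cell centred on
    ``x_grid[j]`` for coherence ``i``.  For every coherence,
    ``mass.sum() + absorbed_upper + absorbed_lower == 1`` up to round-off.
    """

    x_grid: np.ndarray
    dx: float
    mass: np.ndarray            # (n_coh, n_x)
    absorbed_upper: np.ndarray  # (n_coh,)
    absorbed_lower: np.ndarray  # (n_coh,)
    t: float

    def total_mass(self) -> np.ndarray:
        return self.mass.sum(axis=1) + self.absorbed_upper + self.absorbed_lower

    def interior_mass(self) -> np.ndarray:
        return self.mass.sum(axis=1)


def _cc_delta(w: float) -> float:
    """Chang-Cooper exponential-fitting weight; -> 1/2 as w -> 0."""
    if abs(w) < 1e-10:
        return 0.5 - w / 12.0
    return 1.0 / w - 1.0 / math.expm1(w)


def _step_kernel_py(mass, new_mass, adv, dx, dt, j_lo, j_up, a_lo, a_up,
                    out_up, out_lo):
    """Pure-python/NumPy fallback for the bounded implicit step (see njit)."""
    n_coh = mass.shape[0]
    for i in range(n_coh):
        _step_one(mass[i], new_mass[i], adv[i], dx, dt, j_lo, j_up, a_lo,
                  a_up, out_up, out_lo, i)


def _step_one(m, m_new, a, dx, dt, j_lo, j_up, a_lo, a_up, out_up, out_lo, i):
    """One coherence: implicit solve on [j_lo, j_up] with ghost boundaries.

    Interior flux ``F_{j+1/2} = c_up m_{j+1} + c_dn m_j`` with
    ``c_up = a (1 - d) + D/dx``, ``c_dn = a d - D/dx`` (advection coefficient
    ``a = -mu``).  Boundary fluxes use the same form with spacing ``a_up`` /
    ``a_lo`` to a zero ghost, giving single-sided coefficients.
    """
    D = DIFFUSION
    d_in = _cc_delta(a * dx / D)
    c_up = a * (1.0 - d_in) + D / dx
    c_dn = a * d_in - D / dx
    d_b_up = _cc_delta(a * a_up / D)
    c_dn_b = a * d_b_up - D / a_up          # flux into the upper ghost
    d_b_lo = _cc_delta(a * a_lo / D)
    c_up_b = a * (1.0 - d_b_lo) + D / a_lo  # flux out of the lower ghost

    nb = j_up - j_lo + 1
    # Tridiagonal M = I - dt * L on the block; Thomas algorithm.
    sub = np.empty(nb)
    dia = np.empty(nb)
    sup = np.empty(nb)
    r = dt / dx
    sub[:] = r * c_dn
    sup[:] = -r * c_up
    dia[:] = 1.0 - r * (c_dn - c_up)
    if nb == 1:
        dia[0] = 1.0 - r * (c_dn_b - c_up_b)
    else:
        dia[0] = 1.0 - r * (c_dn - c_up_b)
        dia[nb - 1] = 1.0 - r * (c_dn_b - c_up)

    rhs = m[j_lo:j_up + 1].copy()
    # forward sweep
    for k in range(1, nb):
        w = sub[k] / dia[k - 1]
        dia[k] -= w * sup[k - 1]
        rhs[k] -= w * rhs[k - 1]
    sol = np.empty(nb)
    sol[nb - 1] = rhs[nb - 1] / dia[nb - 1]
    for k in range(nb - 2, -1, -1):
        sol[k] = (rhs[k] - sup[k] * sol[k + 1]) / dia[k]

    m_new[:] = 0.0
    m_new[j_lo:j_up + 1] = sol
    out_up[i] = -r * c_dn_b * sol[nb - 1]
    out_lo[i] = r * c_up_b * sol[0]


def _bounded_step_all(mass, new_mass, adv, dx, dt, x, bound, out_up, out_lo):
    """Full bounded step for all coherences; returns nothing, fills outputs.

    ``out_up`` / ``out_lo`` receive the total mass absorbed this step per
    coherence, including mass the (moving) bound had already overtaken.
    """
    n = x.size
    n_coh = mass.shape[0]
    if bound <= 0.0:
        c = n // 2
        for i in range(n_coh):
            up = 0.5 * mass[i, c]
            lo = 0.5 * mass[i, c]
            for j in range(c + 1, n):
                up += mass[i, j]
            for j in range(c):
                lo += mass[i, j]
            out_up[i] += up
            out_lo[i] += lo
            for j in range(n):
                new_mass[i, j] = 0.0
        return
    j_up = int(np.searchsorted(x, bound - 1e-15)) - 1
    j_lo = n - 1 - j_up
    a = bound - x[j_up]
    for i in range(n_coh):
        pre_up = 0.0
        for j in range(j_up + 1, n):
            pre_up += mass[i, j]
        pre_lo = 0.0
        for j in range(j_lo):
            pre_lo += mass[i, j]
        _step_one(mass[i], new_mass[i], adv[i], dx, dt, j_lo, j_up, a, a,
                  out_up, out_lo, i)
        out_up[i] += pre_up
        out_lo[i] += pre_lo


def _match_kernel_py(mass, new_mass, adv, dx, dt, x, priors, demand,
                     hint, out_up, out_lo):
    """Bisection on the bound height so absorbed mass equals ``demand``.

    Returns the matched bound, or -1.0 when even a zero bound cannot
    release the demanded mass (caller clamps and flags).  ``hint`` < 0
    means no warm bracket.  Outputs are left at the matched step.
    """
    x_max = x[-1]
    n_coh = mass.shape[0]

    def absorbed(b):
        for i in range(n_coh):
            out_up[i] = 0.0
            out_lo[i] = 0.0
        _bounded_step_all(mass, new_mass, adv, dx, dt, x, b, out_up, out_lo)
        tot = 0.0
        for i in range(n_coh):
            tot += priors[i] * (out_up[i] + out_lo[i])
        return tot

    # ceiling: no bound can absorb less than the widest one
    if absorbed(x_max) >= demand:
        return x_max
    lo = 0.0
    hi = x_max
    if hint > 0.0 and hint < x_max:
        half = 4.0 * dx if 4.0 * dx > 0.05 * hint else 0.05 * hint
        lo_h = hint - half
        if lo_h < 0.0:
            lo_h = 0.0
        hi_h = hint + half
        if hi_h > x_max:
            hi_h = x_max
        while True:
            ok_lo = lo_h <= 0.0 or absorbed(lo_h) >= demand
            ok_hi = hi_h >= x_max or absorbed(hi_h) <= demand
            if ok_lo and ok_hi:
                lo = lo_h
                hi = hi_h
                break
            half *= 2.0
            if not ok_lo:
                lo_h = lo_h - half
                if lo_h < 0.0:
                    lo_h = 0.0
            if not ok_hi:
                hi_h = hi_h + half
                if hi_h > x_max:
                    hi_h = x_max
    if lo <= 0.0 and absorbed(0.0) < demand:
        absorbed(0.0)  # leave outputs at the clamped step
        return -1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if absorbed(mid) > demand:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-7:
            break
    b = 0.5 * (lo + hi)
    absorbed(b)
    return b


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _cc_delta = njit(cache=True)(_cc_delta)
    _step_one = njit(cache=True)(_step_one)
    _step_kernel = njit(cache=True)(_step_kernel_py)
    _bounded_step_all = njit(cache=True)(_bounded_step_all)
    _match_kernel = njit(cache=True)(_match_kernel_py)
except Exception:  # numba unavailable: fall back to the python loops
    _step_kernel = _step_kernel_py
    _match_kernel = _match_kernel_py


class FokkerPlanckPropagator:
    """Propagates per-coherence densities with a fixed (dx, dt) grid.

    Parameters
    ----------
    drifts : array-like
        Per-coherence drift rates ``kappa * coh`` (signed).
    dx : float
        Grid spacing in evidence units.
    dt : float
        Time step in seconds.
    x_max : float
        Half-extent of the symmetric grid; every applied bound must satisfy
        ``B <= x_max``.
    """

    def __init__(self, drifts, dx: float = 0.01, dt: float = 0.0005,
                 x_max: float = 3.0):
        self.drifts = np.atleast_1d(np.asarray(drifts, dtype=float))
        if dx <= 0 or dt <= 0 or x_max <= 0:
            raise ValueError("dx, dt and x_max must be positive")
        self.dx = float(dx)
        self.dt = float(dt)
        n_half = int(np.ceil(x_max / dx - 1e-9))
        self.x_grid = np.arange(-n_half, n_half + 1) * dx
        self.x_max = float(self.x_grid[-1])
        self._adv = -self.drifts  # advection coefficient a = -mu

    @property
    def n_coherences(self) -> int:
        return self.drifts.size

    def initial_state(self) -> FPState:
        """All mass on the node nearest x = 0 (delta start)."""
        n = self.x_grid.size
        mass = np.zeros((self.n_coherences, n))
        mass[:, n // 2] = 1.0
        zeros = np.zeros(self.n_coherences)
        return FPState(self.x_grid, self.dx, mass, zeros.copy(), zeros.copy(), 0.0)

    # -- unbounded step (zero-flux grid ends), used for free-diffusion checks
    def advance_free(self, state: FPState) -> FPState:
        """One implicit step with reflecting grid ends and no absorption."""
        n = self.x_grid.size
        new_mass = np.empty_like(state.mass)
        for i, a in enumerate(self._adv):
            d_in = _cc_delta(a * self.dx / DIFFUSION)
            c_up = a * (1.0 - d_in) + DIFFUSION / self.dx
            c_dn = a * d_in - DIFFUSION / self.dx
            r = self.dt / self.dx
            ab = np.zeros((3, n))
            ab[0, 1:] = -r * c_up
            ab[1, :] = 1.0 - r * (c_dn - c_up)
            ab[1, 0] = 1.0 - r * c_dn
            ab[1, -1] = 1.0 + r * c_up
            ab[2, :-1] = r * c_dn
            new_mass[i] = solve_banded((1, 1), ab, state.mass[i])
        return replace(state, mass=new_mass, t=state.t + self.dt)

    def _block(self, bound: float) -> tuple[int, int, float, float]:
        """Interior block indices and ghost spacings for bounds ``+-bound``."""
        x, dx = self.x_grid, self.dx
        if bound > self.x_max + 1e-12:
            raise GridExtentError(
                f"bound {bound:.4f} exceeds grid extent {self.x_max:.4f}")
        j_up = int(np.searchsorted(x, bound - 1e-15, side="left")) - 1
        j_lo = x.size - 1 - j_up
        a_up = bound - x[j_up]
        return j_lo, j_up, a_up, a_up

    def propagate_step(self, state: FPState, bound_now: float) -> FPState:
        """Advance one implicit step with absorbing bounds ``+-bound_now``.

        Mass strictly outside the bounds before the step (possible when the
        bound moved inward) is absorbed directly, split by side of origin;
        the centre cell splits evenly when the bound reaches zero.
        """
        if bound_now < 0:
            raise ValueError("bound must be non-negative")
        x = self.x_grid
        t_new = state.t + self.dt
        if bound_now <= 0.0:
            # Degenerate bound: everything exits, split by side of origin.
            up = state.mass @ (x > 0) + 0.5 * state.mass[:, x.size // 2]
            lo = state.interior_mass() - up
            return replace(
                state,
                mass=np.zeros_like(state.mass),
                absorbed_upper=state.absorbed_upper + up,
                absorbed_lower=state.absorbed_lower + lo,
                t=t_new,
            )
        self._block(bound_now)  # validates the grid extent
        new_mass = np.empty_like(state.mass)
        out_up = np.zeros(self.n_coherences)
        out_lo = np.zeros(self.n_coherences)
        _bounded_step_all(state.mass, new_mass, self._adv, self.dx, self.dt,
                          self.x_grid, float(bound_now), out_up, out_lo)
        return FPState(
            x_grid=state.x_grid,
            dx=state.dx,
            mass=new_mass,
            absorbed_upper=state.absorbed_upper + out_up,
            absorbed_lower=state.absorbed_lower + out_lo,
            t=t_new,
        )

    def step_matching_demand(
        self,
        state: FPState,
        priors,
        demand: float,
        bracket_hint: float | None = None,
    ) -> tuple[FPState, float | None]:
        """One step whose prior-weighted absorption equals ``demand``.

        The absorbed mass is monotone non-increasing in the bound height, so
        the height is located by bisection on ``absorbed(B) - demand`` over
        ``[0, x_max]``, starting from a narrow expanding bracket around
        ``bracket_hint`` when given.  Returns the advanced state and the
        matched bound, or ``(state at B=0, None)`` when even a fully
        collapsed bound cannot release the demanded mass.
        """
        priors = np.asarray(priors, dtype=float)
        new_mass = np.empty_like(state.mass)
        out_up = np.zeros(self.n_coherences)
        out_lo = np.zeros(self.n_coherences)
        hint = -1.0 if bracket_hint is None else float(bracket_hint)
        b = _match_kernel(state.mass, new_mass, self._adv, self.dx, self.dt,
                          self.x_grid, priors, float(demand), hint,
                          out_up, out_lo)
        new_state = FPState(
            x_grid=state.x_grid,
            dx=state.dx,
            mass=new_mass,
            absorbed_upper=state.absorbed_upper + out_up,
            absorbed_lower=state.absorbed_lower + out_lo,
            t=state.t + self.dt,
        )
        return new_state, (None if b < 0 else float(b))


def marginal_density(state: FPState, priors) -> np.ndarray:
    """Coherence-marginal density over x: ``p(x,t) = sum_i p(x,t|coh_i) p(coh_i)``."""
    priors = np.asarray(priors, dtype=float)
    if priors.shape[0] != state.mass.shape[0]:
        raise ValueError("one prior weight per coherence is required")
    if not np.isclose(priors.sum(), 1.0, atol=1e-8):
        raise ValueError("priors must sum to 1")
    return (priors @ state.mass) / state.dx


def exit_probability(state_before: FPState, state_after: FPState, priors) -> float:
    """Prior-weighted mass absorbed between two consecutive states."""
    priors = np.asarray(priors, dtype=float)
    before = state_before.absorbed_upper + state_before.absorbed_lower
    after = state_after.absorbed_upper + state_after.absorbed_lower
    return float(priors @ (after - before))


def first_passage_densities(
    drifts,
    bounds,
    dx: float = 0.01,
    dt: float | None = None,
    t_max: float | None = None,
    x_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-coherence upper/lower first-passage mass per step under ``bounds``.

    Returns ``(times, exit_upper, exit_lower)`` where ``times[k]`` is the
    midpoint of step k and ``exit_*[i, k]`` the probability absorbed at that
    step for coherence i.  Steps run to ``t_max`` (default: bound support).
    """
    dt = bounds.dt if dt is None else dt
    t_max = bounds.t_max if t_max is None else t_max
    b_max = float(np.max(bounds.values))
    if x_max is None:
        x_max = b_max + 0.5
    fp = FokkerPlanckPropagator(drifts, dx=dx, dt=dt, x_max=max(x_max, b_max + 2 * dx))
    state = fp.initial_state()
    n_steps = int(round(t_max / dt))
    n_coh = fp.n_coherences
    exit_up = np.zeros((n_coh, n_steps))
    exit_lo = np.zeros((n_coh, n_steps))
    times = (np.arange(n_steps) + 0.5) * dt
    for k in range(n_steps):
        t_new = (k + 1) * dt
        prev_up, prev_lo = state.absorbed_upper, state.absorbed_lower
        state = fp.propagate_step(state, float(bounds(t_new)))
        exit_up[:, k] = state.absorbed_upper - prev_up
        exit_lo[:, k] = state.absorbed_lower - prev_lo
        if state.interior_mass().max() < 1e-10:
            break
    return times, exit_up, exit_lo
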