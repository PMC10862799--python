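"""Nonparametric-bound drift-diffusion model (npb-DDM).

The shape of the time-varying decision bounds is not a free parametric form:
it is derived from the data.  Given the drift sensitivity ``kappa`` and the
mean non-decision time ``mu_nd``, the empirical decision-time distribution
(reaction times shifted by ``mu_nd``, smoothed with an Epanechnikov kernel)
uniquely pins down the symmetric bound ``B(t)``: at every time step the
bound is placed where the probability mass absorbed by the propagated
decision-variable density, aggregated over motion coherences, equals the
probability that a decision terminated at that moment.  Only three scalars
(kappa, mu_nd, sigma_nd) remain free and are fitted by maximum likelihood
over single-trial choices and reaction times; the bounds are re-derived from
the data inside every likelihood evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .bounds import BoundCurve
from .ddm_sim import DDMParams
from .fokker_planck import FokkerPlanckPropagator, first_passage_densities
from .trial_data import COHERENCES, TrialRecord, records_to_frame

LIKELIHOOD_FLOOR = 1e-10


@dataclass(frozen=True)
class DecisionTimeDensity:
    """Kernel-smoothed decision-time density on a uniform grid.

    ``density[k]`` is the value at the step midpoint ``(k + 1/2) * dt``;
    the support is truncated to ``t > 0`` and renormalized.
    """

    dt: float
    density: np.ndarray = field(repr=False)
    n_trials: int = 0

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.density.size) + 0.5) * self.dt

    def integral(self) -> float:
        return float(self.density.sum() * self.dt)


@dataclass(frozen=True)
class JointPredictive:
    """Predicted joint density of RT and choice per signed coherence.

    ``upper[i, k]`` / ``lower[i, k]`` are RT densities (per second) at the
    grid midpoint ``times[k]`` for a right / left choice given coherence
    ``coherences[i]``.  Densities integrate (over RT and both choices) to at
    most 1 per coherence; the deficit is mass not yet absorbed at ``t_max``.
    """

    dt: float
    coherences: np.ndarray
    upper: np.ndarray = field(repr=False)
    lower: np.ndarray = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.upper.shape[1]) + 0.5) * self.dt

    def choice_probability(self, coh: float, choice: str = "right") -> float:
        i = _coherence_index(self.coherences, coh)
        dens = self.upper if choice == "right" else self.lower
        return float(dens[i].sum() * self.dt)

    def rt_density(self, coh: float, choice: str, rts) -> np.ndarray:
        """Interpolated joint density values at the given reaction times."""
        i = _coherence_index(self.coherences, coh)
        dens = self.upper if choice == "right" else self.lower
        return np.interp(np.asarray(rts, dtype=float), self.times, dens[i],
                         left=0.0, right=0.0)


def _coherence_index(coherences: np.ndarray, coh: float) -> int:
    i = int(np.argmin(np.abs(coherences - coh)))
    if not math.isclose(coherences[i], coh, abs_tol=1e-9):
        raise ValueError(f"coherence {coh} not in the model's coherence set")
    return i


def epanechnikov_kernel(u: np.ndarray, half_width: float) -> np.ndarray:
    """Inverted-parabola kernel with support ``|u| <= half_width``.

    The kernel's standard deviation is ``half_width / sqrt(5)``.
    """
    z = np.asarray(u, dtype=float) / half_width
    out = 0.75 * (1.0 - z * z) / half_width
    return np.where(np.abs(z) <= 1.0, out, 0.0)


def estimate_decision_time_density(
    rts,
    mu_nd: float,
    bandwidth_sd: float = 0.1,
    dt: float = 0.0005,
    t_max: float = 5.0,
    deconvolve: int = 0,
) -> DecisionTimeDensity:
    """Epanechnikov KDE of decision times ``Td_i = RT_i - mu_nd``.

    ``bandwidth_sd`` is the kernel's standard deviation in seconds (the
    half-width is ``bandwidth_sd * sqrt(5)``).  Mass falling at ``t <= 0``
    after the shift is discarded and the density renormalized.

    First-passage densities have a sharp onset that a 0.1-s kernel smears
    substantially; because the smoothing kernel is known exactly,
    ``deconvolve > 0`` applies that many Van Cittert iterations (with
    positivity clipping and truncation below the smallest observed decision
    time) to undo most of that bias.  Deconvolution sharpens the *shape* of
    bounds recovered at known parameters but perturbs the likelihood
    ranking across candidate non-decision times, so parameter fitting uses
    the plain KDE (the default).
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("no reaction times given")
    if mu_nd < 0:
        raise ValueError("mu_nd must be non-negative")
    td = rts - mu_nd
    h = bandwidth_sd * math.sqrt(5.0)
    if np.max(td) + h <= 0:
        raise ValueError("all decision times are non-positive after the shift")
    n_steps = int(round(t_max / dt))
    grid = (np.arange(n_steps) + 0.5) * dt
    dens = np.zeros(n_steps)
    # each kernel touches ~2h/dt nodes; accumulate per trial on its window
    for t_i in td:
        lo = max(0, int(np.floor((t_i - h) / dt - 0.5)) + 1)
        hi = min(n_steps, int(np.ceil((t_i + h) / dt - 0.5)) + 1)
        if hi > lo:
            dens[lo:hi] += epanechnikov_kernel(grid[lo:hi] - t_i, h)
    dens /= rts.size
    total = dens.sum() * dt
    if total <= 0:
        raise ValueError("decision-time density has no mass on t > 0")
    dens = dens / total
    if deconvolve > 0:
        m = int(round(h / dt))
        if m >= 1:
            kernel = epanechnikov_kernel(np.arange(-m, m + 1) * dt, h)
            kernel /= kernel.sum()
            t_min = float(np.min(td))
            g = dens.copy()
            for _ in range(int(deconvolve)):
                g = np.clip(g + (dens - np.convolve(g, kernel, mode="same")),
                            0.0, None)
                g[grid < t_min] = 0.0
            total = g.sum() * dt
            if total > 0:
                dens = g / total
    return DecisionTimeDensity(dt=dt, density=dens, n_trials=rts.size)


def derive_bounds(
    density: DecisionTimeDensity,
    params: DDMParams,
    priors,
    coherences=COHERENCES,
    dx: float = 0.01,
    x_max: float = 3.0,
    mass_tol: float = 1e-4,
) -> BoundCurve:
    """Invert a decision-time density into the symmetric bound ``B(t)``.

    Alternates one Fokker-Planck propagation step with a *match* step that
    root-finds the bound height whose absorbed mass (aggregated over
    coherences with the given priors) equals ``density * dt`` at that step.
    Iteration stops once cumulative absorbed mass reaches ``1 - mass_tol``
    or the density grid is exhausted.  If the demanded exit mass ever
    exceeds what remains unabsorbed, the bound is clamped to zero from that
    step onward (with a warning).
    """
    priors = np.asarray(priors, dtype=float)
    if not np.isclose(priors.sum(), 1.0, atol=1e-6):
        raise ValueError("priors must sum to 1")
    drifts = params.kappa * np.asarray(coherences, dtype=float)
    fp = FokkerPlanckPropagator(drifts, dx=dx, dt=density.dt, x_max=x_max)
    state = fp.initial_state()
    values = [fp.x_max]
    absorbed = 0.0
    hint: float | None = None
    for k in range(density.density.size):
        demand = float(density.density[k] * density.dt)
        state, b = fp.step_matching_demand(state, priors, demand, bracket_hint=hint)
        if b is None:
            warnings.warn(
                "demanded exit mass exceeds remaining interior mass; "
                f"bound clamped to 0 from t = {state.t:.3f} s",
                stacklevel=2,
            )
            values.append(0.0)
            break
        values.append(b)
        hint = b if b < fp.x_max else None
        absorbed = float(priors @ (state.absorbed_upper + state.absorbed_lower))
        if absorbed >= 1.0 - mass_tol:
            break
    values[0] = values[1] if len(values) > 1 else fp.x_max
    return BoundCurve(dt=density.dt, values=np.asarray(values))


def _tnd_kernel(mu_nd: float, sigma_nd: float, dt: float) -> np.ndarray:
    """Discretized non-decision-time distribution on the step grid.

    Gaussian ``N(mu_nd, sigma_nd^2)`` censored at zero (negative draws are
    clamped to 0); ``sigma_nd = 0`` degenerates to a pure shift.
    """
    if sigma_nd <= 0:
        w = np.zeros(int(round(mu_nd / dt)) + 1)
        w[-1] = 1.0
        return w
    n = int(math.ceil((mu_nd + 6 * sigma_nd) / dt)) + 1
    edges = np.arange(n + 1) * dt
    cdf = norm.cdf(edges, loc=mu_nd, scale=sigma_nd)
    w = np.diff(cdf)
    w[0] += cdf[0]  # censored negative mass sits at zero delay
    s = w.sum()
    return w / s if s > 0 else w


def predict_joint(
    params: DDMParams,
    bounds: BoundCurve,
    priors=None,
    coherences=COHERENCES,
    dx: float = 0.01,
    t_max: float = 5.0,
) -> JointPredictive:
    """Joint RT/choice density per coherence under given bounds and theta.

    First-passage densities from the Fokker-Planck propagation are convolved
    with the (censored) Gaussian non-decision-time distribution.
    """
    coherences = np.asarray(coherences, dtype=float)
    drifts = params.kappa * coherences
    _, exit_up, exit_lo = first_passage_densities(
        drifts, bounds, dx=dx, t_max=t_max,
        x_max=float(np.max(bounds.values)) + 0.5,
    )
    dt = bounds.dt
    w = _tnd_kernel(params.mu_nd, params.sigma_nd, dt)
    n_rt = exit_up.shape[1] + w.size - 1
    upper = np.empty((coherences.size, n_rt))
    lower = np.empty((coherences.size, n_rt))
    for i in range(coherences.size):
        upper[i] = np.convolve(exit_up[i], w) / dt
        lower[i] = np.convolve(exit_lo[i], w) / dt
    return JointPredictive(dt=dt, coherences=coherences, upper=upper, lower=lower)


def log_likelihood(
    jp: JointPredictive,
    cohs,
    choices,
    rts,
    floor: float = LIKELIHOOD_FLOOR,
) -> float:
    """Sum of per-trial log joint densities with a numerical floor."""
    cohs = np.asarray(cohs, dtype=float)
    rts = np.asarray(rts, dtype=float)
    choices = np.asarray(choices)
    total = 0.0
    for coh in np.unique(cohs):
        i = _coherence_index(jp.coherences, coh)
        for side, dens in (("right", jp.upper[i]), ("left", jp.lower[i])):
            sel = (cohs == coh) & (choices == side)
            if not sel.any():
                continue
            vals = np.interp(rts[sel], jp.times, dens, left=0.0, right=0.0)
            total += float(np.log(np.maximum(vals, floor)).sum())
    return total


def _extract_trials(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed coherences, choices and RTs from records or a trial table."""
    if len(X) and isinstance(next(iter(X)), TrialRecord):
        X = records_to_frame(X)
    cohs = np.asarray(X["coherence"], dtype=float)
    choices = np.asarray(X["choice"], dtype=object)
    rts = np.asarray(X["rt_s"], dtype=float)
    ok = np.isin(choices, ("left", "right")) & np.isfinite(rts)
    if not ok.all():
        raise ValueError(
            "fit requires completed trials with a choice and an RT; "
            "use trial_data.filter_standard_trials first"
        )
    return cohs, choices.astype(str), rts


class NonparametricBoundDDM(BaseEstimator):
    """Maximum-likelihood npb-DDM fit of choice/RT data.

    Parameters
    ----------
    dt, dx : float
        Time step (s) and evidence-grid spacing of the Fokker-Planck
        propagation used inside every likelihood evaluation.
    x_max : float
        Bound ceiling / half-extent of the evidence grid.
    bandwidth_sd : float
        Standard deviation (s) of the Epanechnikov kernel smoothing the
        decision-time distribution.
    coherences : sequence
        Signed coherence set of the task.
    priors : "empirical" or array
        Coherence weights used in propagation and match; ``"empirical"``
        uses the fitted dataset's per-coherence trial frequencies.
    kappa0, mu_nd0, sigma_nd0 : float
        Optimizer starting point.
    n_restarts : int
        Additional Nelder-Mead starts from jittered initial points.
    max_iter : int
        Nelder-Mead iteration budget per start.
    sigma_nd_min : float
        Lower floor (s) on the non-decision-time spread.
    random_state : int or Generator, optional
        Seeds the start-point jitter.

    Attributes
    ----------
    kappa_, mu_nd_, sigma_nd_ : fitted parameters.
    params_ : DDMParams
    bounds_ : BoundCurve derived from the data at the fitted parameters.
    log_likelihood_ : float
    priors_ : coherence weights actually used.
    converged_ : bool
    """

    def __init__(
        self,
        dt: float = 0.0005,
        dx: float = 0.01,
        x_max: float = 3.0,
        bandwidth_sd: float = 0.1,
        t_max: float = 5.0,
        coherences=COHERENCES,
        priors="empirical",
        kappa0: float = 15.0,
        mu_nd0: float = 0.3,
        sigma_nd0: float = 0.05,
        n_restarts: int = 3,
        max_iter: int = 100,
        sigma_nd_min: float = 0.001,
        random_state=None,
    ):
        self.dt = dt
        self.dx = dx
        self.x_max = x_max
        self.bandwidth_sd = bandwidth_sd
        self.t_max = t_max
        self.coherences = coherences
        self.priors = priors
        self.kappa0 = kappa0
        self.mu_nd0 = mu_nd0
        self.sigma_nd0 = sigma_nd0
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.sigma_nd_min = sigma_nd_min
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _empirical_priors(self, cohs: np.ndarray) -> np.ndarray:
        coherences = np.asarray(self.coherences, dtype=float)
        counts = np.array([(cohs == c).sum() for c in coherences], dtype=float)
        return counts / counts.sum()

    def _evaluate(self, theta: DDMParams, cohs, choices, rts, priors) -> tuple:
        density = estimate_decision_time_density(
            rts, theta.mu_nd, bandwidth_sd=self.bandwidth_sd,
            dt=self.dt, t_max=self.t_max,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bounds = derive_bounds(
                density, theta, priors, coherences=self.coherences,
                dx=self.dx, x_max=self.x_max,
            )
        jp = predict_joint(theta, bounds, coherences=self.coherences,
                           dx=self.dx, t_max=self.t_max)
        return log_likelihood(jp, cohs, choices, rts), bounds, jp

    def _theta_from_vec(self, z: np.ndarray) -> DDMParams | None:
        kappa = math.exp(z[0])
        mu_nd = z[1]
        sigma_nd = max(self.sigma_nd_min, math.exp(z[2]))
        if not (0.5 <= kappa <= 200.0 and 0.01 <= mu_nd <= 1.5
                and sigma_nd <= 0.5):
            return None
        return DDMParams(kappa=kappa, mu_nd=mu_nd, sigma_nd=sigma_nd)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None):
        cohs, choices, rts = _extract_trials(X)
        if isinstance(self.priors, str) and self.priors == "empirical":
            priors = self._empirical_priors(cohs)
        else:
            priors = np.asarray(self.priors, dtype=float)
        rng = np.random.default_rng(self.random_state)

        def objective(z: np.ndarray) -> float:
            theta = self._theta_from_vec(z)
            if theta is None:
                return 1e12
            try:
                ll, _, _ = self._evaluate(theta, cohs, choices, rts, priors)
            except (ValueError, FloatingPointError):
                return 1e12
            return -ll

        z0 = np.array([
            math.log(self.kappa0),
            self.mu_nd0,
            math.log(max(self.sigma_nd0, self.sigma_nd_min)),
        ])
        starts = [z0]
        for _ in range(self.n_restarts):
            starts.append(z0 + rng.normal(0.0, [0.15, 0.03, 0.3]))
        best = None
        converged = False
        for z_start in starts:
            res = minimize(
                objective, z_start, method="Nelder-Mead",
                options={"maxiter": self.max_iter, "xatol": 1e-3,
                         "fatol": 1e-2, "adaptive": True},
            )
            if best is None or res.fun < best.fun:
                best = res
                converged = bool(res.success)
        if not converged:
            warnings.warn("npb-DDM optimizer did not fully converge; "
                          "reporting best parameters found", stacklevel=2)
        theta = self._theta_from_vec(best.x)
        ll, bounds, jp = self._evaluate(theta, cohs, choices, rts, priors)
        self.kappa_ = theta.kappa
        self.mu_nd_ = theta.mu_nd
        self.sigma_nd_ = theta.sigma_nd
        self.params_ = theta
        self.bounds_ = bounds
        self.priors_ = priors
        self.log_likelihood_ = ll
        self.predictive_ = jp
        self.converged_ = converged
        self.n_trials_ = rts.size
        return self

    def predict_joint(self) -> JointPredictive:
        """Joint RT/choice predictive at the fitted parameters."""
        self._check_fitted()
        return self.predictive_

    def score(self, X, y=None) -> float:
        """Mean per-trial log likelihood of ``X`` under the fitted model."""
        self._check_fitted()
        cohs, choices, rts = _extract_trials(X)
        return log_likelihood(self.predictive_, cohs, choices, rts) / rts.size

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise AttributeError("this NonparametricBoundDDM is not fitted yet")


def fit(records, priors="empirical", **estimator_kwargs):
    """Convenience wrapper: fit the npb-DDM and return (params, bounds, logL)."""
    est = NonparametricBoundDDM(priors=priors, **estimator_kwargs)
    est.fit(records)
    return est.params_, est.bounds_, est.log_likelihood_
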