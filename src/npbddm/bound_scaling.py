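"""Shape-preserving bound scaling and the cross-fitting permutation test.

Tests whether a participant's bound *shape* is an individual trait: bounds
derived from one phase (or participant) are allowed to change only by a
linear stretch in time and magnitude, ``B'(t) = s_m * B(t / s_t)``, and the
two scale factors are fitted by maximum likelihood to another dataset with
the diffusion parameters held fixed.  The fit quality relative to the full
nonparametric fit (log-likelihood difference per trial) populates a
cross-fitting matrix whose diagonal ranks feed an exact permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .bounds import BoundCurve
from .ddm_sim import DDMParams
from .npb_ddm import _extract_trials, log_likelihood, predict_joint
from .trial_data import COHERENCES


@dataclass(frozen=True)
class ScalingFit:
    """Fitted time/magnitude scale factors and their fit quality."""

    s_t: float
    s_m: float
    log_likelihood: float
    delta_log_likelihood_per_trial: float | None
    n_trials: int


def scale_bounds(base: BoundCurve, s_t: float, s_m: float) -> BoundCurve:
    """``B'(t) = s_m * B(t / s_t)`` (see :meth:`BoundCurve.scaled`)."""
    return base.scaled(s_t, s_m)


class ScaledBoundDDM(BaseEstimator):
    """Two-parameter scaled-bound fit with fixed diffusion parameters.

    Parameters
    ----------
    theta : DDMParams
        Drift sensitivity and non-decision time, held fixed (typically the
        npb-DDM fit to the target dataset).
    base_bounds : BoundCurve
        The bound shape to be scaled (typically derived from another phase
        or participant).
    reference_log_likelihood : float, optional
        Log likelihood of the full npb-DDM fit on the same trials; enables
        the per-trial ``delta_log_likelihood_per_trial_``.
    grid : sequence of float
        Initial grid over both scale factors; the best grid point seeds a
        Nelder-Mead refinement in log-scale coordinates.

    Attributes
    ----------
    s_t_, s_m_ : fitted scale factors.
    log_likelihood_ : maximized log likelihood.
    delta_log_likelihood_per_trial_ : (logP_scaled - logP_npb) / n, or None.
    scaled_bounds_ : the best-fitting scaled curve.
    """

    def __init__(
        self,
        theta: DDMParams,
        base_bounds: BoundCurve,
        reference_log_likelihood: float | None = None,
        coherences=COHERENCES,
        dx: float = 0.01,
        t_max: float = 5.0,
        grid=(0.5, 0.75, 1.0, 1.25, 1.5),
        max_iter: int = 60,
    ):
        self.theta = theta
        self.base_bounds = base_bounds
        self.reference_log_likelihood = reference_log_likelihood
        self.coherences = coherences
        self.dx = dx
        self.t_max = t_max
        self.grid = grid
        self.max_iter = max_iter

    def _loglik(self, s_t: float, s_m: float, cohs, choices, rts) -> float:
        scaled = self.base_bounds.scaled(s_t, s_m)
        jp = predict_joint(self.theta, scaled, coherences=self.coherences,
                           dx=self.dx, t_max=self.t_max)
        return log_likelihood(jp, cohs, choices, rts)

    def fit(self, X, y=None):
        cohs, choices, rts = _extract_trials(X)
        evals: dict[tuple[float, float], float] = {}

        def objective(z) -> float:
            s_t, s_m = math.exp(z[0]), math.exp(z[1])
            if not (0.05 <= s_t <= 20.0 and 0.05 <= s_m <= 20.0):
                return 1e12
            key = (round(s_t, 10), round(s_m, 10))
            if key not in evals:
                evals[key] = self._loglik(s_t, s_m, cohs, choices, rts)
            return -evals[key]

        best_z, best_f = None, np.inf
        for s_t, s_m in itertools.product(self.grid, self.grid):
            z = np.array([math.log(s_t), math.log(s_m)])
            f = objective(z)
            if f < best_f:
                best_z, best_f = z, f
        res = minimize(objective, best_z, method="Nelder-Mead",
                       options={"maxiter": self.max_iter, "xatol": 1e-4,
                                "fatol": 1e-4})
        if res.fun > best_f:  # optimizer failure: fall back to the grid
            warnings.warn("scaled-bound optimizer did not improve on the "
                          "grid search; reporting the grid optimum",
                          stacklevel=2)
            z_best, f_best = best_z, best_f
        else:
            z_best, f_best = res.x, res.fun
        self.s_t_ = math.exp(z_best[0])
        self.s_m_ = math.exp(z_best[1])
        self.log_likelihood_ = -f_best
        self.scaled_bounds_ = self.base_bounds.scaled(self.s_t_, self.s_m_)
        self.n_trials_ = rts.size
        if self.reference_log_likelihood is not None:
            self.delta_log_likelihood_per_trial_ = (
                self.log_likelihood_ - self.reference_log_likelihood
            ) / rts.size
        else:
            self.delta_log_likelihood_per_trial_ = None
        return self

    def result_(self) -> ScalingFit:
        return ScalingFit(
            s_t=self.s_t_,
            s_m=self.s_m_,
            log_likelihood=self.log_likelihood_,
            delta_log_likelihood_per_trial=self.delta_log_likelihood_per_trial_,
            n_trials=self.n_trials_,
        )


def fit_scaling(
    records,
    theta: DDMParams,
    base_bounds: BoundCurve,
    reference_log_likelihood: float | None = None,
    **kwargs,
) -> ScalingFit:
    """Fit ``(s_t, s_m)`` by maximum likelihood; thin estimator wrapper."""
    est = ScaledBoundDDM(theta, base_bounds,
                         reference_log_likelihood=reference_log_likelihood,
                         **kwargs)
    est.fit(records)
    return est.result_()


def rank_matrix(delta_loglik: np.ndarray) -> np.ndarray:
    """Within-row ranks of a cross-fitting quality matrix (1 = best).

    Rows index the fitted dataset, columns the origin of the scaled
    bounds; larger values indicate better fits.  Exact ties are an error
    (they are measure-zero for continuous likelihoods).
    """
    m = np.asarray(delta_loglik, dtype=float)
    ranks = np.empty_like(m, dtype=int)
    for i, row in enumerate(m):
        if np.unique(row).size != row.size:
            raise ValueError(f"tied fit qualities in row {i}")
        order = np.argsort(-row)
        ranks[i, order] = np.arange(1, row.size + 1)
    return ranks


def permutation_rank_pvalue(rank_diagonal) -> float:
    """Exact p-value for the diagonal rank sum of the cross-fitting matrix.

    Under the null every diagonal cell's rank is uniform on ``1..n``
    independently, giving ``n ** n`` equally likely patterns; the p-value
    is the fraction whose rank sum does not exceed the observed sum.
    """
    ranks = list(rank_diagonal)
    n = len(ranks)
    if n == 0:
        raise ValueError("empty rank diagonal")
    if any((not float(r).is_integer()) or not 1 <= int(r) <= n for r in ranks):
        raise ValueError(f"ranks must be integers in 1..{n}, got {ranks}")
    observed = sum(int(r) for r in ranks)
    count = sum(
        1 for pattern in itertools.product(range(1, n + 1), repeat=n)
        if sum(pattern) <= observed
    )
    return count / n ** n
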