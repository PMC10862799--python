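"""Symmetric time-varying decision bounds on a uniform time grid.

A bound curve ``B(t)`` gives the magnitude of the two absorbing thresholds
``+B(t)`` (right choice) and ``-B(t)`` (left choice) acting on the decision
variable.  Values between grid nodes are obtained by linear interpolation;
beyond the last node the final value is held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BoundCurve:
    """Symmetric decision bound ``B(t) >= 0`` sampled at ``t = 0, dt, 2*dt, ...``

    Parameters
    ----------
    dt : float
        Grid step in seconds.
    values : ndarray
        Bound heights at the grid nodes; all non-negative.
    """

    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(vals < 0):
            raise ValueError("bound values must be non-negative")
        object.__setattr__(self, "values", vals)

    @property
    def t_max(self) -> float:
        return (len(self.values) - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate ``B(t)`` with linear interpolation, holding the last value."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values)
        return float(out) if out.ndim == 0 else out

    def scaled(self, s_t: float, s_m: float) -> "BoundCurve":
        """Return ``B'(t) = s_m * B(t / s_t)`` on the same time grid.

        Time stretching by ``s_t > 1`` slows the collapse; magnitude scaling by
        ``s_m`` raises or lowers the whole curve.  Evaluation beyond the
        support of the base curve holds the base curve's final value.
        """
        if s_t <= 0 or s_m <= 0:
            raise ValueError("scale factors must be positive")
        new_vals = s_m * self(self.times / s_t)
        return BoundCurve(dt=self.dt, values=np.asarray(new_vals, dtype=float))

    @classmethod
    def flat(cls, height: float, t_max: float, dt: float = 0.0005) -> "BoundCurve":
        n = int(round(t_max / dt)) + 1
        return cls(dt=dt, values=np.full(n, float(height)))

    @classmethod
    def linear_collapse(
        cls, b0: float, slope: float, t_max: float, dt: float = 0.0005
    ) -> "BoundCurve":
        """``B(t) = max(0, b0 - slope * t)``."""
        t = np.arange(int(round(t_max / dt)) + 1) * dt
        return cls(dt=dt, values=np.maximum(0.0, b0 - slope * t))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.times, "bound": self.values})
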