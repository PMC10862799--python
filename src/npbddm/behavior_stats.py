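"""Descriptive and inferential analyses of trial tables.

Covers the phase comparisons of the task: RT differences between phases by
linear regression with motion-strength indicators, accuracy differences by
intercept-free logistic regression with a likelihood-ratio test,
time-dependent accuracy in sliding RT windows, and reaction-time dynamics
aligned to trial cancellations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .trial_data import records_to_frame


@dataclass(frozen=True)
class RegressionResult:
    """Coefficients, their standard errors and the phase-term test."""

    params: pd.Series = field(repr=False)
    bse: pd.Series = field(repr=False)
    beta_phase: float
    se_phase: float
    statistic: float
    pvalue: float
    n: int
    test: str                        # "t" or "lr"
    flags: tuple[str, ...] = ()


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return records_to_frame(records)


def rt_phase_regression(records, outcome_filter: str = "correct",
                        phases: Sequence[str] | None = None) -> RegressionResult:
    """Linear regression of RT on motion-strength indicators plus a phase term.

    ``RT = sum_i beta_coh(i) I_coh(i) + beta_phase I_phase + eps`` fitted to
    completed trials with the given outcome (``correct`` or ``error``);
    ``I_phase`` is 1 for the later of the two phases compared.  The phase
    coefficient is tested against zero by t-test.
    """
    df = _as_frame(records)
    df = df[df["outcome"] == outcome_filter].copy()
    if phases is None:
        phases = sorted(df["phase"].unique())
    if len(phases) != 2:
        raise ValueError(f"exactly two phases required, got {list(phases)}")
    df = df[df["phase"].isin(phases)]
    for ph in phases:
        if (df["phase"] == ph).sum() == 0:
            raise ValueError(f"no {outcome_filter} trials in phase {ph}")
    df["strength"] = df["coherence"].abs()
    strengths = np.sort(df["strength"].unique())
    if strengths.size < 2:
        raise ValueError("at least two motion strengths are required")
    X = pd.DataFrame({
        f"coh_{s:g}": (df["strength"] == s).astype(float) for s in strengths
    })
    X["phase"] = (df["phase"] == phases[1]).astype(float)
    res = sm.OLS(df["rt_s"].to_numpy(), X).fit()
    return RegressionResult(
        params=res.params, bse=res.bse,
        beta_phase=float(res.params["phase"]),
        se_phase=float(res.bse["phase"]),
        statistic=float(res.tvalues["phase"]),
        pvalue=float(res.pvalues["phase"]),
        n=int(res.nobs), test="t",
        flags=() if np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]
        else ("rank_deficient",),
    )


def accuracy_phase_logistic(records, pooled: bool = False,
                            phases: Sequence[str] | None = None) -> RegressionResult:
    """Intercept-free logistic regression of accuracy on motion strength.

    ``logit(p_correct) = beta_1 |coh| + beta_phase I_phase`` per participant,
    or with per-participant strength slopes when ``pooled``.  The phase term
    is assessed with a likelihood-ratio test against the nested model
    without it.  The absence of an intercept pins chance accuracy (0.5) at
    zero coherence.
    """
    df = _as_frame(records)
    df = df[df["outcome"].isin(["correct", "error"])].copy()
    if phases is None:
        phases = sorted(df["phase"].unique())
    if len(phases) != 2:
        raise ValueError(f"exactly two phases required, got {list(phases)}")
    df = df[df["phase"].isin(phases)]
    for ph in phases:
        if (df["phase"] == ph).sum() == 0:
            raise ValueError(f"no completed trials in phase {ph}")
    y = (df["outcome"] == "correct").astype(float).to_numpy()
    strength = df["coherence"].abs().to_numpy()
    if pooled:
        X = pd.DataFrame({
            f"strength_{subj}": strength * (df["participant"] == subj).to_numpy()
            for subj in sorted(df["participant"].unique())
        })
    else:
        X = pd.DataFrame({"strength": strength})
    X_full = X.copy()
    X_full["phase"] = (df["phase"] == phases[1]).astype(float).to_numpy()
    flags: list[str] = []
    try:
        full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit()
        null = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception:
        # perfect separation or non-convergence: tiny-ridge fallback
        flags.append("penalized_fallback")
        full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-6, L1_wt=0.0)
        null = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-6, L1_wt=0.0)
    lr = 2.0 * (full.llf - null.llf)
    pvalue = float(sps.chi2.sf(max(lr, 0.0), df=1))
    try:
        bse = full.bse
        se_phase = float(bse["phase"])
    except Exception:
        bse = pd.Series(dtype=float)
        se_phase = float("nan")
    return RegressionResult(
        params=full.params, bse=bse,
        beta_phase=float(full.params["phase"]),
        se_phase=se_phase,
        statistic=float(lr), pvalue=pvalue, n=int(len(y)), test="lr",
        flags=tuple(flags),
    )


def time_dependent_accuracy(records, window_trials: int = 100
                            ) -> dict[float, pd.DataFrame]:
    """Accuracy as a function of RT per motion strength, sliding windows.

    Trials of each motion strength are sorted by RT; accuracy and mean RT
    are computed in windows of ``window_trials`` trials with stride 1.
    Returns a frame per strength with columns ``rt``, ``accuracy``, ``se``.
    A strength with fewer trials than the window yields a single window
    (with a ``single_window`` marker column).
    """
    df = _as_frame(records)
    df = df[df["outcome"].isin(["correct", "error"])].copy()
    df["strength"] = df["coherence"].abs()
    out: dict[float, pd.DataFrame] = {}
    for s, grp in df.groupby("strength"):
        grp = grp.sort_values("rt_s")
        rt = grp["rt_s"].to_numpy()
        acc = (grp["outcome"] == "correct").to_numpy(dtype=float)
        n = rt.size
        w = min(window_trials, n)
        kernel = np.ones(w) / w
        mean_rt = np.convolve(rt, kernel, mode="valid")
        mean_acc = np.convolve(acc, kernel, mode="valid")
        se = np.sqrt(np.clip(mean_acc * (1 - mean_acc), 0.0, None) / w)
        frame = pd.DataFrame({"rt": mean_rt, "accuracy": mean_acc, "se": se})
        frame.attrs["window"] = w
        frame.attrs["single_window"] = bool(w < window_trials)
        out[float(s)] = frame
    return out


def cancellation_aligned_rt(records, lags: int = 5) -> pd.DataFrame:
    """Mean z-scored RT at trial lags around each cancellation.

    RTs are z-scored within motion strength across all completed trials of
    the given records (all Phase II trial types are eligible).  For each
    canceled trial, completed trials at offsets ``-lags..-1, +1..+lags``
    within the same session contribute their z-scored RT at that lag.
    Returns a frame indexed by lag with ``mean_z``, ``n``, ``se``.
    """
    df = _as_frame(records)
    df = df.reset_index(drop=True)
    completed = df["outcome"].isin(["correct", "error"])
    df["strength"] = df["coherence"].abs()
    z = np.full(len(df), np.nan)
    for s, grp in df[completed].groupby("strength"):
        rts = grp["rt_s"].to_numpy(dtype=float)
        mu, sd = rts.mean(), rts.std(ddof=0)
        z[grp.index] = (rts - mu) / sd if sd > 0 else 0.0
    canceled_idx = df.index[df["outcome"] == "canceled"]
    if canceled_idx.size == 0:
        import warnings

        warnings.warn("no canceled trials in the records", stacklevel=2)
        return pd.DataFrame(columns=["mean_z", "n", "se"])
    lag_values = [k for k in range(-lags, lags + 1) if k != 0]
    sums = {k: [] for k in lag_values}
    for ci in canceled_idx:
        sess = df.at[ci, "session"]
        part = df.at[ci, "participant"]
        for k in lag_values:
            j = ci + k
            if j < 0 or j >= len(df):
                continue
            if df.at[j, "session"] != sess or df.at[j, "participant"] != part:
                continue
            if np.isfinite(z[j]):
                sums[k].append(z[j])
    rows = []
    for k in lag_values:
        vals = np.asarray(sums[k], dtype=float)
        rows.append({
            "lag": k,
            "mean_z": vals.mean() if vals.size else np.nan,
            "n": vals.size,
            "se": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1
            else np.nan,
        })
    return pd.DataFrame(rows).set_index("lag")


def pre_post_cancellation_test(records, n_trials: int = 2) -> tuple[float, float]:
    """Two-sample t-test of z-scored RTs just before vs just after cancellations.

    Compares the last ``n_trials`` completed trials before each canceled
    trial against the first ``n_trials`` after it.
    """
    df = _as_frame(records).reset_index(drop=True)
    aligned = cancellation_aligned_rt(records, lags=n_trials)
    # reconstruct raw samples: rerun alignment collecting values
    completed = df["outcome"].isin(["correct", "error"])
    df["strength"] = df["coherence"].abs()
    z = np.full(len(df), np.nan)
    for s, grp in df[completed].groupby("strength"):
        rts = grp["rt_s"].to_numpy(dtype=float)
        mu, sd = rts.mean(), rts.std(ddof=0)
        z[grp.index] = (rts - mu) / sd if sd > 0 else 0.0
    before, after = [], []
    for ci in df.index[df["outcome"] == "canceled"]:
        sess, part = df.at[ci, "session"], df.at[ci, "participant"]
        for k in range(1, n_trials + 1):
            for j, box in ((ci - k, before), (ci + k, after)):
                if 0 <= j < len(df) and df.at[j, "session"] == sess \
                        and df.at[j, "participant"] == part and np.isfinite(z[j]):
                    box.append(z[j])
    if not before or not after:
        raise ValueError("not enough trials around cancellations")
    stat, p = sps.ttest_ind(before, after, equal_var=False)
    return float(stat), float(p)
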