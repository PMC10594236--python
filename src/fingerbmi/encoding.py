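"""Lagged linear encoding models of SBP on kinematics and distance to target.

Single-lag models regress each channel's activity in bin k on the selected
kinematic variables (position P, velocity V, signed distance-to-target D; one
column per finger group) evaluated at bin k + l.  Negative lags therefore
mean the kinematics precede the neural activity.  Multi-lag models use every
lag in [-L, L] jointly.  Percent variance explained is in-sample R^2 per
channel, summarized across channels as mean +/- SEM; the contribution of the
distance term is assessed by the nested comparison of the velocity+position
model against velocity+position+distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .session import SimSession

__all__ = [
    "LagModelFit",
    "LagLinearModel",
    "fit_single_lag",
    "fit_multi_lag",
    "variance_curve",
    "channel_max_variance",
    "compare_nested",
]

REGRESSOR_ORDER = ("P", "V", "D")
DEFAULT_LAG_GRID = range(-12, 13)  # -600..+600 ms at 50 ms bins


@dataclass
class LagModelFit:
    """OLS fit of SBP on lagged kinematics.

    ``coef`` has shape (n_features, n_channels) with features ordered
    regressor-major, then finger group, then lag; ``r2`` is per-channel
    in-sample R^2 (NaN for zero-variance channels).
    """

    regressors: tuple[str, ...]
    lags: tuple[int, ...]
    n_groups: int
    coef: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    n_samples: int

    @property
    def feature_names(self) -> list[str]:
        return [
            f"{reg}{g}@l{lag:+d}"
            for reg in self.regressors
            for g in range(self.n_groups)
            for lag in self.lags
        ]


class LagLinearModel(BaseEstimator, RegressorMixin):
    """Sklearn-style wrapper: fit SBP on session kinematics at given lags."""

    def __init__(self, regressors: tuple[str, ...] = ("V", "P", "D"), lags: tuple[int, ...] = (0,)):
        self.regressors = regressors
        self.lags = lags

    def fit(self, session: SimSession, y=None):
        self.fit_ = _fit_lags(session, self.regressors, tuple(self.lags))
        self.coef_ = self.fit_.coef
        self.intercept_ = self.fit_.intercept
        self.r2_ = self.fit_.r2
        return self

    def score(self, session: SimSession, y=None) -> float:
        return float(np.nanmean(self.fit_.r2))


def _normalize_regressors(regressors) -> tuple[str, ...]:
    regs = tuple(r.upper() for r in regressors)
    if not regs:
        raise ValueError("regressor set must be non-empty")
    bad = set(regs) - set(REGRESSOR_ORDER)
    if bad:
        raise ValueError(f"unknown regressors {sorted(bad)}; allowed: P, V, D")
    return tuple(r for r in REGRESSOR_ORDER if r in regs)


def _kinematics(session: SimSession) -> dict[str, np.ndarray]:
    return {"P": session.pos, "V": session.vel, "D": session.dist}


def _fit_lags(session: SimSession, regressors, lags: tuple[int, ...]) -> LagModelFit:
    """Shared OLS core.  Bins whose lagged index falls outside the session
    are dropped (no padding in analysis, unlike the generator)."""
    regs = _normalize_regressors(regressors)
    if session.sbp is None:
        raise ValueError("session has no SBP to fit")
    n = session.n_bins
    lo = max(0, -min(lags))
    hi = n - max(0, max(lags))
    if hi - lo <= 1:
        raise ValueError("lag range leaves no usable bins")
    rows = np.arange(lo, hi)
    kin = _kinematics(session)
    cols = [
        kin[reg][rows + lag, g]
        for reg in regs
        for g in range(session.n_groups)
        for lag in lags
    ]
    X = np.column_stack(cols + [np.ones(len(rows))])
    if X.shape[1] > X.shape[0]:
        raise ValueError(
            f"design has {X.shape[1]} columns but only {X.shape[0]} usable bins"
        )
    Y = session.sbp[rows]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sse = np.sum(resid**2, axis=0)
    sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    r2 = np.where(np.isnan(r2), np.nan, np.clip(r2, 0.0, 1.0))
    return LagModelFit(
        regressors=regs,
        lags=tuple(lags),
        n_groups=session.n_groups,
        coef=beta[:-1],
        intercept=beta[-1],
        r2=r2,
        n_samples=len(rows),
    )


def fit_single_lag(session: SimSession, regressors, lag: int) -> LagModelFit:
    """Single-lag model: SBP(k) on kinematics(k + lag)."""
    if abs(lag) >= session.n_bins / 4:
        raise ValueError(f"|lag| = {abs(lag)} must be < n_bins / 4 = {session.n_bins / 4:g}")
    return _fit_lags(session, regressors, (int(lag),))


def fit_multi_lag(session: SimSession, regressors, L: int) -> LagModelFit:
    """Multi-lag model over the 2L+1 lags in [-L, L]; L = 0 reduces exactly
    to the single-lag model at lag 0."""
    if L < 0:
        raise ValueError("L must be >= 0")
    return _fit_lags(session, regressors, tuple(range(-L, L + 1)))


def variance_curve(session: SimSession, regressors, lags=DEFAULT_LAG_GRID) -> pd.DataFrame:
    """Mean percent variance explained by a single-lag model per lag.

    Returns a DataFrame with columns ``lag``, ``mean_pct``, ``sem_pct`` and a
    ``peak_lag`` attribute (argmax of the mean curve).  Channels with
    zero-variance activity are excluded from the mean with a warning.
    """
    lags = list(lags)
    if not lags:
        raise ValueError("lag range must be non-empty")
    rows = []
    warned = False
    for lag in lags:
        fit = fit_single_lag(session, regressors, lag)
        pct = 100.0 * fit.r2
        bad = np.isnan(pct)
        if bad.any() and not warned:
            warnings.warn(
                f"{bad.sum()} constant channel(s) excluded from variance curve "
                "(R^2 undefined)",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        ok = pct[~bad]
        sem = ok.std(ddof=1) / np.sqrt(len(ok)) if len(ok) > 1 else 0.0
        rows.append({"lag": lag, "mean_pct": float(ok.mean()), "sem_pct": float(sem)})
    out = pd.DataFrame(rows)
    out.attrs["peak_lag"] = int(out.loc[out["mean_pct"].idxmax(), "lag"])
    out.attrs["regressors"] = _normalize_regressors(regressors)
    return out


def channel_max_variance(session: SimSession, lags=DEFAULT_LAG_GRID) -> pd.DataFrame:
    """Per-channel maximum single-lag percent variance explained by velocity
    and by distance, plus the cross-channel linear R^2 between the two.

    A close-to-linear relation indicates that the channels most tuned to
    velocity are also the ones most tuned to the distance to target.
    """
    if session.n_channels < 2:
        raise ValueError("channel_max_variance requires at least 2 channels")
    lags = list(lags)
    max_v = np.full(session.n_channels, -np.inf)
    max_d = np.full(session.n_channels, -np.inf)
    for lag in lags:
        max_v = np.fmax(max_v, 100.0 * fit_single_lag(session, ("V",), lag).r2)
        max_d = np.fmax(max_d, 100.0 * fit_single_lag(session, ("D",), lag).r2)
    out = pd.DataFrame({"channel": np.arange(session.n_channels), "max_v_pct": max_v, "max_d_pct": max_d})
    ok = np.isfinite(max_v) & np.isfinite(max_d)
    if ok.sum() >= 2 and np.std(max_v[ok]) > 0 and np.std(max_d[ok]) > 0:
        r = stats.pearsonr(max_v[ok], max_d[ok]).statistic
        out.attrs["cross_channel_r2"] = float(r**2)
    else:
        out.attrs["cross_channel_r2"] = np.nan
    return out


def compare_nested(session: SimSession, L: int = 4, base=("V", "P"), full=("V", "P", "D")):
    """Nested multi-lag comparison: does adding the distance terms explain
    significantly more variance across channels?

    Returns a dict with per-channel R^2 of both models and the one-sided
    Wilcoxon signed-rank p-value (alternative: full > base).
    """
    fit_base = fit_multi_lag(session, base, L)
    fit_full = fit_multi_lag(session, full, L)
    ok = np.isfinite(fit_base.r2) & np.isfinite(fit_full.r2)
    res = stats.wilcoxon(fit_full.r2[ok], fit_base.r2[ok], alternative="greater")
    return {
        "r2_base": fit_base.r2,
        "r2_full": fit_full.r2,
        "p_value": float(res.pvalue),
        "L": L,
    }
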