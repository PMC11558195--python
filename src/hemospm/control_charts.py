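"""Multivariate control charts: T², SPE, and the SFA slow/fast T² pair.

With scores scaled so that the training score covariance is the identity,
the retained-block T² statistic reduces to the squared score norm and is
chi-square distributed under the null:

    T²(k)   = ||s_1:c(k)||²      ~ chi²_c,
    T²d(k)  = ||s_1:d(k)||²      ~ chi²_d,
    T²e(k)  = ||s_d+1:J(k)||²    ~ chi²_{J-d},

with flat control limits at the (1 - alpha) quantile (default
alpha = 0.01, the 99th percentile).  The residual-block SPE statistic
has no chi-square form; its per-minute limit uses the Box moment-matching
approximation g * chi²_h with g = v/(2m) and h = 2m²/v, where m and v are
the mean and variance of the training-cohort SPE at that minute, pooled
over a centered 5-minute window to stabilize the small-sample moments.

Invalid minutes yield no statistic (a chart gap), never an alarm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ContractError

CHART_NAMES = ("PCA_T2", "PCA_SPE", "SFA_T2D", "SFA_T2E")


@dataclass
class ControlChart:
    """Per-minute monitoring statistic, control limit and alarm mask."""

    name: str
    minutes: np.ndarray
    statistic: np.ndarray  # NaN at minutes with no usable observation
    limit: np.ndarray
    alarm: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.limit = np.broadcast_to(
            np.asarray(self.limit, dtype=float), self.statistic.shape).copy()
        self.alarm = np.asarray(self.alarm, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.statistic)

    @property
    def exceedance_fraction(self) -> float:
        v = self.valid
        return float(self.alarm[v].mean()) if v.any() else float("nan")


@dataclass
class SPELimitProfile:
    """Windowed per-minute moments of the training SPE and the resulting
    Box g*chi²_h limit."""

    minutes: np.ndarray
    m: np.ndarray  # windowed mean of training SPE per minute
    v: np.ndarray  # windowed variance of training SPE per minute
    limit: np.ndarray
    window: int
    alpha: float

    @property
    def g(self) -> np.ndarray:
        return self.v / (2.0 * self.m)

    @property
    def h(self) -> np.ndarray:
        return 2.0 * self.m**2 / self.v


def _finish(name, minutes, statistic, limit, alpha) -> ControlChart:
    statistic = np.asarray(statistic, dtype=float)
    limit = np.broadcast_to(np.asarray(limit, dtype=float), statistic.shape)
    valid = np.isfinite(statistic)
    alarm = np.zeros(statistic.shape, dtype=bool)
    alarm[valid] = statistic[valid] > limit[valid]
    return ControlChart(name, np.asarray(minutes), statistic, limit, alarm, alpha)


def t2_chart(scores: np.ndarray, minutes: np.ndarray, c: int,
             alpha: float = 0.01, name: str = "PCA_T2") -> ControlChart:
    """Hotelling T² chart on the retained score block (first c columns).

    ``scores`` is (K, >=c) with NaN rows at chart gaps; scores must be on
    the variance-consistent scale (training covariance = identity), so the
    (S'S)^{-1} weighting reduces to the identity and the statistic is the
    squared norm with a flat chi²_c limit.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if c < 1 or c > scores.shape[1]:
        raise ContractError(f"c must be in [1, {scores.shape[1]}]")
    stat = np.einsum("ij,ij->i", scores[:, :c], scores[:, :c])
    limit = stats.chi2.ppf(1.0 - alpha, c)
    return _finish(name, minutes, stat, limit, alpha)


def spe_limit_profile(training_spe: np.ndarray, minutes: np.ndarray,
                      window: int = 5, alpha: float = 0.01) -> SPELimitProfile:
    """Per-minute SPE control limits from training-cohort SPE samples.

    ``training_spe`` is (I_train, K) with NaN where a training patient has
    no observation.  Samples are pooled over a centered ``window``-minute
    span before computing the mean m and variance v (pooling the raw
    samples, rather than smoothing m and v afterwards, is the stabler
    reading of limit smoothing for small cohorts); minutes where the
    pooled variance is zero or fewer than 2 samples exist borrow the
    nearest resolvable minute's limit.
    """
    if window < 1 or window % 2 == 0:
        raise ContractError("window must be an odd integer >= 1")
    spe = np.atleast_2d(np.asarray(training_spe, dtype=float))
    I, K = spe.shape
    half = window // 2
    m = np.full(K, np.nan)
    v = np.full(K, np.nan)
    for k in range(K):
        pool = spe[:, max(0, k - half):k + half + 1]
        pool = pool[np.isfinite(pool)]
        if len(pool) >= 2:
            m[k] = pool.mean()
            v[k] = pool.var(ddof=1)
    resolvable = np.isfinite(m) & np.isfinite(v) & (v > 0) & (m > 0)
    if not resolvable.any():
        raise ContractError("no minute has enough training SPE samples")
    idx = np.flatnonzero(resolvable)
    nearest = idx[np.argmin(np.abs(np.arange(K)[:, None] - idx[None]), axis=1)]
    m = m[nearest]
    v = v[nearest]
    g = v / (2.0 * m)
    h = 2.0 * m**2 / v
    limit = g * stats.chi2.ppf(1.0 - alpha, h)  # non-integer dof
    return SPELimitProfile(np.asarray(minutes), m, v, limit, window, alpha)


def spe_chart(residual_scores: np.ndarray, minutes: np.ndarray,
              profile: SPELimitProfile, name: str = "PCA_SPE") -> ControlChart:
    """SPE chart: squared norm of the residual score block (columns c+1..J)
    against the windowed Box-approximation limits of ``profile``."""
    residual_scores = np.atleast_2d(np.asarray(residual_scores, dtype=float))
    if residual_scores.shape[0] != len(profile.limit):
        raise ContractError("residual scores and limit profile grids differ")
    stat = np.einsum("ij,ij->i", residual_scores, residual_scores)
    return _finish(name, minutes, stat, profile.limit, profile.alpha)


def sfa_t2_charts(scores: np.ndarray, minutes: np.ndarray, d: int,
                  alpha: float = 0.01):
    """SFA slow-block (T²,d) and fast-block (T²,e) charts.

    ``scores`` is the full (K, J) slow-feature score matrix ordered by
    ascending slowness.  Returns ``(T2D chart, T2E chart)`` with flat
    chi²_d and chi²_{J-d} limits; the two statistics partition the total
    score energy exactly.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    J = scores.shape[1]
    if not 1 <= d < J:
        raise ContractError(f"d must be in [1, {J - 1}]")
    slow = np.einsum("ij,ij->i", scores[:, :d], scores[:, :d])
    fast = np.einsum("ij,ij->i", scores[:, d:], scores[:, d:])
    t2d = _finish("SFA_T2D", minutes, slow, stats.chi2.ppf(1 - alpha, d), alpha)
    t2e = _finish("SFA_T2E", minutes, fast, stats.chi2.ppf(1 - alpha, J - d), alpha)
    return t2d, t2e


def alarm_sparks(chart: ControlChart, min_duration: int = 0):
    """Maximal runs of alarm minutes as half-open intervals.

    Runs shorter than ``min_duration`` minutes are discarded (the default
    0 keeps raw crossings — the charts do not debounce).  Chart gaps break
    runs.
    """
    a = chart.alarm & chart.valid
    edges = np.diff(a.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if a.size and a[0]:
        starts.insert(0, 0)
    if a.size and a[-1]:
        ends.append(len(a))
    minutes = np.asarray(chart.minutes)
    return [(int(minutes[s]), int(minutes[e - 1]) + 1)
            for s, e in zip(starts, ends)
            if e - s >= max(min_duration, 1)]
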