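"""Nonparametric trend and change-point inference for yearly climate-metric series.

Implements the classical suite used for environmental time series:

* Mann-Kendall test for monotone trend (tie-corrected variance, continuity
  correction on the normal deviate).
* Theil-Sen slope: the median of all pairwise slopes, with a Conover-form
  intercept ``median(v - slope * year)``.
* Pettitt change-point test for a single shift in central tendency, with the
  usual exponential approximation for significance (clamped at 1, since the
  approximation can exceed 1 for weak shifts).
* Before/after re-fitting of the trend suite around the detected change year,
  where the change year itself belongs to the "after" regime.

Years (not indices) are the time covariate throughout, so missing years do not
distort slopes. Missing values (NaN) are dropped together with their years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrendResult",
    "ChangePointResult",
    "StratumResult",
    "mann_kendall",
    "sen_slope",
    "trend_suite",
    "pettitt",
    "split_trends",
    "classify_direction",
    "summarize_directions",
]

INCREASE = "increase"
DECREASE = "decrease"
NO_CHANGE = "no_change"


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall + Theil-Sen output for one series.

    Attributes
    ----------
    s : Mann-Kendall score, ``sum_{i<j} sgn(v_j - v_i)``.
    var_s : tie-corrected variance of ``s``.
    z : continuity-corrected normal deviate.
    p : two-sided p-value from the normal approximation.
    sen_slope : median pairwise slope, units per year.
    slope_per_decade : ``10 * sen_slope``.
    intercept : ``median(v - slope * year)``.
    n : number of non-missing observations used.
    """

    s: int
    var_s: float
    z: float
    p: float
    sen_slope: float
    slope_per_decade: float
    intercept: float
    n: int


@dataclass(frozen=True)
class ChangePointResult:
    """Pettitt test output.

    ``u`` holds U_t for t = 1..n-1; ``k = max|U_t|``; ``t_star`` is the
    1-based index attaining it (earliest on ties); ``change_year`` is the year
    at index ``t_star`` (0-based ``t_star``), i.e. the first year of the
    "after" segment.
    """

    u: np.ndarray
    k: int
    t_star: int
    change_year: float
    p: float


@dataclass(frozen=True)
class StratumResult:
    """Full trend/change-point verdict for one stratum (realm x season x metric)."""

    stratum: str
    realm: str
    season: str
    metric: str
    full: TrendResult
    change_point: ChangePointResult | None
    before: TrendResult | None
    after: TrendResult | None
    slope_ratio: float
    direction: str


def _clean(values, years=None):
    v = np.asarray(values, dtype=float)
    if years is None:
        y = np.arange(v.size, dtype=float)
    else:
        y = np.asarray(years, dtype=float)
        if y.size != v.size:
            raise ValueError("values and years must have equal length")
    keep = ~np.isnan(v)
    return v[keep], y[keep]


def mann_kendall(values) -> tuple[int, float, float, float]:
    """Mann-Kendall test for monotone trend.

    Returns ``(S, var_S, z, p)`` where S is the pairwise sign score, var_S is
    tie-corrected, z carries the +/-1 continuity correction and p is the
    two-sided normal tail. A fully tied series has var_S = 0 and is reported
    as z = 0, p = 1 (no evidence of trend).
    """
    v, _ = _clean(values)
    n = v.size
    if n < 3:
        raise ValueError(f"Mann-Kendall requires n >= 3, got {n}")
    diff = np.sign(v[None, :] - v[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(v, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    if var_s <= 0:
        return s, 0.0, 0.0, 1.0
    if s > 0:
        z = (s - 1) / math.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / math.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return s, var_s, z, min(p, 1.0)


def sen_slope(values, years=None) -> tuple[float, float]:
    """Theil-Sen slope and intercept.

    slope = median over all pairs i<j of (v_j - v_i)/(year_j - year_i);
    intercept = median(v - slope * year).
    """
    v, y = _clean(values, years)
    n = v.size
    if n < 2:
        raise ValueError(f"Theil-Sen requires n >= 2, got {n}")
    i, j = np.triu_indices(n, k=1)
    dy = y[j] - y[i]
    if np.any(dy == 0):
        raise ValueError("years must be strictly increasing")
    slope = float(np.median((v[j] - v[i]) / dy))
    intercept = float(np.median(v - slope * y))
    return slope, intercept


def trend_suite(values, years=None) -> TrendResult:
    """Mann-Kendall test and Theil-Sen fit on one series."""
    v, y = _clean(values, years)
    s, var_s, z, p = mann_kendall(v)
    slope, intercept = sen_slope(v, y)
    return TrendResult(
        s=s,
        var_s=var_s,
        z=z,
        p=p,
        sen_slope=slope,
        slope_per_decade=10.0 * slope,
        intercept=intercept,
        n=v.size,
    )


def pettitt(values, years=None) -> ChangePointResult:
    """Pettitt test for a single change point in central tendency.

    ``U_t = sum_{i<=t} sum_{j>t} sgn(v_i - v_j)`` for t = 1..n-1;
    ``K = max|U_t|``; significance ``p = min(1, 2 exp(-6 K^2 / (n^3 + n^2)))``.
    Argmax ties resolve to the earliest t so output is deterministic.
    """
    v, y = _clean(values, years)
    n = v.size
    if n < 4:
        raise ValueError(f"Pettitt requires n >= 4, got {n}")
    sgn = np.sign(v[:, None] - v[None, :])
    u = np.empty(n - 1)
    for t in range(n - 1):
        u[t] = np.sum(sgn[: t + 1, t + 1 :])
    k = int(np.max(np.abs(u)))
    t_star = int(np.argmax(np.abs(u))) + 1  # 1-based split index
    p = 2.0 * math.exp(-6.0 * k * k / (n**3 + n**2))
    change_year = float(y[t_star])  # first year of the "after" segment
    return ChangePointResult(u=u, k=k, t_star=t_star, change_year=change_year, p=min(1.0, p))


def split_trends(
    values, years, change_year: float, min_segment: int = 3
) -> tuple[TrendResult | None, TrendResult | None, float]:
    """Re-fit the trend suite before and after a change year.

    ``before`` uses years < change_year, ``after`` uses years >= change_year
    (the change year opens the new regime). A segment shorter than
    ``min_segment`` is returned as None. ``slope_ratio`` is
    ``|after.sen_slope| / |before.sen_slope|`` and NaN when either side is
    unavailable or the before-slope is zero.
    """
    v, y = _clean(values, years)
    if not (y.min() < change_year <= y.max()):
        raise ValueError(f"change_year {change_year} outside series span")
    mask = y < change_year
    before = trend_suite(v[mask], y[mask]) if mask.sum() >= min_segment else None
    after = trend_suite(v[~mask], y[~mask]) if (~mask).sum() >= min_segment else None
    if before is None or after is None or before.sen_slope == 0:
        ratio = float("nan")
    else:
        ratio = abs(after.sen_slope) / abs(before.sen_slope)
    return before, after, ratio


def classify_direction(p: float, slope: float, alpha: float = 0.05) -> str:
    """Classify a stratum: increase / decrease when significant, else no_change."""
    if p <= alpha and slope > 0:
        return INCREASE
    if p <= alpha and slope < 0:
        return DECREASE
    return NO_CHANGE


def summarize_directions(directions) -> tuple[float, float, float]:
    """Percentages (increase, decrease, no_change) over a list of verdicts."""
    dirs = list(directions)
    if not dirs:
        raise ValueError("no strata to summarize")
    n = len(dirs)
    inc = 100.0 * sum(d == INCREASE for d in dirs) / n
    dec = 100.0 * sum(d == DECREASE for d in dirs) / n
    return inc, dec, 100.0 - inc - dec


def analyze_stratum(
    values,
    years,
    stratum: str = "",
    realm: str = "",
    season: str = "",
    metric: str = "",
    alpha: float = 0.05,
) -> StratumResult:
    """Run the full suite on one yearly series and classify its direction."""
    v, y = _clean(values, years)
    full = trend_suite(v, y)
    if v.size >= 4:
        cp = pettitt(v, y)
        before, after, ratio = split_trends(v, y, cp.change_year)
    else:
        cp, before, after, ratio = None, None, None, float("nan")
    return StratumResult(
        stratum=stratum,
        realm=realm,
        season=season,
        metric=metric,
        full=full,
        change_point=cp,
        before=before,
        after=after,
        slope_ratio=ratio,
        direction=classify_direction(full.p, full.sen_slope, alpha),
    )
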