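"""Closed-form test statistics shared across modules.

The statistics (t, F, KS D) are computed from their textbook sum-of-squares /
ECDF definitions; only the reference distributions (Student t, Fisher F,
asymptotic Kolmogorov) come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import special, stats as sps


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero-ward (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """100 * count / total rounded half-up; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


@dataclass
class TTestResult:
    t: float
    df: int
    p_one_sided: float
    p_two_sided: float
    mean: float


def one_sample_t(values: Sequence[float], popmean: float) -> TTestResult:
    """One-sample t test from its closed form; sample SD uses ddof=1."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("one-sample t test needs at least 2 observations")
    m = float(x.mean())
    s = float(x.std(ddof=1))
    if s == 0.0:
        t = math.inf if m > popmean else (-math.inf if m < popmean else 0.0)
    else:
        t = (m - popmean) / (s / math.sqrt(n))
    p1 = float(sps.t.sf(t, n - 1))
    p2 = float(2 * sps.t.sf(abs(t), n - 1))
    return TTestResult(t=t, df=n - 1, p_one_sided=p1, p_two_sided=p2, mean=m)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sum-of-squares decomposition.

    ``degenerate`` flags zero within-group variance with nonzero between-group
    spread (F formally infinite).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    n_total = sum(a.size for a in arrays)
    grand = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        if ss_between > 0:
            return AnovaResult(math.inf, df_b, df_w, 0.0, degenerate=True)
        return AnovaResult(0.0, df_b, df_w, 1.0, degenerate=True)
    F = (ss_between / df_b) / ms_w
    return AnovaResult(float(F), df_b, df_w, float(sps.f.sf(F, df_b, df_w)))


@dataclass
class TwoWayAnovaResult:
    F_a: float
    F_b: float
    F_ab: float
    p_a: float
    p_b: float
    p_ab: float
    df: dict
    degenerate: bool = False


def two_way_anova_balanced(table: np.ndarray) -> TwoWayAnovaResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    ``table`` has shape (levels_a, levels_b, replicates); every design cell
    must hold the same number of replicates (n >= 2).
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 3:
        raise ValueError("table must be (a, b, n)")
    a, b, n = y.shape
    if n < 2:
        raise ValueError("need >= 2 replicates per cell")
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)
    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_e = ((y - mean_ab[:, :, None]) ** 2).sum()
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e
    df = {"a": df_a, "b": df_b, "ab": df_ab, "error": df_e}
    if ms_e == 0.0:
        inf_or0 = lambda ss: math.inf if ss > 0 else 0.0
        return TwoWayAnovaResult(
            inf_or0(ss_a), inf_or0(ss_b), inf_or0(ss_ab),
            0.0 if ss_a > 0 else 1.0, 0.0 if ss_b > 0 else 1.0,
            0.0 if ss_ab > 0 else 1.0, df, degenerate=True,
        )
    F_a = (ss_a / df_a) / ms_e
    F_b = (ss_b / df_b) / ms_e
    F_ab = (ss_ab / df_ab) / ms_e
    return TwoWayAnovaResult(
        float(F_a), float(F_b), float(F_ab),
        float(sps.f.sf(F_a, df_a, df_e)),
        float(sps.f.sf(F_b, df_b, df_e)),
        float(sps.f.sf(F_ab, df_ab, df_e)),
        df,
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and asymptotic p.

    D = sup |ECDF_a - ECDF_b| evaluated at every pooled data point; p from the
    asymptotic Kolmogorov distribution at sqrt(nm/(n+m)) * D.
    """
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    n, m = xa.size, xb.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, xb])
    cdf_a = np.searchsorted(xa, pooled, side="right") / n
    cdf_b = np.searchsorted(xb, pooled, side="right") / m
    d = float(np.abs(cdf_a - cdf_b).max())
    en = math.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return d, min(max(p, 0.0), 1.0)


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean (ddof=1); NaN for fewer than 2 values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / math.sqrt(x.size))
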