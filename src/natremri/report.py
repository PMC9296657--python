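"""Group-level statistics used throughout the analysis figures.

Unpaired two-tailed Student (pooled-variance) t comparisons, Pearson
correlation with its t-based p-value, and the fold-change convention used
in the results text: fold change = (A - B)/B, i.e. relative change over the
comparator (a "2.5-fold increase" means A = 3.5 B; "0.7-fold lower" means
A = 0.3 B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float
    fold_change: float | None
    degenerate: bool = False


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float


def compare_groups(a, b, name_a: str = "A", name_b: str = "B",
                   welch: bool = False) -> GroupComparison:
    """Unpaired two-tailed t comparison of two groups.

    Pooled-variance Student t by default (df = n_a + n_b - 2); Welch's
    unequal-variance form by flag. A zero pooled variance with equal means
    is reported as t = 0, p = 1; with unequal means the comparison is
    degenerate (infinite t, p = 0, flagged).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    common = dict(
        group_a=name_a, group_b=name_b, n_a=na, n_b=nb,
        mean_a=float(ma), mean_b=float(mb),
        sem_a=float(np.sqrt(va / na)), sem_b=float(np.sqrt(vb / nb)),
        fold_change=float((ma - mb) / mb) if mb != 0 else None,
    )
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return _degenerate_comparison(ma, mb, common)
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0:
            return _degenerate_comparison(ma, mb, common)
        t = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(t=float(t), p=float(p), **common)


def _degenerate_comparison(ma, mb, common) -> GroupComparison:
    if ma == mb:
        return GroupComparison(t=0.0, p=1.0, **common)
    return GroupComparison(t=float(np.sign(ma - mb)) * np.inf, p=0.0,
                           degenerate=True, **common)


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with the exact t-based two-tailed p-value,
    t = r * sqrt((n - 2) / (1 - r^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xc**2)), np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)


def fold_change(mean_a: float, mean_b: float) -> float:
    """Relative change of A over comparator B: (A - B)/B."""
    if mean_b == 0:
        raise ZeroDivisionError("comparator mean is zero")
    return (mean_a - mean_b) / mean_b
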