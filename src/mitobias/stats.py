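"""Two-sample Kolmogorov–Smirnov testing and Bonferroni correction.

The D statistic is computed exactly from the two empirical CDFs (ties
included); the p-value uses the asymptotic Kolmogorov distribution with
effective sample size n1*n2/(n1+n2).  On heavily tied count data this
approximation is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import kolmogorov

__all__ = ["KSResult", "ks_two_sample", "bonferroni", "significance_band"]

SIGNIFICANCE_BANDS = [(0.001, "<=0.001"), (0.01, "<=0.01"), (0.05, "<=0.05")]


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n1: int
    n2: int
    sidedness: str = "two-sided"


def ks_two_sample(x, y) -> KSResult:
    """Two-sided two-sample KS test with asymptotic p-value.

    D is the supremum of |ECDF1 - ECDF2| over all observed points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    xs, ys = np.sort(x), np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf1 = np.searchsorted(xs, grid, side="right") / n1
    cdf2 = np.searchsorted(ys, grid, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return KSResult(d_statistic=d, p_value=p, n1=n1, n2=n2)


def bonferroni(p_values) -> list[float]:
    """Multiply each p-value by the number of tests, capping at 1."""
    p = list(p_values)
    k = len(p)
    out = []
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {v}")
        out.append(min(1.0, v * k))
    return out


def significance_band(p: float) -> str:
    """Reporting band for a (corrected) p-value: <=0.001, <=0.01, <=0.05, >0.05."""
    for cut, label in SIGNIFICANCE_BANDS:
        if p <= cut:
            return label
    return ">0.05"
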