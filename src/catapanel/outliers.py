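"""Small-sample outlier tests used for panelist screening.

Three classical tests on a univariate sample, each asking whether the most
extreme value is an outlier:

* Grubbs: G = extreme deviation / sample standard deviation, with the
  standard t-based p-value.
* Dixon: ratio of the gap between the extreme value and its neighbour to
  (a portion of) the range, using the sample-size-appropriate variant
  (r10 for n 3-7, r11 for 8-10, r21 for 11-13, r22 for 14-30); p-values by
  piecewise-linear interpolation in published critical-value tables.
* Chi-square: (x_extreme - mean)^2 / s^2 referred to chi-square(1).  Note
  this criterion is anticonservative for the sample extreme (p < 0.05
  corresponds to |z| > 1.96, which the most extreme of ~20 values exceeds in
  a large fraction of null samples); it is reported during screening but not
  used for removal decisions by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .dataset import DegenerateDataError

__all__ = ["TestResult", "grubbs_test", "dixon_test", "chisq_outlier_test"]

Alternative = Literal["min", "max", "two_sided"]


@dataclass(frozen=True)
class TestResult:
    """Generic hypothesis-test result."""

    statistic: float
    p_value: float
    method: str
    alternative: Optional[str] = None
    df: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if np.isnan(x).any():
        raise ValueError("values contain NaN")
    return x


def grubbs_test(values, alternative: Alternative = "two_sided") -> TestResult:
    """Grubbs test for a single outlier.

    G is the deviation of the extreme value (smallest for ``min``, largest
    for ``max``, largest absolute for ``two_sided``) from the mean, divided
    by the sample standard deviation.  The p-value uses the exact t-based
    tail bound p = min(1, c * n * P(T_{n-2} > t)) with
    t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2) and c = 2 for the two-sided
    alternative.
    """
    x = _clean(values)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateDataError("Grubbs test undefined for zero-variance data")
    mean = x.mean()
    if alternative == "min":
        g = (mean - x.min()) / s
    elif alternative == "max":
        g = (x.max() - mean) / s
    elif alternative == "two_sided":
        g = np.abs(x - mean).max() / s
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    denom = (n - 1) ** 2 - n * g**2
    if denom <= 0:  # G at its attainable maximum (n-1)/sqrt(n)
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * g**2 / denom)
        tail = stats.t.sf(t, df=n - 2)
        factor = 2 * n if alternative == "two_sided" else n
        p = min(1.0, factor * tail)
    return TestResult(float(g), float(p), "Grubbs test", alternative, df=n - 2, n=n)


# Two-tailed Dixon critical values (Dixon 1953 / Rorabacher 1991) for the
# size-appropriate ratio variant, at significance levels 0.01/0.02/0.05/0.10.
_DIXON_ALPHAS = (0.01, 0.02, 0.05, 0.10)
_DIXON_CRITICAL = {
    3: (0.988, 0.976, 0.941, 0.886),
    4: (0.889, 0.846, 0.765, 0.679),
    5: (0.780, 0.729, 0.642, 0.557),
    6: (0.698, 0.644, 0.560, 0.482),
    7: (0.637, 0.586, 0.507, 0.434),
    8: (0.683, 0.631, 0.554, 0.479),
    9: (0.635, 0.587, 0.512, 0.441),
    10: (0.597, 0.551, 0.477, 0.409),
    11: (0.679, 0.638, 0.576, 0.517),
    12: (0.642, 0.605, 0.546, 0.490),
    13: (0.615, 0.578, 0.521, 0.467),
    14: (0.641, 0.602, 0.546, 0.492),
    15: (0.616, 0.579, 0.525, 0.472),
    16: (0.595, 0.559, 0.507, 0.454),
    17: (0.577, 0.542, 0.490, 0.438),
    18: (0.561, 0.527, 0.475, 0.424),
    19: (0.547, 0.514, 0.462, 0.412),
    20: (0.535, 0.502, 0.450, 0.401),
    21: (0.524, 0.491, 0.440, 0.391),
    22: (0.514, 0.481, 0.430, 0.382),
    23: (0.505, 0.472, 0.421, 0.374),
    24: (0.497, 0.464, 0.413, 0.367),
    25: (0.489, 0.457, 0.406, 0.360),
    26: (0.486, 0.450, 0.399, 0.354),
    27: (0.475, 0.443, 0.393, 0.348),
    28: (0.469, 0.437, 0.387, 0.342),
    29: (0.463, 0.431, 0.381, 0.337),
    30: (0.457, 0.426, 0.376, 0.332),
}


def _dixon_ratio(x_sorted: np.ndarray) -> float:
    """Size-appropriate Dixon ratio for the *largest* value of a sorted sample."""
    n = x_sorted.size
    if n <= 7:
        num = x_sorted[-1] - x_sorted[-2]
        den = x_sorted[-1] - x_sorted[0]
    elif n <= 10:
        num = x_sorted[-1] - x_sorted[-2]
        den = x_sorted[-1] - x_sorted[1]
    elif n <= 13:
        num = x_sorted[-1] - x_sorted[-3]
        den = x_sorted[-1] - x_sorted[1]
    else:
        num = x_sorted[-1] - x_sorted[-3]
        den = x_sorted[-1] - x_sorted[2]
    if den == 0:
        raise DegenerateDataError("Dixon test undefined: zero range")
    return float(num / den)


def dixon_test(values, alternative: Literal["min", "max"] = "max") -> TestResult:
    """Dixon ratio test for a single outlier (3 <= n <= 30).

    The p-value is interpolated piecewise-linearly between the tabulated
    critical values, anchored at (ratio 0, p 1) and (ratio 1, p 0); it is
    therefore approximate outside the tabulated 0.01-0.10 band.
    """
    x = _clean(values)
    n = x.size
    if not 3 <= n <= 30:
        raise ValueError("Dixon test supports 3 <= n <= 30")
    x_sorted = np.sort(x)
    if alternative == "min":
        x_sorted = np.sort(-x)  # mirror: smallest value becomes the largest
    elif alternative != "max":
        raise ValueError(f"unknown alternative {alternative!r}")
    q = _dixon_ratio(x_sorted)

    crit = _DIXON_CRITICAL[n]
    # knots ordered by increasing statistic: (0,1) ... table ... (1,0)
    xs = [0.0] + [crit[i] for i in reversed(range(len(crit)))] + [1.0]
    ps = [1.0] + [_DIXON_ALPHAS[i] for i in reversed(range(len(crit)))] + [0.0]
    p = float(np.interp(q, xs, ps))
    variant = "r10" if n <= 7 else "r11" if n <= 10 else "r21" if n <= 13 else "r22"
    return TestResult(q, p, f"Dixon test ({variant})", alternative, n=n)


def chisq_outlier_test(values, alternative: Literal["min", "max"] = "max") -> TestResult:
    """Chi-square criterion for a single outlier.

    Statistic (x_extreme - mean)^2 / s^2 with the sample variance, referred
    to the chi-square distribution with 1 degree of freedom (the convention
    of the classical R implementation).
    """
    x = _clean(values)
    if x.size < 3:
        raise ValueError("chi-square outlier test needs n >= 3")
    var = x.var(ddof=1)
    if var == 0:
        raise DegenerateDataError("chi-square outlier test undefined for zero variance")
    extreme = x.min() if alternative == "min" else x.max()
    if alternative not in ("min", "max"):
        raise ValueError(f"unknown alternative {alternative!r}")
    stat = (extreme - x.mean()) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(float(stat), p, "chi-square outlier test", alternative, df=1, n=x.size)
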