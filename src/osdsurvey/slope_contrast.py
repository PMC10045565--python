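"""Contrast of subjective and objective slopes on the rejecting half.

On the subset of respondents whose attitude score is <= 0 the study fits
separate OLS regressions of the subjective-understanding score and of the
objective-knowledge score on attitude, and compares the two slopes with

    t = (slope1 - slope2) / sqrt(SEM1^2 + SEM2^2),   df = n1 + n2 - 4.

A more negative subjective slope than objective slope means self-assessed
understanding rises faster than demonstrated knowledge as attitudes become
more negative.  The default p-value is one-sided (lower tail of t), matching
the published tables; two-sided is available via ``sided='two'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import DegenerateDataError, ParameterError, ValidationError

__all__ = ["SlopePair", "fit_attitude_slope", "slope_diff_test",
           "compare_slopes"]


@dataclass
class SlopePair:
    """Slope-contrast result mirroring the published table columns."""

    slope_subjective: float
    sem_subjective: float
    n_subjective: int
    slope_objective: float
    sem_objective: float
    n_objective: int
    t: float
    df: int
    p: float
    sided: str


def fit_attitude_slope(attitude, response, subset: str = "nonpositive",
                       ) -> tuple[float, float, int]:
    """OLS slope of ``response`` on ``attitude`` over an attitude subset.

    ``subset`` is one of ``'nonpositive'`` (attitude <= 0, the default used
    by the study), ``'nonnegative'`` or ``'all'``.  Returns
    ``(slope, sem, n)`` where ``sem`` is the standard error of the slope.
    """
    attitude = np.asarray(attitude, dtype=float)
    response = np.asarray(response, dtype=float)
    if attitude.shape != response.shape or attitude.ndim != 1:
        raise ValidationError("attitude and response must be equal-length 1-d")
    masks = {"nonpositive": attitude <= 0,
             "nonnegative": attitude >= 0,
             "all": np.ones_like(attitude, dtype=bool)}
    if subset not in masks:
        raise ParameterError(f"unknown subset {subset!r}")
    mask = masks[subset]
    a, r = attitude[mask], response[mask]
    n = a.size
    if n < 3:
        raise DegenerateDataError("subset has fewer than 3 rows")
    if np.unique(a).size < 2:
        raise DegenerateDataError("subset has fewer than 2 distinct attitudes")
    res = stats.linregress(a, r)
    return float(res.slope), float(res.stderr), n


def slope_diff_test(slope1: float, sem1: float, n1: int,
                    slope2: float, sem2: float, n2: int,
                    sided: str = "one") -> tuple[float, int, float]:
    """t test for a difference between two independent regression slopes.

    ``t = (slope1 - slope2) / sqrt(sem1^2 + sem2^2)`` with
    ``df = n1 + n2 - 4``.  One-sided p is the lower-tail probability
    ``P(T <= t)`` (slope1 more negative than slope2); equal slopes give
    p = 0.5.  Two-sided doubles the tail of ``|t|``.
    """
    if sided not in ("one", "two"):
        raise ParameterError(f"sided must be 'one' or 'two', got {sided!r}")
    if sem1 < 0 or sem2 < 0:
        raise ParameterError("standard errors must be non-negative")
    df = int(n1) + int(n2) - 4
    if df < 1:
        raise ValidationError("n1 + n2 - 4 must be at least 1")
    denom = np.hypot(sem1, sem2)
    if denom == 0:
        if slope1 == slope2:
            raise DegenerateDataError(
                "both SEMs are zero with equal slopes; t undefined")
        t = np.inf if slope1 > slope2 else -np.inf
    else:
        t = (slope1 - slope2) / denom
    if sided == "one":
        p = float(stats.t.cdf(t, df))
    else:
        p = float(2 * stats.t.sf(abs(t), df))
    return float(t), df, p


def compare_slopes(attitude, subjective, objective,
                   subset: str = "nonpositive", sided: str = "one",
                   ) -> SlopePair:
    """Full slope contrast for one attitude question.

    Fits the subjective and objective slopes on the chosen attitude subset
    and tests their difference (subjective minus objective).
    """
    s1, e1, m1 = fit_attitude_slope(attitude, subjective, subset)
    s2, e2, m2 = fit_attitude_slope(attitude, objective, subset)
    t, df, p = slope_diff_test(s1, e1, m1, s2, e2, m2, sided=sided)
    return SlopePair(slope_subjective=s1, sem_subjective=e1, n_subjective=m1,
                     slope_objective=s2, sem_objective=e2, n_objective=m2,
                     t=t, df=df, p=p, sided=sided)
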