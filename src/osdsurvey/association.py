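"""Rank correlation and partial rank correlation tables.

The study's correlation tables show, for a set of variables, the plain
Spearman rho above the diagonal and below it the pairwise partial
correlation of each pair controlling for all remaining variables.  Partials
are computed on rank-transformed data (average ranks) by inverting the
correlation matrix of the ranked variables; significance is flagged at a raw
(uncorrected) two-sided 0.05, as in the source analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DegenerateDataError, ParameterError, ValidationError

__all__ = ["spearman", "partial_spearman", "build_correlation_table",
           "CorrelationTable"]


def _check_finite_1d(name, v):
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} contains non-finite values")
    return v


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  Raises :class:`DegenerateDataError` for a
    constant input (rho undefined).
    """
    x = _check_finite_1d("x", x)
    y = _check_finite_1d("y", y)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input; rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, controls=(), method: str = "spearman",
                     ) -> tuple[float, float]:
    """Partial correlation of ``x`` and ``y`` given ``controls``.

    With ``method='spearman'`` (default) every variable is rank-transformed
    (average ranks) first, so the statistic is a rank-based partial
    correlation; ``method='pearson'`` partials on the raw values.  The
    partial coefficient comes from the inverse of the correlation matrix of
    ``[x, y, *controls]``:

        r_xy.z = -P_xy / sqrt(P_xx * P_yy)

    where ``P`` is the precision matrix.  The two-sided p-value uses the t
    approximation with ``n - k - 2`` degrees of freedom (k controls).  With
    no controls this reduces exactly to the plain correlation.
    """
    if method not in ("spearman", "pearson"):
        raise ParameterError(f"method must be 'spearman' or 'pearson', "
                             f"got {method!r}")
    x = _check_finite_1d("x", x)
    y = _check_finite_1d("y", y)
    ctrl = [_check_finite_1d(f"controls[{i}]", c)
            for i, c in enumerate(controls)]
    n, k = x.size, len(ctrl)
    for c in ctrl:
        if c.size != n:
            raise ValidationError("all vectors must have equal length")
    if y.size != n:
        raise ValidationError("x and y must have equal length")
    if n < k + 3:
        raise ValidationError(f"need at least {k + 3} observations for "
                              f"{k} controls")

    cols = [x, y] + ctrl
    if method == "spearman":
        cols = [stats.rankdata(c) for c in cols]
    M = np.column_stack(cols)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError("constant variable; correlation undefined")
    C = np.corrcoef(M, rowvar=False)
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as e:
        raise DegenerateDataError(f"singular correlation matrix: {e}") from e
    denom = P[0, 0] * P[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateDataError("singular correlation matrix")
    r = float(-P[0, 1] / np.sqrt(denom))
    r = float(np.clip(r, -1.0, 1.0))

    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class CorrelationTable:
    """Square correlation summary in the study's table layout.

    ``matrix`` holds plain rho above the diagonal and the partial rho of each
    pair, controlling for all other listed variables, below it; the diagonal
    is NaN.  ``p_values`` mirrors the layout; ``significant`` flags cells
    with p < ``alpha``.
    """

    variables: list[str]
    matrix: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    n: int
    alpha: float = 0.05
    method: str = "spearman"

    def cell(self, row: str, col: str) -> float:
        return float(self.matrix.loc[row, col])

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)

    def formatted(self) -> pd.DataFrame:
        """Rendering with significance shown as a trailing ``*``."""
        def fmt(r, c):
            if r == c:
                return "-"
            v = self.matrix.loc[r, c]
            star = "*" if bool(self.significant.loc[r, c]) else ""
            return f"{v:.3f}{star}"
        return pd.DataFrame(
            [[fmt(r, c) for c in self.variables] for r in self.variables],
            index=self.variables, columns=self.variables)


def build_correlation_table(scored: pd.DataFrame,
                            variables: Sequence[str],
                            alpha: float = 0.05,
                            method: str = "spearman") -> CorrelationTable:
    """Build the rho / partial-rho table for ``variables`` of ``scored``.

    Rows with a missing value in any listed variable are dropped listwise;
    the per-analysis N is recorded on the result.  Upper triangle: plain
    Spearman rho of the pair.  Lower triangle: partial correlation of the
    pair controlling for all other listed variables.
    """
    missing = [v for v in variables if v not in scored.columns]
    if missing:
        raise ValidationError(f"variables not in table: {missing}")
    variables = list(variables)
    data = scored[variables].dropna()
    n = len(data)
    if n < 3:
        raise ValidationError(f"fewer than 3 complete rows (N={n})")

    m = len(variables)
    rho = np.full((m, m), np.nan)
    pval = np.full((m, m), np.nan)
    arrays = {v: data[v].to_numpy(dtype=float) for v in variables}
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            vi, vj = variables[i], variables[j]
            if i < j:       # upper triangle: plain correlation
                r, p = spearman(arrays[vi], arrays[vj])
            else:           # lower triangle: partial, controlling the rest
                ctrl = [arrays[v] for v in variables if v not in (vi, vj)]
                r, p = partial_spearman(arrays[vi], arrays[vj], ctrl,
                                        method=method)
            rho[i, j], pval[i, j] = r, p

    matrix = pd.DataFrame(rho, index=variables, columns=variables)
    p_values = pd.DataFrame(pval, index=variables, columns=variables)
    significant = (p_values < alpha) & p_values.notna()
    return CorrelationTable(variables=variables, matrix=matrix,
                            p_values=p_values, significant=significant,
                            n=n, alpha=alpha, method=method)
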