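"""Linear-versus-quadratic model comparison with a balanced-resampling null.

The study asks whether self-assessed understanding is a U-shaped function of
attitude (scored -2..+2, treated as numeric).  Three instruments:

* :func:`fit_linear_quadratic` -- OLS fits of ``y ~ x`` and ``y ~ x + x^2``,
  adjusted R-squared for both, and the nested F test (1 numerator df) for the
  improvement of the quadratic over the linear fit.
* :func:`balanced_resample_test` -- because attitude classes are very
  unbalanced (the extreme classes are small), the improvement test is
  repeated on resamples that draw the minimum class size from every class
  without replacement, and the proportion of resamples whose quadratic
  improvement is significant at ``alpha`` is reported.
* :func:`split_correlations` -- Spearman correlations of y with x computed
  separately on the non-negative (x >= 0) and non-positive (x <= 0) halves;
  respondents scoring exactly zero appear in both halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._exceptions import DegenerateDataError, ParameterError, ValidationError
from .association import spearman

__all__ = ["FitComparison", "ResampleResult", "fit_linear_quadratic",
           "balanced_resample_test", "split_correlations"]


@dataclass
class FitComparison:
    """Outcome of the nested linear/quadratic comparison."""

    n: int
    coef_linear: np.ndarray       #: (intercept, slope)
    coef_quadratic: np.ndarray    #: (intercept, slope, curvature)
    rss_linear: float
    rss_quadratic: float
    adj_r2_linear: float
    adj_r2_quadratic: float
    f_statistic: float
    improvement_p: float

    @property
    def quadratic_coefficient(self) -> float:
        """The fitted coefficient on x^2; positive means a U shape."""
        return float(self.coef_quadratic[2])


def _adj_r2(rss, tss, n, p):
    # p = number of predictors excluding the intercept
    if tss == 0:
        raise DegenerateDataError("response has zero variance")
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_linear_quadratic(x, y) -> FitComparison:
    """Fit ``y ~ x`` and ``y ~ x + x^2`` by OLS and test the improvement.

    The improvement p-value is the nested F test
    ``F = (RSS_lin - RSS_quad) / (RSS_quad / (n - 3))`` on (1, n-3) df.
    Requires n >= 4 and at least three distinct x values (otherwise the
    quadratic design is collinear).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if np.unique(x).size < 3:
        raise DegenerateDataError(
            "need at least 3 distinct x values for a quadratic fit")

    X_lin = np.column_stack([np.ones(n), x])
    X_quad = np.column_stack([np.ones(n), x, x * x])
    beta_lin, _, _, _ = np.linalg.lstsq(X_lin, y, rcond=None)
    beta_quad, _, _, _ = np.linalg.lstsq(X_quad, y, rcond=None)
    rss_lin = float(np.sum((y - X_lin @ beta_lin) ** 2))
    rss_quad = float(np.sum((y - X_quad @ beta_quad) ** 2))
    rss_quad = min(rss_quad, rss_lin)  # guard numerical noise on exact fits

    tss = float(np.sum((y - y.mean()) ** 2))
    adj_lin = _adj_r2(rss_lin, tss, n, 1)
    adj_quad = _adj_r2(rss_quad, tss, n, 2)

    df_resid = n - 3
    if rss_quad == 0.0:
        f = np.inf
        p = 0.0
    else:
        f = (rss_lin - rss_quad) / (rss_quad / df_resid)
        p = float(stats.f.sf(f, 1, df_resid))
    return FitComparison(n=n, coef_linear=beta_lin, coef_quadratic=beta_quad,
                         rss_linear=rss_lin, rss_quadratic=rss_quad,
                         adj_r2_linear=adj_lin, adj_r2_quadratic=adj_quad,
                         f_statistic=float(f), improvement_p=p)


@dataclass
class ResampleResult:
    """Outcome of the balanced resampling procedure."""

    replicates: int
    class_size: int          #: size of the smallest attitude class
    n_classes: int
    fraction_significant: float
    n_significant: int
    alpha: float
    seed: int | None


def balanced_resample_test(x, y, replicates: int = 10_000,
                           alpha: float = 0.05,
                           seed: int | np.random.Generator | None = None,
                           ) -> ResampleResult:
    """Quadratic-improvement rate over class-balanced resamples.

    Each replicate draws, without replacement, ``m`` members from every
    attitude class, where ``m`` is the size of the smallest class, giving a
    balanced sample of ``m * n_classes`` rows; the linear/quadratic
    comparison is run and significance of the improvement at ``alpha``
    recorded.  Draws are independent across replicates.  Returns the
    fraction of replicates with a significant improvement.

    Because the balanced design matrix is identical in every replicate (each
    class value repeated ``m`` times), the per-replicate F tests are
    evaluated with precomputed orthonormal design bases, which is
    algebraically identical to refitting each replicate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    classes, counts = np.unique(x, return_counts=True)
    if classes.size < 3:
        raise DegenerateDataError("need at least 3 attitude classes")
    m = int(counts.min())
    if m < 2:
        bad = classes[np.argmin(counts)]
        raise ValidationError(
            f"attitude class {bad:g} has fewer than 2 members")

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    members = [np.nonzero(x == c)[0] for c in classes]
    k = classes.size
    nb = m * k

    # Balanced design shared by all replicates: each class label m times.
    xb = np.repeat(classes, m)
    X_lin = np.column_stack([np.ones(nb), xb])
    X_quad = np.column_stack([np.ones(nb), xb, xb * xb])
    Q_lin, _ = np.linalg.qr(X_lin)
    Q_quad, _ = np.linalg.qr(X_quad)

    # Y: replicates x nb matrix of resampled responses, class blocks in the
    # same order as xb.
    cols = []
    for idx in members:
        # permuted-argsort trick: first m of an independent permutation per
        # replicate = sampling m without replacement.
        keys = rng.random((replicates, idx.size))
        take = np.argpartition(keys, m - 1, axis=1)[:, :m]
        cols.append(y[idx[take]])
    Y = np.concatenate(cols, axis=1)

    tot = np.sum(Y * Y, axis=1)
    fit_lin = Q_lin.T @ Y.T          # 2 x reps
    fit_quad = Q_quad.T @ Y.T        # 3 x reps
    rss_lin = tot - np.sum(fit_lin ** 2, axis=0)
    rss_quad = tot - np.sum(fit_quad ** 2, axis=0)
    rss_quad = np.minimum(rss_quad, rss_lin)

    df_resid = nb - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_lin - rss_quad) / (rss_quad / df_resid)
    p = stats.f.sf(f, 1, df_resid)
    p = np.where(rss_quad <= 0, 0.0, p)
    n_sig = int(np.sum(p < alpha))
    return ResampleResult(
        replicates=replicates, class_size=m, n_classes=k,
        fraction_significant=n_sig / replicates, n_significant=n_sig,
        alpha=alpha,
        seed=seed if isinstance(seed, (int, np.integer)) else None)


def split_correlations(x, y) -> dict:
    """Spearman rho of (x, y) on the x >= 0 and x <= 0 halves.

    Zero-scored respondents belong to both halves, matching the study's
    "greater than or equal" / "less than or equal" split.  Returns a dict
    with keys ``rho_nonneg, p_nonneg, n_nonneg, rho_nonpos, p_nonpos,
    n_nonpos``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    out = {}
    for name, mask in (("nonneg", x >= 0), ("nonpos", x <= 0)):
        if mask.sum() < 3:
            raise ValidationError(f"{name} half has fewer than 3 rows")
        rho, p = spearman(x[mask], y[mask])
        out[f"rho_{name}"] = rho
        out[f"p_{name}"] = p
        out[f"n_{name}"] = int(mask.sum())
    return out
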