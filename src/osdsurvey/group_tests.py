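"""Group comparisons: vaccine-stance heterogeneity, sex ratios, unimodality.

Covers the omnibus/post-hoc machinery the study applies to vaccine groups
(one-way ANOVA with Tukey HSD, Mann-Whitney contrasts between acceptors and
decliners), the Pearson chi-squared test for sex-ratio heterogeneity across
attitude classes, and the Hartigan-Hartigan dip test of unimodality with a
uniform-reference bootstrap p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._dip import dip_pvalue_bootstrap, dip_statistic
from ._exceptions import DegenerateDataError, ValidationError

__all__ = ["GroupComparison", "anova_tukey", "mann_whitney",
           "sex_ratio_heterogeneity", "dip_test"]


@dataclass
class GroupComparison:
    """One-way ANOVA summary with Tukey-adjusted pairwise contrasts."""

    labels: list
    n: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    f_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  #: columns group1, group2, meandiff, p_adj

    def pairwise_p(self, g1, g2) -> float:
        pw = self.pairwise
        row = pw[((pw.group1 == g1) & (pw.group2 == g2))
                 | ((pw.group1 == g2) & (pw.group2 == g1))]
        if row.empty:
            raise KeyError(f"no pair ({g1}, {g2})")
        return float(row.p_adj.iloc[0])


def anova_tukey(groups, response) -> GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    ``groups`` are labels (one per observation), ``response`` the measured
    value.  The omnibus F/P come from the classical one-way ANOVA; pairwise
    p-values are family-adjusted through the studentised-range distribution.
    """
    groups = np.asarray(groups)
    response = np.asarray(response, dtype=float)
    if groups.shape != response.shape or groups.ndim != 1:
        raise ValidationError("groups and response must be equal-length 1-d")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 2:
        bad = labels[np.argmin(counts)]
        raise ValidationError(f"group {bad!r} has fewer than 2 observations")
    samples = [response[groups == g] for g in labels]
    f, p = stats.f_oneway(*samples)

    tk = pairwise_tukeyhsd(response, groups)
    pairwise = pd.DataFrame(tk.summary().data[1:],
                            columns=[c.strip() for c in
                                     tk.summary().data[0]])
    pairwise = pairwise.rename(columns={"p-adj": "p_adj"})
    # statsmodels rounds the displayed p-values; keep the exact ones
    pairwise["p_adj"] = tk.pvalues
    pairwise["meandiff"] = tk.meandiffs
    return GroupComparison(
        labels=list(labels),
        n=counts,
        means=np.array([s.mean() for s in samples]),
        sds=np.array([s.std(ddof=1) for s in samples]),
        f_statistic=float(f), omnibus_p=float(p),
        pairwise=pairwise[["group1", "group2", "meandiff", "p_adj"]])


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test (exact for small samples without ties, normal
    approximation otherwise, as chosen by scipy's ``method='auto'``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def sex_ratio_heterogeneity(attitude_classes, sex) -> tuple[float, int, float]:
    """Pearson chi-squared for heterogeneity of a binary trait across classes.

    Builds the 2 x k contingency table of ``sex`` against the attitude
    classes and applies the Pearson chi-squared test without continuity
    correction, df = k - 1.
    """
    attitude_classes = np.asarray(attitude_classes)
    sex = np.asarray(sex)
    if attitude_classes.shape != sex.shape or sex.ndim != 1:
        raise ValidationError("classes and sex must be equal-length 1-d")
    table = pd.crosstab(pd.Series(sex), pd.Series(attitude_classes))
    if table.shape[0] != 2:
        raise ValidationError(
            f"expected 2 sex categories, found {table.shape[0]}")
    if (table.sum(axis=0) == 0).any():
        raise DegenerateDataError("empty attitude class")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(),
                                            correction=False)
    return float(chi2), int(df), float(p)


def dip_test(values, bootstrap_reps: int = 10_000,
             seed: int | np.random.Generator | None = None,
             ) -> tuple[float, float]:
    """Hartigan-Hartigan dip test of unimodality.

    Returns ``(dip, p)``; the p-value is the proportion of
    ``bootstrap_reps`` uniform samples of the same size whose dip is at
    least the observed one (the uniform being the classical least
    favourable unimodal reference).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 4:
        raise ValidationError("dip test needs at least 4 observations")
    if bootstrap_reps < 1:
        raise ValidationError("bootstrap_reps must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    d = dip_statistic(values)
    p = dip_pvalue_bootstrap(d, values.size, bootstrap_reps, rng)
    return d, p
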