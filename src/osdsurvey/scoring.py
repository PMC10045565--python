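"""Scoring of raw survey items into the derived measures.

A respondent contributes three 5-point attitude items (Trust, Hype, GM; coded
-2..+2 with +2 the most accepting position), six ordinal self-assessed
understanding items, twelve true/false knowledge items, and covariates
(age, religiosity, educational attainment, ten political-identity items, sex,
vaccine status).  Derived per-respondent scores:

subjective
    mean of each understanding item divided by its theoretical maximum
    (maxima 3, 3, 4, 4, 4, 4), range [0, 1].
knowledge
    mean of +1 (correct) / -1 (incorrect) over the twelve items scored
    against an answer key, range [-1, 1]; 0 is the guessing expectation.
osd
    objective-subjective deficit, ``knowledge - subjective``; negative values
    indicate overconfidence (self-assessment exceeding demonstrated
    knowledge).  Range [-2, 1].
z_osd
    sample-relative variant: z-score of knowledge minus z-score of
    subjective, each standardised within the analysed sample.
political
    mean of direction-coded political items divided by 2, range [-1, 1]
    (-1 strongly left, +1 strongly right); missing items are dropped.
attitude strength
    the absolute value of an attitude score, range 0..2.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import DegenerateDataError, ParameterError, ValidationError

__all__ = [
    "DEFAULT_ANSWER_KEY",
    "SUBJECTIVE_ITEM_MAXIMA",
    "POLITICAL_REVERSED_ITEMS",
    "attitude_strength",
    "score_subjective",
    "score_knowledge",
    "compute_osd",
    "compute_z_osd",
    "score_political",
    "cronbach_alpha",
    "score_respondents",
    "robustness_rescore",
]

#: Theoretical maximum of each of the six self-assessed-understanding items.
#: Items 1-2 ask about science news / feeling informed (0-3); items 3-6 rate
#: understanding of the terms DNA, GM, natural selection and PCR (0-4).
SUBJECTIVE_ITEM_MAXIMA = (3, 3, 4, 4, 4, 4)

#: Scientifically correct truth value of each of the twelve knowledge
#: statements, in questionnaire order: all organisms have DNA (T); oxygen
#: comes from plants (T); clones are genetically identical (T); eating GM
#: fruit modifies your genes (F); all radioactivity is human-made (F); the
#: mother's genes determine the child's sex (F); electrons are smaller than
#: atoms (T); only GM tomatoes contain genes (F); dinosaurs and humans share
#: a common ancestor (T); viral variants spread by natural selection (T);
#: COVID-19 is caused by bacteria (F); viruses are smaller than bacteria (T).
DEFAULT_ANSWER_KEY = (
    True, True, True, False, False, False,
    True, False, True, True, False, True,
)

#: 1-based indices of political items where agreement is the right-wing pole.
#: Items 1-6 are left-agreement statements (redistribution, state ownership,
#: ...), items 7-10 right-agreement (tradition, tougher sentencing, ...).
POLITICAL_REVERSED_ITEMS = (7, 8, 9, 10)

#: Knowledge items retained by the biology-only robustness variant
#: (drops item 5, radioactivity, and item 7, electrons vs atoms; 1-based).
BIOLOGY_KNOWLEDGE_ITEMS = (1, 2, 3, 4, 6, 8, 9, 10, 11, 12)

#: Subjective items retained by the genetics-only robustness variant
#: (the four term-specific questions; 1-based).
GENETICS_SUBJECTIVE_ITEMS = (3, 4, 5, 6)


def attitude_strength(score):
    """Attitude strength: absolute deviation of a -2..+2 score from neutral."""
    return np.abs(score)


def score_subjective(subj_items: Sequence[float],
                     maxima: Sequence[int] = SUBJECTIVE_ITEM_MAXIMA) -> float:
    """Self-assessed-understanding score: mean of item/maximum, in [0, 1].

    Parameters
    ----------
    subj_items : sequence of int
        One response per item, each within ``0..maxima[i]``.
    maxima : sequence of int
        Theoretical per-item maxima (not observed maxima).
    """
    items = np.asarray(subj_items, dtype=float)
    maxima = np.asarray(maxima, dtype=float)
    if items.shape != maxima.shape:
        raise ValidationError(
            f"expected {len(maxima)} subjective items, got {items.shape}")
    bad = np.nonzero(~((items >= 0) & (items <= maxima)))[0]
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"subjective item {i + 1} out of scale 0..{int(maxima[i])}: "
            f"{subj_items[i]!r}")
    return float(np.mean(items / maxima))


def score_knowledge(know_items: Sequence[bool],
                    key: Sequence[bool] = DEFAULT_ANSWER_KEY) -> float:
    """Knowledge score: mean of +1 (correct) / -1 (incorrect), in [-1, 1]."""
    answers = np.asarray(know_items, dtype=bool)
    key = np.asarray(key, dtype=bool)
    if answers.shape != key.shape:
        raise ValidationError(
            f"expected {key.size} knowledge answers, got {answers.size}")
    return float(np.mean(np.where(answers == key, 1.0, -1.0)))


def compute_osd(knowledge: float, subjective: float) -> float:
    """Objective-subjective deficit: knowledge minus subjective.

    Negative values indicate overconfidence.  Perfect calibration lies on the
    line of slope one through the origin in the (knowledge, subjective) plane.
    """
    knowledge = np.asarray(knowledge, dtype=float)
    subjective = np.asarray(subjective, dtype=float)
    if np.any((knowledge < -1) | (knowledge > 1)):
        raise ValidationError("knowledge score outside [-1, 1]")
    if np.any((subjective < 0) | (subjective > 1)):
        raise ValidationError("subjective score outside [0, 1]")
    out = knowledge - subjective
    return float(out) if out.ndim == 0 else out


def compute_z_osd(knowledge: Sequence[float],
                  subjective: Sequence[float]) -> np.ndarray:
    """Sample-relative deficit: z(knowledge) - z(subjective), per respondent.

    Standardisation uses the sample mean and (ddof=1) SD of each component;
    the output therefore has sample mean zero.  Raises
    :class:`DegenerateDataError` if either component is constant.
    """
    k = np.asarray(knowledge, dtype=float)
    s = np.asarray(subjective, dtype=float)
    if k.shape != s.shape or k.ndim != 1:
        raise ValidationError("knowledge and subjective must be equal-length 1-d")
    if k.size < 2:
        raise DegenerateDataError("need at least 2 respondents for z-scores")
    sd_k, sd_s = k.std(ddof=1), s.std(ddof=1)
    if sd_k == 0:
        raise DegenerateDataError("knowledge scores are constant; z undefined")
    if sd_s == 0:
        raise DegenerateDataError("subjective scores are constant; z undefined")
    return (k - k.mean()) / sd_k - (s - s.mean()) / sd_s


def score_political(political_items: Sequence[float],
                    reversed_items: Sequence[int] = POLITICAL_REVERSED_ITEMS,
                    ) -> float:
    """Political-identity score in [-1, +1] (-1 left, +1 right) or NaN.

    ``political_items`` are raw agreement values on -2..+2 (+2 = strongly
    agree) with NaN for "do not know" / no response.  Items are direction
    coded so that a more positive coded value is more right wing: agreement
    with items 1-6 is scored negative (they are left-pole statements) and
    agreement with ``reversed_items`` (7-10) positive.  The score is the mean
    of the coded non-missing items divided by 2; all-missing gives NaN.
    """
    items = np.asarray(political_items, dtype=float)
    present = ~np.isnan(items)
    vals = items[present]
    if np.any((vals < -2) | (vals > 2)):
        raise ValidationError("political item outside -2..+2")
    if not present.any():
        return float("nan")
    sign = np.array([1.0 if (i + 1) in set(reversed_items) else -1.0
                     for i in range(items.size)])
    coded = sign * items
    return float(np.nanmean(coded) / 2.0)


def cronbach_alpha(item_matrix) -> tuple[float, np.ndarray]:
    """Cronbach's alpha and the alpha-if-item-dropped vector.

    alpha = k/(k-1) * (1 - sum(var_i)/var(total)), variances with ddof=1 over
    complete rows.  Returns ``(alpha, dropped)`` where ``dropped[i]`` is the
    alpha of the scale with item ``i`` removed.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("need a respondents x items matrix, both >= 2")
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 2:
        raise ValidationError("fewer than 2 complete rows")

    def _alpha(M):
        k = M.shape[1]
        total_var = M.sum(axis=1).var(ddof=1)
        if total_var == 0:
            raise DegenerateDataError("total score has zero variance")
        return k / (k - 1) * (1 - M.var(axis=0, ddof=1).sum() / total_var)

    alpha = _alpha(X)
    if X.shape[1] == 2:
        # a 1-item "scale" has no internal consistency to speak of
        dropped = np.array([np.nan, np.nan])
    else:
        dropped = np.array([_alpha(np.delete(X, j, axis=1))
                            for j in range(X.shape[1])])
    return float(alpha), dropped


# ---------------------------------------------------------------------------
# table-level scoring

_SUBJ_COLS = [f"subj_q{i}" for i in range(1, 7)]
_KNOW_COLS = [f"know_q{i}" for i in range(1, 13)]
_POL_COLS = [f"pol_q{i}" for i in range(1, 11)]
_PASSTHROUGH = ["vaccine_status", "age", "religiosity", "education", "sex"]


def score_respondents(records: pd.DataFrame,
                      key: Sequence[bool] = DEFAULT_ANSWER_KEY,
                      subj_items: Sequence[int] = (1, 2, 3, 4, 5, 6),
                      know_items: Sequence[int] = tuple(range(1, 13)),
                      ) -> pd.DataFrame:
    """Score a table of raw respondent records.

    ``records`` must carry the raw item columns (``trust_raw``, ``hype_raw``,
    ``gm_raw``, ``subj_q1..6``, ``know_q1..12``, ``pol_q1..10``) plus the
    pass-through covariates.  ``subj_items`` / ``know_items`` select (1-based)
    item subsets, used by the robustness variant; the answer key and item
    maxima are subset accordingly.

    Returns a DataFrame with one row per respondent: ``trust``, ``hype``,
    ``gm``, their ``*_strength`` columns, ``subjective``, ``knowledge``,
    ``osd``, ``z_osd``, ``political`` and the covariates.
    """
    required = ["trust_raw", "hype_raw", "gm_raw"] + _SUBJ_COLS + _KNOW_COLS
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")

    key = np.asarray(key, dtype=bool)
    subj_idx = [i - 1 for i in subj_items]
    know_idx = [i - 1 for i in know_items]
    maxima = np.asarray(SUBJECTIVE_ITEM_MAXIMA, dtype=float)[subj_idx]

    subj = records[[_SUBJ_COLS[i] for i in subj_idx]].to_numpy(dtype=float)
    if np.any((subj < 0) | (subj > maxima)):
        raise ValidationError("subjective item out of scale")
    subjective = (subj / maxima).mean(axis=1)

    know = records[[_KNOW_COLS[i] for i in know_idx]].to_numpy(dtype=bool)
    knowledge = np.where(know == key[know_idx], 1.0, -1.0).mean(axis=1)

    out = pd.DataFrame(index=records.index)
    for col in ("trust", "hype", "gm"):
        raw = records[f"{col}_raw"].to_numpy(dtype=float)
        if np.any((raw < -2) | (raw > 2)):
            raise ValidationError(f"{col}_raw outside -2..+2")
        out[col] = raw
        out[f"{col}_strength"] = np.abs(raw)
    out["subjective"] = subjective
    out["knowledge"] = knowledge
    out["osd"] = knowledge - subjective
    out["z_osd"] = compute_z_osd(knowledge, subjective)

    if all(c in records.columns for c in _POL_COLS):
        pol = records[_POL_COLS].to_numpy(dtype=float)
        sign = np.where(np.isin(np.arange(1, 11), POLITICAL_REVERSED_ITEMS),
                        1.0, -1.0)
        if np.any(np.abs(pol) > 2):  # NaN compares False
            raise ValidationError("political item outside -2..+2")
        coded = pol * sign
        n_present = (~np.isnan(pol)).sum(axis=1)
        sums = np.nansum(coded, axis=1)
        out["political"] = np.where(n_present > 0,
                                    sums / np.maximum(n_present, 1) / 2.0,
                                    np.nan)

    for col in _PASSTHROUGH:
        if col in records.columns:
            out[col] = records[col]
    return out


def robustness_rescore(records: pd.DataFrame, mode: str = "full",
                       key: Sequence[bool] = DEFAULT_ANSWER_KEY,
                       ) -> pd.DataFrame:
    """Rescore under an item-subset robustness variant.

    ``mode='full'`` reproduces :func:`score_respondents` exactly.
    ``mode='biology_genetics'`` defines knowledge from the ten biological
    items (dropping the radioactivity and electron items) and subjective
    understanding from the four genetics-specific items, leaving the scoring
    formulas unchanged.
    """
    if mode == "full":
        return score_respondents(records, key=key)
    if mode == "biology_genetics":
        return score_respondents(records, key=key,
                                 subj_items=GENETICS_SUBJECTIVE_ITEMS,
                                 know_items=BIOLOGY_KNOWLEDGE_ITEMS)
    raise ParameterError(f"unknown mode: {mode!r} "
                         "(expected 'full' or 'biology_genetics')")
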