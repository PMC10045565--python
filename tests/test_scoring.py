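"""Scoring of raw survey items into derived measures."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osdsurvey import (DegenerateDataError, ParameterError, ValidationError,
                       attitude_strength, compute_osd, compute_z_osd,
                       cronbach_alpha, robustness_rescore, score_knowledge,
                       score_political, score_respondents, score_subjective)
from osdsurvey.scoring import DEFAULT_ANSWER_KEY, SUBJECTIVE_ITEM_MAXIMA

KEY = list(DEFAULT_ANSWER_KEY)


@pytest.mark.parametrize("items, expected", [
    ((3, 3, 4, 4, 4, 4), 1.0),          # all-maximum identity
    ((0, 0, 0, 0, 0, 0), 0.0),          # all-minimum
    ((3, 0, 2, 2, 2, 2), 0.5),          # mean(1, 0, .5, .5, .5, .5)
])
def test_subjective_hand_examples(items, expected):
    assert score_subjective(items) == pytest.approx(expected, abs=1e-12)


def test_subjective_out_of_scale_names_item():
    with pytest.raises(ValidationError, match="item 2"):
        score_subjective((1, 4, 0, 0, 0, 0))


@pytest.mark.parametrize("n_correct, expected", [(12, 1.0), (6, 0.0),
                                                 (9, 0.5), (0, -1.0)])
def test_knowledge_hand_examples(n_correct, expected):
    answers = [KEY[i] if i < n_correct else not KEY[i] for i in range(12)]
    assert score_knowledge(answers) == pytest.approx(expected, abs=1e-12)


def test_knowledge_wrong_length():
    with pytest.raises(ValidationError):
        score_knowledge([True] * 11)


@pytest.mark.parametrize("k, s, expected", [
    (0.5, 0.75, -0.25),
    (1.0, 1.0, 0.0),      # perfect calibration line
    (-1.0, 1.0, -2.0),    # extreme overconfidence bound
])
def test_osd_hand_examples(k, s, expected):
    assert compute_osd(k, s) == pytest.approx(expected, abs=1e-12)


def test_z_osd_two_point_hand_case():
    z = compute_z_osd([1.0, -1.0], [1.0, 0.0])
    assert z == pytest.approx([0.0, 0.0], abs=1e-12)


def test_z_osd_degenerate_knowledge():
    with pytest.raises(DegenerateDataError):
        compute_z_osd([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])


@given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0, 1)),
                min_size=3, max_size=40))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_z_osd_mean_zero(pairs):
    k = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    # near-constant inputs make the standardisation ill-conditioned
    if k.std() < 1e-2 or s.std() < 1e-2:
        return
    assert abs(compute_z_osd(k, s).mean()) < 1e-10


@pytest.mark.parametrize("items, expected", [
    ([2] * 6 + [-2] * 4, -1.0),                   # maximally left pattern
    ([np.nan] * 10, np.nan),                      # all missing
    ([0] * 6 + [2] * 4, 0.4),                     # mean 0.8 halved
])
def test_political_hand_examples(items, expected):
    got = score_political(items)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_political_partial_missing_uses_observed_items():
    items = [2, np.nan, np.nan, np.nan, np.nan, np.nan,
             np.nan, np.nan, np.nan, -2]
    # item 1 codes to -2, item 10 codes to -2: mean -2, halved -> -1
    assert score_political(items) == pytest.approx(-1.0)


@pytest.mark.parametrize("score, expected", [(-2, 2), (0, 0), (1, 1)])
def test_attitude_strength(score, expected):
    assert attitude_strength(score) == expected


@given(st.lists(st.integers(0, 4), min_size=4, max_size=4))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_subjective_item_order_invariance_within_scale(tail):
    """Permuting responses among items that share a scale maximum leaves
    the score unchanged."""
    head = [2, 1]
    base = score_subjective(head + tail)
    assert score_subjective(head[::-1] + tail) == pytest.approx(base)
    assert score_subjective(head + tail[::-1]) == pytest.approx(base)


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        col = np.random.default_rng(0).normal(size=50)
        alpha, dropped = cronbach_alpha(np.column_stack([col] * 4))
        assert alpha == pytest.approx(1.0, abs=1e-12)
        assert dropped == pytest.approx(np.ones(4), abs=1e-12)

    def test_independent_items_alpha_near_zero(self, rng):
        X = rng.normal(size=(10_000, 2))
        alpha, _ = cronbach_alpha(X)
        assert abs(alpha) < 0.07

    def test_matches_direct_formula_and_pingouin(self, rng):
        X = rng.normal(size=(40, 5)) + rng.normal(size=(40, 1))
        alpha, dropped = cronbach_alpha(X)
        k = X.shape[1]
        direct = k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum()
                                / X.sum(axis=1).var(ddof=1))
        assert alpha == pytest.approx(direct, abs=1e-12)
        assert alpha == pytest.approx(
            pg.cronbach_alpha(data=pd.DataFrame(X))[0], abs=1e-10)
        assert dropped.shape == (5,)

    def test_zero_variance_degenerate(self):
        X = np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]])
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(X)


class TestTableScoring:
    def test_scored_columns_and_identities(self, small_scored):
        s = small_scored
        assert ((s.subjective >= 0) & (s.subjective <= 1)).all()
        assert ((s.knowledge >= -1) & (s.knowledge <= 1)).all()
        assert ((s.osd >= -2) & (s.osd <= 1)).all()
        assert np.allclose(s.osd, s.knowledge - s.subjective)
        assert np.allclose(s.trust_strength, s.trust.abs())
        assert abs(s.z_osd.mean()) < 1e-10

    def test_row_scores_match_scalar_functions(self, small_records):
        records, _ = small_records
        scored = score_respondents(records)
        row = records.iloc[17]
        subj = score_subjective([row[f"subj_q{i}"] for i in range(1, 7)])
        know = score_knowledge([row[f"know_q{i}"] for i in range(1, 13)])
        pol = score_political([row[f"pol_q{i}"] for i in range(1, 11)])
        assert scored.subjective.iloc[17] == pytest.approx(subj)
        assert scored.knowledge.iloc[17] == pytest.approx(know)
        got_pol = scored.political.iloc[17]
        if np.isnan(pol):
            assert np.isnan(got_pol)
        else:
            assert got_pol == pytest.approx(pol)

    def test_robustness_full_mode_is_identity(self, small_records):
        records, _ = small_records
        full = robustness_rescore(records, "full")
        base = score_respondents(records)
        pd.testing.assert_frame_equal(full, base)

    def test_robustness_biology_genetics_subsets(self, small_records):
        records, _ = small_records
        alt = robustness_rescore(records, "biology_genetics")
        row = records.iloc[3]
        # knowledge from the ten biological items (5 and 7 dropped)
        keep = [1, 2, 3, 4, 6, 8, 9, 10, 11, 12]
        know = np.mean([1.0 if row[f"know_q{i}"] == KEY[i - 1] else -1.0
                        for i in keep])
        subj = np.mean([row[f"subj_q{i}"] / SUBJECTIVE_ITEM_MAXIMA[i - 1]
                        for i in (3, 4, 5, 6)])
        assert alt.knowledge.iloc[3] == pytest.approx(know)
        assert alt.subjective.iloc[3] == pytest.approx(subj)

    def test_robustness_all_correct_biology(self):
        rec = pd.DataFrame({
            "trust_raw": [0], "hype_raw": [0], "gm_raw": [0],
            **{f"subj_q{i}": [2] for i in range(1, 7)},
            **{f"know_q{i}": [KEY[i - 1]] for i in range(1, 13)},
        })
        rec2 = pd.concat([rec, rec], ignore_index=True)
        rec2.loc[1, "know_q1"] = not KEY[0]
        rec2.loc[1, "subj_q3"] = 0  # keep z-scores well defined
        alt = robustness_rescore(rec2, "biology_genetics")
        assert alt.knowledge.iloc[0] == 1.0

    def test_unknown_mode(self, small_records):
        records, _ = small_records
        with pytest.raises(ParameterError):
            robustness_rescore(records, "biology_only")
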