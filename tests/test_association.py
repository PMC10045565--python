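"""Rank correlations, partial correlations and the study-style tables."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from osdsurvey import (DegenerateDataError, ValidationError,
                       build_correlation_table, partial_spearman, spearman)
from _oracles import partial_corr_first_order


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([0.5, 1.2, 3.0, 7.7, 9.0])
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_rank_formula(self):
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8, abs=1e-12)

    def test_independent_near_zero(self, rng):
        rho, _ = spearman(rng.random(10_000), rng.random(10_000))
        assert abs(rho) < 0.03

    def test_constant_degenerate(self):
        with pytest.raises(DegenerateDataError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_empty_controls_reduces_to_plain(self, rng):
        x, y = rng.random(60), rng.random(60)
        assert partial_spearman(x, y)[0] == pytest.approx(
            spearman(x, y)[0], abs=1e-12)

    def test_first_order_closed_form(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            z = rng.normal(size=n)
            x = z + rng.normal(size=n)
            y = z + rng.normal(size=n)
            r, _ = partial_spearman(x, y, [z])
            assert r == pytest.approx(partial_corr_first_order(x, y, z),
                                      abs=1e-10)

    def test_confounder_removed(self, rng):
        n = 5000
        z = rng.normal(size=n)
        x = z + 0.3 * rng.normal(size=n)
        y = z + 0.3 * rng.normal(size=n)
        plain, _ = spearman(x, y)
        partial, _ = partial_spearman(x, y, [z])
        assert plain > 0.7
        assert abs(partial) < 0.1

    def test_matches_pingouin_with_two_controls(self, rng):
        df = pd.DataFrame(rng.normal(size=(150, 4)), columns=list("xyzw"))
        r, p = partial_spearman(df.x, df.y, [df.z, df.w])
        ref = pg.partial_corr(df, x="x", y="y", covar=["z", "w"],
                              method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            partial_spearman([1, 2, 3], [2, 1, 3], [[1, 5, 2]])


class TestCorrelationTable:
    def test_two_variable_table_upper_equals_lower(self, small_scored):
        tab = build_correlation_table(small_scored,
                                      ["subjective", "knowledge"])
        assert tab.cell("subjective", "knowledge") == pytest.approx(
            tab.cell("knowledge", "subjective"), abs=1e-12)

    def test_cells_match_recomputation(self, small_scored):
        variables = ["education", "age", "subjective", "osd"]
        tab = build_correlation_table(small_scored, variables)
        data = small_scored[variables].dropna()
        arrays = {v: data[v].to_numpy(float) for v in variables}
        # upper triangle: plain rho; lower: partial given the others
        r_plain, p_plain = spearman(arrays["age"], arrays["osd"])
        assert tab.cell("age", "osd") == pytest.approx(r_plain, abs=1e-12)
        ctrl = [arrays["education"], arrays["age"]]
        r_part, p_part = partial_spearman(arrays["osd"], arrays["subjective"],
                                          ctrl)
        assert tab.cell("osd", "subjective") == pytest.approx(r_part,
                                                              abs=1e-12)
        assert bool(tab.significant.loc["age", "osd"]) == (p_plain < 0.05)
        assert tab.n == len(data)

    def test_listwise_deletion_drops_missing_political(self, small_scored):
        scored = small_scored.copy()
        scored.loc[scored.index[:25], "political"] = np.nan
        tab = build_correlation_table(scored, ["political", "osd", "age"])
        assert tab.n == len(scored) - 25

    def test_label_permutation_consistency(self, small_scored):
        v1 = ["education", "age", "osd"]
        v2 = ["age", "osd", "education"]
        t1 = build_correlation_table(small_scored, v1)
        t2 = build_correlation_table(small_scored, v2)
        # plain-rho (upper-triangle) cells follow their labels regardless
        # of the listing order
        assert t1.cell("education", "age") == pytest.approx(
            t2.cell("age", "education"), abs=1e-12)
        assert t1.cell("age", "osd") == pytest.approx(
            t2.cell("age", "osd"), abs=1e-12)
        # partials control the same remaining set, so they agree too
        assert t1.cell("osd", "age") == pytest.approx(
            t2.cell("osd", "age"), abs=1e-12)

    def test_missing_variable_raises(self, small_scored):
        with pytest.raises(ValidationError):
            build_correlation_table(small_scored, ["osd", "nope"])

    def test_formatted_flags(self, small_scored):
        tab = build_correlation_table(small_scored, ["subjective",
                                                     "knowledge", "age"])
        rendered = tab.formatted()
        cell = rendered.loc["subjective", "knowledge"]
        assert cell.endswith("*") == bool(
            tab.significant.loc["subjective", "knowledge"])
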