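"""ANOVA/Tukey, Mann-Whitney, chi-squared and dip tests."""

import numpy as np
import pytest

from osdsurvey import (ValidationError, anova_tukey, dip_statistic,
                       dip_test, mann_whitney, sex_ratio_heterogeneity)
from _oracles import chi2_direct, dip_lp_oracle, mann_whitney_enum


class TestAnovaTukey:
    def test_null_omnibus_calibration(self, rng):
        groups = np.repeat(["a", "b", "c", "d"], 25)
        hits = 0
        reps = 400
        for _ in range(reps):
            comp = anova_tukey(groups, rng.normal(size=100))
            hits += comp.omnibus_p < 0.05
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_shifted_group_detected(self, rng):
        groups = np.repeat(["a", "b", "c"], 100)
        y = rng.normal(size=300)
        y[200:] += 5.0
        comp = anova_tukey(groups, y)
        assert comp.pairwise_p("a", "c") < 1e-6
        assert comp.pairwise_p("b", "c") < 1e-6
        assert comp.pairwise_p("a", "b") > 0.05

    def test_two_group_reduction_matches_omnibus(self, rng):
        groups = np.repeat(["a", "b"], 30)
        y = rng.normal(size=60)
        y[30:] += 0.7
        comp = anova_tukey(groups, y)
        assert comp.pairwise_p("a", "b") == pytest.approx(comp.omnibus_p,
                                                          rel=1e-6)

    def test_group_summaries(self, rng):
        groups = np.repeat(["a", "b", "c"], 40)
        y = rng.normal(size=120)
        comp = anova_tukey(groups, y)
        assert len(comp.pairwise) == 3  # k(k-1)/2
        assert comp.means[0] == pytest.approx(y[:40].mean())


class TestMannWhitney:
    def test_matches_enumeration(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(3, 8))
            n2 = int(rng.integers(3, 8))
            x = rng.normal(size=n1)
            y = rng.normal(0.8, 1, size=n2)
            u, p = mann_whitney(x, y)
            u_ref, p_ref = mann_whitney_enum(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_fully_separated_extreme_u(self, rng):
        x = rng.uniform(0, 1, 10)
        y = rng.uniform(10, 11, 10)
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p < 1e-3

    def test_identical_samples(self):
        x = np.arange(10.0)
        u, p = mann_whitney(x, x.copy())
        assert p > 0.9

    def test_empty_group(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestSexRatio:
    def test_equal_split_zero(self):
        classes = np.repeat([-2, -1, 0, 1, 2], 10)
        sex = np.tile(["m", "f"], 25)
        chi2, df, p = sex_ratio_heterogeneity(classes, sex)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 4

    def test_hand_two_by_two(self):
        # table (10,20 / 20,10): chi2 = 100/15
        classes = np.repeat([0, 1], 30)
        sex = np.array(["m"] * 10 + ["f"] * 20 + ["m"] * 20 + ["f"] * 10)
        chi2, df, p = sex_ratio_heterogeneity(classes, sex)
        assert chi2 == pytest.approx(100 / 15, abs=1e-10)
        assert df == 1

    def test_matches_direct_sum(self, rng):
        for _ in range(20):
            table = rng.integers(5, 40, size=(2, 5))
            classes = np.repeat(np.tile(np.arange(5), 2), table.ravel())
            sex = np.repeat(np.repeat(["m", "f"], 5), table.ravel())
            chi2, df, _ = sex_ratio_heterogeneity(classes, sex)
            assert chi2 == pytest.approx(chi2_direct(table), abs=1e-9)
            assert df == 4


class TestDip:
    def test_known_values(self):
        assert dip_statistic([0] * 50 + [1] * 50) == pytest.approx(0.25)
        assert dip_statistic(np.arange(10)) == pytest.approx(0.05)
        assert dip_statistic([3.0]) == 0.0
        assert dip_statistic([1.0, 2.0]) == pytest.approx(0.25)

    def test_bounds(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 200))
            v = rng.normal(size=n)
            d = dip_statistic(v)
            assert 1 / (2 * n) - 1e-12 <= d <= 0.25 + 1e-12

    def test_matches_lp_oracle(self, rng):
        """The hull-based computation equals direct minimisation of the
        defining sup-distance problem."""
        cases = []
        for k in range(12):
            n = int(rng.integers(4, 11))
            if k % 3 == 0:
                cases.append(rng.random(n))
            elif k % 3 == 1:
                cases.append(rng.integers(0, 4, n).astype(float))
            else:
                cases.append(np.concatenate([rng.normal(-2, 0.3, n),
                                             rng.normal(2, 0.3, n)]))
        for v in cases:
            assert dip_statistic(v) == pytest.approx(dip_lp_oracle(v),
                                                     abs=3e-4)

    def test_uniform_calibration_median_p(self, rng):
        ps = []
        for _ in range(30):
            d, p = dip_test(rng.random(80), bootstrap_reps=150, seed=rng)
            ps.append(p)
        assert 0.2 < np.median(ps) < 0.8

    def test_bimodal_significant(self, rng):
        v = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])
        d, p = dip_test(v, bootstrap_reps=300, seed=0)
        assert p < 0.01
        assert d > 0.1

    def test_needs_four_observations(self):
        with pytest.raises(ValidationError):
            dip_test([1.0, 2.0, 3.0])

    def test_seeded_reproducibility(self):
        v = np.random.default_rng(3).normal(size=60)
        r1 = dip_test(v, bootstrap_reps=100, seed=9)
        r2 = dip_test(v, bootstrap_reps=100, seed=9)
        assert r1 == r2
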