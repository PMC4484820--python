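"""Exact tests, group comparison and bootstrap against independent oracles."""
import numpy as np
import pandas as pd
import pytest

import roctree as rt

from .conftest import make_frame
from .oracles import (binom_lower_tail, binom_upper_tail, chi2_closed_form,
                      fisher_two_sided_oracle)


class TestBinomialTails:
    def test_published_replication_example(self):
        # 9/13 correct in the new cohort vs 90% reference accuracy
        assert rt.binom_test_vs_reference(9, 13, 0.90) == pytest.approx(
            0.034, abs=5e-4)

    def test_full_success_lower_tail_is_one(self):
        assert rt.binom_test_vs_reference(13, 13, 0.9) == 1.0

    def test_matches_pmf_summation(self):
        assert rt.binom_test_vs_reference(3, 10, 0.5) == pytest.approx(
            binom_lower_tail(3, 10, 0.5), rel=1e-12)

    def test_exactness_against_log_factorial_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n = int(rng.integers(1, 201))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            assert rt.binom_test_vs_reference(k, n, p) == pytest.approx(
                binom_lower_tail(k, n, p), rel=1e-12)
            assert rt.chance_test(k, n, 1 - p) == pytest.approx(
                binom_upper_tail(k, n, p), rel=1e-12)

    def test_monotonic_in_successes(self):
        ps = [rt.binom_test_vs_reference(k, 20, 0.8) for k in range(21)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))
        qs = [rt.chance_test(k, 20, 0.35) for k in range(1, 21)]
        assert all(a >= b - 1e-15 for a, b in zip(qs, qs[1:]))

    def test_chance_test_published_nodes(self):
        # the 26/29 test-cohort node and the pooled 57/67 selection both
        # beat the 35% literature remission rate decisively
        p_test = rt.chance_test(26, 29, 0.35)
        assert p_test == pytest.approx(binom_upper_tail(26, 29, 0.65), rel=1e-12)
        assert p_test < 0.01
        p_pooled = rt.chance_test(57, 67, 0.35)
        assert p_pooled < 0.001

    def test_chance_tail_vanishes_as_chance_rate_grows(self):
        # higher assumed remission under chance means observing many
        # non-remitters among the selected is ever less likely
        ps = [rt.chance_test(8, 10, r) for r in (0.2, 0.35, 0.5, 0.65, 0.8, 0.99)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rt.binom_test_vs_reference(3, 10, 1.0)
        with pytest.raises(ValueError):
            rt.chance_test(11, 10)


class TestAssociation:
    def test_chi2_melancholia_table(self):
        stat, p = rt.chi2_2x2(((6, 51), (12, 34)))
        assert stat == pytest.approx(4.27, abs=5e-3)
        assert p == pytest.approx(0.039, abs=5e-4)

    def test_chi2_identical_rows_zero(self):
        stat, p = rt.chi2_2x2(((7, 13), (7, 13)))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi2_matches_closed_form(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            t = rng.integers(1, 40, size=(2, 2))
            stat, _ = rt.chi2_2x2(t)
            assert stat == pytest.approx(chi2_closed_form(t), rel=1e-12)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            rt.chi2_2x2(((0, 0), (3, 4)))

    def test_fisher_canonical_values(self):
        assert rt.fisher_exact_2x2(((2, 0), (0, 2))) == pytest.approx(1 / 3)
        assert rt.fisher_exact_2x2(((5, 5), (5, 5))) == 1.0

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        tables = [((18, 2), (17, 15))] + [
            tuple(map(tuple, rng.integers(0, 25, size=(2, 2))))
            for _ in range(40)]
        for t in tables:
            if sum(map(sum, t)) == 0:
                continue
            assert rt.fisher_exact_2x2(t) == pytest.approx(
                fisher_two_sided_oracle(t), rel=1e-9)


def _vol_rules():
    return rt.extract_actionable_rules(rt.published_volumetric_tree())


class TestBootstrap:
    def test_full_pool_draw_degenerates(self, paper_cohort):
        res = rt.bootstrap_cv(paper_cohort, rules=_vol_rules(), n_iter=5,
                              m=len(paper_cohort), seed=3)
        assert res.sd_specificity == 0.0
        pooled = rt.apply_rules(_vol_rules(), paper_cohort)
        assert res.mean_specificity == pytest.approx(pooled.accuracy)

    def test_seed_determinism(self, paper_cohort):
        a = rt.bootstrap_cv(paper_cohort, rules=_vol_rules(), n_iter=50,
                            m=100, seed=7)
        b = rt.bootstrap_cv(paper_cohort, rules=_vol_rules(), n_iter=50,
                            m=100, seed=7)
        np.testing.assert_array_equal(a.specificity, b.specificity)
        np.testing.assert_array_equal(a.coverage, b.coverage)

    def test_summaries_recomputable_from_iterations(self, paper_cohort):
        res = rt.bootstrap_cv(paper_cohort, rules=_vol_rules(), n_iter=100,
                              m=100, seed=1)
        assert res.mean_specificity == pytest.approx(
            np.nanmean(res.specificity))
        assert res.sd_specificity == pytest.approx(
            np.nanstd(res.specificity, ddof=1))
        assert np.nanmin(res.specificity) >= 0.0
        assert np.nanmax(res.specificity) <= 1.0

    def test_empty_selection_iterations_counted(self):
        # a rule that matches exactly one subject: most size-3 subsamples
        # select nobody and must be excluded from the mean, not zeroed
        n = 30
        x = np.full(n, 5.0)
        x[0] = 50.0
        df = make_frame({"x": x.tolist()},
                        [False] + [True, False] * 14 + [False])
        rule = rt.Rule(conditions=(rt.Condition("x", 40.0, "ge"),))
        res = rt.bootstrap_cv(df, rules=[rule], n_iter=200, m=3, seed=0)
        assert 0 < res.n_undefined_specificity < 200
        assert np.isfinite(res.mean_specificity)

    def test_oversized_subsample_rejected(self, paper_cohort):
        with pytest.raises(ValueError):
            rt.bootstrap_cv(paper_cohort, rules=_vol_rules(),
                            m=len(paper_cohort) + 1)

    def test_no_rules_rejected(self, paper_cohort):
        with pytest.raises(ValueError):
            rt.bootstrap_cv(paper_cohort, rules=[])


class TestCompareGroups:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"age": rng.normal(35, 10, 40),
                           "melancholic": rng.random(40) < 0.3})
        out = rt.compare_groups(df, df.copy(), ["age", "melancholic"])
        assert out.loc["age", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["melancholic", "p"] == pytest.approx(1.0)

    def test_melancholia_fixture_reproduces_published_p(self):
        a = pd.DataFrame({"melancholic": [True] * 6 + [False] * 51})
        b = pd.DataFrame({"melancholic": [True] * 12 + [False] * 34})
        out = rt.compare_groups(a, b, ["melancholic"])
        assert out.loc["melancholic", "statistic"] == pytest.approx(4.27, abs=5e-3)
        assert out.loc["melancholic", "p"] == pytest.approx(0.039, abs=5e-4)

    def test_type_one_error_near_nominal(self):
        """Null simulation: the t-test rejects at about its nominal rate."""
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, 25)
            b = rng.normal(0, 1, 25)
            a_df = pd.DataFrame({"v": a})
            b_df = pd.DataFrame({"v": b})
            out = rt.compare_groups(a_df, b_df, ["v"])
            rejections += out.loc["v", "p"] < 0.05
        rate = rejections / reps
        assert 0.03 < rate < 0.07

    def test_missing_variable_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(KeyError):
            rt.compare_groups(a, a, ["y"])


class TestEvaluateSelection:
    def test_counts_and_tests_attached(self, validation_cohort):
        rules = _vol_rules()
        sel = rt.apply_rules(rules, validation_cohort)
        ev = rt.evaluate_selection(sel, validation_cohort, rule_id="vol",
                                   cohort="validation",
                                   reference_accuracy=26 / 29)
        assert (ev.n_selected, ev.n_correct) == (38, 31)
        assert ev.accuracy == pytest.approx(31 / 38)
        assert ev.coverage == pytest.approx(31 / 63)
        assert ev.p_vs_reference > 0.05   # the volumetric rule replicates
        assert ev.p_vs_chance < 0.05
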