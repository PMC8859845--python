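import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import meshtrends as mt
from conftest import make_article


def pearson_chi2_2x2(x1, n1, x2, n2, yates):
    """Independent oracle: explicit observed/expected 2x2 Pearson chi-square."""
    obs = [[x1, n1 - x1], [x2, n2 - x2]]
    col = [x1 + x2, (n1 - x1) + (n2 - x2)]
    row = [n1, n2]
    total = n1 + n2
    chi2 = 0.0
    correction = min(0.5, abs(obs[0][0] - row[0] * col[0] / total)) if yates else 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            chi2 += (abs(obs[i][j] - e) - correction) ** 2 / e
    return chi2


class TestTwoProportionTest:
    def test_small_sample_difference_not_significant(self):
        res = mt.two_proportion_test(9, 10, 7, 10)
        assert res.chi2 == pytest.approx(0.3125)
        assert res.p == pytest.approx(0.576, abs=1e-3)
        assert res.p > 0.05

    def test_same_ratio_at_ten_times_the_size_is_significant(self):
        res = mt.two_proportion_test(90, 100, 70, 100)
        assert res.chi2 == pytest.approx(11.28, abs=0.01)
        assert res.p < 0.05

    def test_identical_proportions_give_p_one_without_correction(self):
        res = mt.two_proportion_test(5, 10, 5, 10, continuity=False)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("x1,x2,n", [(0, 0, 10), (10, 10, 10)])
    def test_degenerate_pooled_proportion_flagged(self, x1, x2, n):
        res = mt.two_proportion_test(x1, n, x2, n)
        assert res.degenerate and res.p == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            mt.two_proportion_test(11, 10, 1, 10)
        with pytest.raises(ValueError):
            mt.two_proportion_test(1, 0, 1, 10)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(2, 40, size=2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            a = mt.two_proportion_test(x1, n1, x2, n2)
            b = mt.two_proportion_test(x2, n2, x1, n1)
            assert a.chi2 == pytest.approx(b.chi2)
            assert a.p == pytest.approx(b.p)

    def test_uncorrected_equals_squared_two_sample_z(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 100:
            n1, n2 = rng.integers(2, 60, size=2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            total = x1 + x2
            if total == 0 or total == n1 + n2:
                continue
            pool = total / (n1 + n2)
            z = (x1 / n1 - x2 / n2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
            res = mt.two_proportion_test(x1, n1, x2, n2, continuity=False)
            assert res.chi2 == pytest.approx(z**2, rel=1e-10)
            checked += 1

    def test_matches_explicit_table_oracle_on_exhaustive_grid(self):
        """Brute-force Pearson chi-square on all tables with n1, n2 <= 12."""
        for n1 in range(1, 13):
            for n2 in range(1, 13):
                for x1 in range(n1 + 1):
                    for x2 in range(n2 + 1):
                        if x1 + x2 in (0, n1 + n2):
                            continue
                        for yates in (False, True):
                            got = mt.two_proportion_test(x1, n1, x2, n2, continuity=yates)
                            want = pearson_chi2_2x2(x1, n1, x2, n2, yates)
                            assert got.chi2 == pytest.approx(want, rel=1e-12), (
                                x1, n1, x2, n2, yates,
                            )

    def test_uncorrected_matches_scipy_contingency(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 50:
            n1, n2 = rng.integers(5, 80, size=2)
            x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
            got = mt.two_proportion_test(x1, n1, x2, n2, continuity=False)
            ref = stats.chi2_contingency(
                [[x1, n1 - x1], [x2, n2 - x2]], correction=False
            )
            assert got.chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert got.p == pytest.approx(ref.pvalue, rel=1e-10)
            checked += 1


class TestBHAdjust:
    def test_step_up_worked_example(self):
        assert mt.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ties_and_singleton(self):
        assert mt.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert mt.bh_adjust([0.07]) == pytest.approx([0.07])

    def test_matches_hand_step_up(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        hand = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        expected = np.empty(m)
        expected[order] = hand
        assert mt.bh_adjust(p) == pytest.approx(expected)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=40)
        assert (mt.bh_adjust(p) >= p - 1e-15).all()

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=12),
        st.data(),
    )
    def test_lowering_a_pvalue_never_loses_rejections(self, pvals, data):
        alpha = 0.05
        base = int((mt.bh_adjust(pvals) <= alpha).sum())
        i = data.draw(st.integers(min_value=0, max_value=len(pvals) - 1))
        lowered = list(pvals)
        lowered[i] = data.draw(st.floats(min_value=0.0, max_value=pvals[i]))
        assert int((mt.bh_adjust(lowered) <= alpha).sum()) >= base

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mt.bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            mt.bh_adjust([])


class TestFisherAggregate:
    def test_single_p_is_identity(self):
        res = mt.fisher_aggregate([0.05])
        assert res.df == 2
        assert res.p == pytest.approx(0.05)
        # df=2 closed form exp(-chi2/2)
        assert res.p == pytest.approx(math.exp(-res.chi2 / 2))

    def test_no_evidence_case(self):
        res = mt.fisher_aggregate([1.0, 1.0])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_p_closed_form(self):
        res = mt.fisher_aggregate([0.1, 0.1])
        assert res.chi2 == pytest.approx(9.2103, abs=1e-4)
        assert res.df == 4
        # df=4 survival (1 + x/2) exp(-x/2)
        assert res.p == pytest.approx((1 + res.chi2 / 2) * math.exp(-res.chi2 / 2))
        assert res.p == pytest.approx(0.0561, abs=1e-4)

    @pytest.mark.parametrize("p", [0.01, 0.05, 0.2])
    def test_replicated_evidence_accumulates(self, p):
        """Repeated small p-values compound: aggregated p strictly decreases
        with the number of copies (valid for p below ~e^-1, where each copy
        contributes more than the null-expected chi-square mass)."""
        aggregated = [mt.fisher_aggregate([p] * k).p for k in range(1, 6)]
        assert all(a > b for a, b in zip(aggregated, aggregated[1:]))

    def test_weak_pvalues_do_not_compound(self):
        """Copies of a large p carry no aggregate evidence: p drifts to 1."""
        aggregated = [mt.fisher_aggregate([0.9] * k).p for k in (1, 5, 20)]
        assert all(a < b for a, b in zip(aggregated, aggregated[1:]))

    def test_zero_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            res = mt.fisher_aggregate([0.0, 0.5])
        assert 0 < res.p < 1e-100
        assert any("clamping" in r.message for r in caplog.records)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mt.fisher_aggregate([])


class TestLogRatio:
    def test_four_fold_control_enrichment(self):
        assert mt.log_ratio(0.005, 0.020) == pytest.approx(-2.0)

    def test_equal_frequencies_give_zero(self):
        assert mt.log_ratio(0.03, 0.03) == 0.0

    def test_zero_control_returns_sentinel(self):
        assert mt.log_ratio(0.007, 0.0) == 10.0
        assert mt.log_ratio(0.007, 0.0, sentinel=99.0) == 99.0

    def test_zero_target_is_minus_infinity(self):
        assert mt.log_ratio(0.0, 0.02) == float("-inf")

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            mt.log_ratio(0.0, 0.0)

    @given(
        st.floats(min_value=1e-6, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_antisymmetry(self, a, b):
        assert mt.log_ratio(a, b) == pytest.approx(-mt.log_ratio(b, a), abs=1e-12)


class TestCompareAllTerms:
    def test_null_term_near_one_enriched_term_minus_two(self, small_panel):
        comps = {c.term: c for c in mt.compare_all_terms(small_panel)}
        null = comps["alpha"]
        assert null.fisher_p > 0.5
        assert null.logratio == 0.0
        assert null.direction == 0
        enriched = comps["beta"]  # 8/10 target vs 2/10 control, every year
        assert enriched.logratio == pytest.approx(2.0)
        assert enriched.direction == 1
        assert enriched.fisher_df == 2 * 3
        for year in ("2015", "2016", "2017"):
            assert enriched.per_year_logratio[year] == pytest.approx(2.0)
            assert enriched.per_year_q[year] >= enriched.per_year_p[year]

    def test_four_fold_control_enriched_panel(self):
        target, control, pmid = [], [], 1
        for year in (2016, 2017):
            for i in range(20):
                target.append(make_article(pmid, year, ["anchor"] + (["et"] if i < 2 else [])))
                pmid += 1
                control.append(make_article(pmid, year, ["anchor"] + (["et"] if i < 8 else [])))
                pmid += 1
        t, c = mt.build_samples(target, control)
        comps = {c_.term: c_ for c_ in mt.compare_all_terms(mt.build_panel(t, c))}
        assert comps["et"].logratio == pytest.approx(-2.0)

    def test_empty_years_excluded_from_per_year_tests(self):
        target = [make_article(1, 2016, ["X"]), make_article(2, 2016, ["X"])]
        control = [
            make_article(3, 2016, ["X"]),
            make_article(4, 2017, ["X"]),
            make_article(5, 2017, ["X"]),
        ]
        t, c = mt.build_samples(target, control)
        panel = mt.build_panel(t, c, years=["2016", "2017"])
        (comp,) = mt.compare_all_terms(panel)
        assert list(comp.per_year_p) == ["2016"]
        assert comp.fisher_df == 2

    def test_type_one_error_calibration_on_null_panel(self):
        """200 null terms, binomial counts: raw uncorrected p<0.05 at ~5%."""
        rng = np.random.default_rng(7)
        n, years = 500, ["2014", "2015", "2016", "2017", "2018"]
        import pandas as pd

        counts = {
            s: pd.DataFrame(
                rng.binomial(n, 0.1, size=(200, len(years))),
                index=[f"t{i}" for i in range(200)],
                columns=years,
            )
            for s in ("target", "control")
        }
        sizes = {s: pd.Series(n, index=years) for s in ("target", "control")}
        panel = mt.FrequencyPanel(counts=counts, sizes=sizes)
        comps = mt.compare_all_terms(panel, continuity=False)
        pvals = np.array([p for c in comps for p in c.per_year_p.values()])
        frac = float((pvals < 0.05).mean())
        se = math.sqrt(0.05 * 0.95 / pvals.size)
        assert abs(frac - 0.05) < 3 * se
        # the Yates-corrected test is conservative, never anticonservative
        comps_corr = mt.compare_all_terms(panel, continuity=True)
        pvals_corr = np.array([p for c in comps_corr for p in c.per_year_p.values()])
        assert (pvals_corr < 0.05).mean() <= 0.05 + 3 * se
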