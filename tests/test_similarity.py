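"""Tier-1/2/3 similarity procedures against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from biosimilarity import (
    SimilarityConfig,
    generate_lots,
    quality_range,
    run_similarity,
    tier3_compare,
    tost_equivalence,
)
from biosimilarity.adalimumab import glycan_tiers, hm_shift_scenario
from biosimilarity.criticality import TierAssignment
from biosimilarity.lots import LotMeasurement, LotTable
from biosimilarity.similarity import (
    DegenerateSpreadError,
    InsufficientLotsError,
)


def welch_ci(test, ref, alpha):
    """First-principles Welch interval, written independently of the
    implementation: plain formulas straight from the t construction."""
    t, r = np.asarray(test, float), np.asarray(ref, float)
    v1, v2 = t.var(ddof=1), r.var(ddof=1)
    n1, n2 = len(t), len(r)
    se = math.sqrt(v1 / n1 + v2 / n2)
    df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    half = stats.t.ppf(1 - alpha, df) * se
    d = t.mean() - r.mean()
    return d - half, d + half


class TestTostEquivalence:
    def test_identical_samples_hand_oracle(self, ref_five):
        # SE 1.0, df 8, t_0.95 = 1.8595; margin = 1.5 * sqrt(2.5)
        res = tost_equivalence(ref_five, ref_five, k1=1.5, alpha=0.05)
        assert res.mean_diff == 0.0
        assert res.ci_high == pytest.approx(1.8595, abs=5e-5)
        assert res.ci_low == pytest.approx(-1.8595, abs=5e-5)
        assert res.df == pytest.approx(8.0)
        assert res.margin == pytest.approx(2.3717, abs=5e-5)
        assert res.passed

    def test_zero_margin_always_fails(self, ref_five):
        res = tost_equivalence([1.1, 2.0, 3.2], ref_five, k1=0.0)
        assert res.margin == 0.0 and not res.passed

    def test_huge_shift_fails(self, ref_five):
        sd_ref = np.std(ref_five, ddof=1)
        test = list(np.array([1, 2, 3, 2, 1, 3]) + 100 * sd_ref)
        ref = list(ref_five) + [2.5, 3.5, 1.5, 4.5, 2.0]
        res = tost_equivalence(test, ref)
        # brute-force: the whole interval sits outside the margin
        lo, hi = welch_ci(test, ref, 0.05)
        assert lo > res.margin
        assert not res.passed

    def test_degenerate_reference_sd_raises(self):
        with pytest.raises(DegenerateSpreadError):
            tost_equivalence([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_insufficient_lots_raise(self, ref_five):
        with pytest.raises(InsufficientLotsError):
            tost_equivalence([1.0, 2.0], ref_five)
        with pytest.raises(InsufficientLotsError):
            tost_equivalence(ref_five, [1.0, 2.0])

    def test_welch_equals_pooled_for_matched_samples(self):
        test = [1.0, 3.0, 5.0, 7.0]
        ref = [2.0, 4.0, 6.0, 8.0]  # same n, same sample variance
        w = tost_equivalence(test, ref, variance_mode="welch")
        p = tost_equivalence(test, ref, variance_mode="pooled")
        assert w.ci_low == pytest.approx(p.ci_low, rel=1e-12)
        assert w.ci_high == pytest.approx(p.ci_high, rel=1e-12)
        assert w.df == pytest.approx(p.df)

    def test_pass_monotone_in_k1(self):
        rng = np.random.default_rng(11)
        test, ref = rng.normal(0.8, 1, 6), rng.normal(0, 1, 10)
        decisions = [
            tost_equivalence(test, ref, k1=k).passed
            for k in (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        assert decisions == sorted(decisions)

    def test_interval_matches_statsmodels(self):
        """Cross-check the 90% interval against statsmodels' CompareMeans
        and the pass decision against its independent TOST p-values."""
        from statsmodels.stats.weightstats import CompareMeans, ttost_ind

        rng = np.random.default_rng(5)
        for _ in range(50):
            test = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                              rng.integers(3, 12))
            ref = rng.normal(0, 1, rng.integers(3, 12))
            res = tost_equivalence(test, ref, alpha=0.05)
            cm = CompareMeans.from_data(test, ref)
            lo, hi = cm.tconfint_diff(alpha=0.10, usevar="unequal")
            assert res.ci_low == pytest.approx(lo, rel=1e-10)
            assert res.ci_high == pytest.approx(hi, rel=1e-10)
            p, *_ = ttost_ind(test, ref, -res.margin, res.margin,
                              usevar="unequal")
            assert res.passed == (p < 0.05)


class TestQualityRange:
    def test_centered_test_lots_pass(self, ref_five):
        res = quality_range([3.0] * 6, ref_five)
        assert res.fraction_inside == 1.0 and res.passed

    def test_hand_arithmetic_oracle(self, ref_five):
        res = quality_range([2.0, 3.0, 9.0], ref_five, k2=3.0)
        assert res.qr_low == pytest.approx(-1.7434, abs=5e-5)
        assert res.qr_high == pytest.approx(7.7434, abs=5e-5)
        assert (res.n_inside, res.n_test) == (2, 3)
        assert res.fraction_inside == pytest.approx(2 / 3)
        assert not res.passed

    def test_boundary_lot_counts_inside(self, ref_five):
        res = quality_range([3.0, 3.0], ref_five)
        hi = res.qr_high
        on_bound = quality_range([hi, 3.0], ref_five)
        assert on_bound.n_inside == 2 and on_bound.passed

    def test_upper_sided_range_is_unbounded_below(self, ref_five):
        res = quality_range([-1000.0, 3.0, 3.0], ref_five, sidedness="upper")
        assert res.qr_low == -math.inf
        assert res.n_inside == 3 and res.passed

    def test_degenerate_reference_raises(self):
        with pytest.raises(DegenerateSpreadError):
            quality_range([1.0], [4.0, 4.0, 4.0])

    def test_pass_monotone_in_k2_and_inside_count(self, ref_five):
        test = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        fracs = [
            quality_range(test, ref_five, k2=k).fraction_inside
            for k in (1.0, 2.0, 3.0, 4.0, 6.0)
        ]
        assert fracs == sorted(fracs)

    def test_n_inside_matches_per_lot_count(self, ref_five):
        rng = np.random.default_rng(3)
        test = rng.normal(3, 3, 8)
        res = quality_range(test, ref_five)
        brute = sum(res.qr_low <= x <= res.qr_high for x in test)
        assert res.n_inside == brute


class TestTier3Compare:
    def test_disjoint_ranges_flag_lower(self):
        res = tier3_compare([2.2, 2.5, 2.9], [6.7, 8.0, 8.4])
        assert res.range_overlap == 0.0 and res.flag == "lower"
        assert res.test_summary.format_mean_range() == "2.5 (2.2–2.9)"

    def test_identical_samples_fully_overlap(self, ref_five):
        res = tier3_compare(ref_five, ref_five)
        assert res.range_overlap == 1.0 and res.flag == "similar"

    def test_partial_overlap_interval_arithmetic(self):
        res = tier3_compare([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert res.range_overlap == pytest.approx(1 / 3)
        assert res.flag == "similar"

    def test_disjoint_above_flags_higher(self):
        res = tier3_compare([10.0, 11.0], [1.0, 2.0])
        assert res.flag == "higher" and res.range_overlap == 0.0


class TestAffineInvariance:
    @pytest.mark.parametrize("a,b", [(2.5, -7.0), (0.01, 100.0), (1e3, 0.3)])
    def test_decisions_unchanged_under_affine_map(self, a, b):
        rng = np.random.default_rng(17)
        for _ in range(20):
            test = rng.normal(rng.uniform(-1, 2), rng.uniform(0.5, 2), 6)
            ref = rng.normal(0, 1, 10)
            t2, r2 = a * test + b, a * ref + b
            assert (
                tost_equivalence(test, ref).passed
                == tost_equivalence(t2, r2).passed
            )
            assert (
                quality_range(test, ref).passed
                == quality_range(t2, r2).passed
            )
            assert tier3_compare(test, ref).flag == tier3_compare(t2, r2).flag


class TestRunSimilarity:
    def test_empty_tier_list_gives_empty_report(self, small_table):
        report = run_similarity(small_table, [])
        assert report.rows == []

    def test_tier_without_data_reported_not_evaluated(self, small_table):
        tiers = [TierAssignment("missing", "assay", 2, "none", "")]
        report = run_similarity(small_table, tiers)
        assert report.rows[0].decision == "not evaluated"
        assert report.n_not_evaluated == 1

    def test_rows_follow_tier_table_order_with_matching_result_types(self):
        table = LotTable(
            [
                LotMeasurement(p, f"{p[0]}{i}", attr, float(v), "%")
                for attr in ("a", "b", "c")
                for p, vals in (
                    ("test", [1.0, 2.0, 3.0, 2.5, 1.5, 2.2]),
                    ("reference", [1.1, 2.1, 3.1, 0.9, 1.9, 2.9]),
                )
                for i, v in enumerate(vals)
            ]
        )
        tiers = [
            TierAssignment("b", "", 2, "none", ""),
            TierAssignment("a", "", 1, "none", ""),
            TierAssignment("c", "", 3, "none", ""),
        ]
        report = run_similarity(table, tiers)
        assert [r.attribute for r in report.rows] == ["b", "a", "c"]
        assert [type(r.result).__name__ for r in report.rows] == [
            "QualityRangeResult",
            "EquivalenceResult",
            "DescriptiveComparison",
        ]

    def test_hm_shift_fixture_flags_only_hm(self):
        """Synthetic study fixture: %HM drawn with separated means is
        flagged lower; the equal-mean glycoforms all read similar."""
        lots = generate_lots(hm_shift_scenario(seed=123))
        report = run_similarity(lots, glycan_tiers(), SimilarityConfig())
        decisions = {r.attribute: r.decision for r in report.rows}
        assert decisions.pop("HM%") == "lower"
        assert set(decisions.values()) == {"similar"}
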