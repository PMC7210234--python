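"""RRF criticality scoring, CQA filtering, and tier assignment rules."""

import io
import itertools

import pytest

from biosimilarity import (
    AttributeDefinition,
    RiskConfig,
    assign_tier,
    classify_cqa,
    rank_risk,
    risk_score,
)
from biosimilarity.adalimumab import (
    attribute_panel,
    panel_risk_config,
    tier_panel,
)
from biosimilarity.criticality import (
    DEFAULT_IMPACT_SCALE,
    DEFAULT_UNCERTAINTY_SCALE,
    ScaleError,
    read_tier_table,
)


class TestRiskScore:
    def test_score_is_exact_product(self):
        assert risk_score(16, 3) == 48.0

    def test_scale_minimum_is_below_cqa_cutoff(self):
        cfg = RiskConfig()
        score = risk_score(
            min(cfg.impact_scale), min(cfg.uncertainty_scale), cfg
        )
        assert score < cfg.cqa_cutoff

    def test_exhaustive_products_match_enumeration(self):
        # brute-force enumeration over the full 5x5 ordinal grid
        for imp, unc in itertools.product(
            DEFAULT_IMPACT_SCALE, DEFAULT_UNCERTAINTY_SCALE
        ):
            assert risk_score(imp, unc) == imp * unc

    def test_off_scale_score_names_allowed_values(self):
        with pytest.raises(ScaleError, match=r"\(2, 4, 12, 16, 20\)"):
            risk_score(3, 3)
        with pytest.raises(ScaleError, match="uncertainty"):
            risk_score(2, 4)


class TestClassifyCqa:
    def test_low_impact_attribute_is_not_cqa(self):
        # e.g. a glycoform with no clinical leverage on the indications
        defn = AttributeDefinition("High mannose", impact=2, uncertainty=3)
        assert not classify_cqa(defn).is_cqa

    def test_mandatory_override_makes_cqa_despite_low_uncertainty(self):
        cfg = RiskConfig(mandatory_cqa=frozenset({"Residual DNA"}))
        defn = AttributeDefinition("Residual DNA", impact=12, uncertainty=1)
        assessment = classify_cqa(defn, cfg)
        assert assessment.risk_score < cfg.cqa_cutoff
        assert assessment.is_cqa

    def test_max_scores_always_cqa(self):
        defn = AttributeDefinition("x", impact=20, uncertainty=7)
        a = classify_cqa(defn)
        assert a.is_cqa and a.risk_rank == "High"

    def test_is_cqa_monotone_in_both_scores(self):
        cfg = RiskConfig()
        grid = {
            (i, u): classify_cqa(
                AttributeDefinition("x", impact=i, uncertainty=u), cfg
            ).is_cqa
            for i in cfg.impact_scale
            for u in cfg.uncertainty_scale
        }
        for (i1, u1), (i2, u2) in itertools.product(grid, repeat=2):
            if i1 <= i2 and u1 <= u2:
                assert grid[(i1, u1)] <= grid[(i2, u2)]


class TestAssignTier:
    def test_moa_direct_goes_to_tier_1(self):
        defn = AttributeDefinition(
            "Soluble TNFa binding", assay="ELISA",
            moa_direct=True, quantitative=True,
        )
        t = assign_tier(defn, "High")
        assert (t.tier, t.annotation) == (1, "none")

    def test_trace_analyte_demoted_to_tier_3_hash(self):
        defn = AttributeDefinition(
            "Free thiols", quantitative=True, trace_analyte=True
        )
        t = assign_tier(defn, "High")
        assert (t.tier, t.annotation) == (3, "hash")

    def test_quantitative_high_risk_goes_to_tier_2(self):
        defn = AttributeDefinition(
            "High-molecular-weight aggregates",
            assay="SEC-HPLC-UV", quantitative=True,
        )
        t = assign_tier(defn, "High")
        assert (t.tier, t.annotation) == (2, "none")

    def test_qualitative_assay_demoted_to_tier_3_star(self):
        defn = AttributeDefinition(
            "Amino acid sequence", qualitative_assay=True
        )
        t = assign_tier(defn, "High")
        assert (t.tier, t.annotation) == (3, "star")

    def test_contradictory_flags_rejected(self):
        with pytest.raises(ValueError, match="quantitative and qualitative"):
            AttributeDefinition("x", quantitative=True, qualitative_assay=True)

    def test_override_cannot_promote_to_tier_1(self):
        cfg = RiskConfig(tier_overrides={("x", "a"): 1})
        with pytest.raises(ValueError, match="reserved"):
            assign_tier(
                AttributeDefinition("x", assay="a", quantitative=True), "High",
                cfg,
            )

    def test_assignment_is_deterministic(self):
        defn = AttributeDefinition("Monomer", assay="SEC-HPLC",
                                   quantitative=True)
        assert assign_tier(defn, "Moderate") == assign_tier(defn, "Moderate")


class TestBundledPanel:
    def test_panel_reproduces_published_tier_column(self):
        """Rule + override table reproduce every published (tier, mark)."""
        for row, assigned in zip(attribute_panel(), tier_panel()):
            assert assigned.tier == row.published_tier, assigned.attribute
            assert assigned.annotation == row.published_annotation, (
                assigned.attribute
            )

    def test_each_readout_gets_exactly_one_tier(self):
        tiers = tier_panel()
        keys = [(t.attribute, t.assay) for t in tiers]
        assert len(keys) == len(set(keys)) == len(attribute_panel())
        assert all(t.tier in (1, 2, 3) for t in tiers)

    def test_particle_rows_need_the_override(self):
        """Without the override, Moderate+quantitative lands in tier 2."""
        cfg = RiskConfig()  # no overrides
        defn = AttributeDefinition(
            "Sub-micron particles", assay="DLS", quantitative=True
        )
        assert assign_tier(defn, "Moderate", cfg).tier == 2
        assert assign_tier(defn, "Moderate", panel_risk_config()).tier == 3


def test_rank_cutpoints_partition_score_axis():
    cfg = RiskConfig(rank_cutpoints=(16.0, 48.0))
    assert rank_risk(15.9, cfg) == "Low"
    assert rank_risk(16.0, cfg) == "Moderate"
    assert rank_risk(48.0, cfg) == "High"


def test_tier_table_csv_round_trip():
    tiers = tier_panel()
    csv = "attribute,assay,tier,annotation,rationale\n" + "".join(
        f'"{t.attribute}","{t.assay}",{t.tier},{t.annotation},"{t.rationale}"\n'
        for t in tiers
    )
    back = read_tier_table(io.StringIO(csv))
    assert back == tiers
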