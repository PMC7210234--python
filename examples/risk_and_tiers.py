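"""Score attribute criticality and assign similarity tiers.

Scores a couple of hand-built attributes through the risk ranking and
filtering (RRF) scheme, then tiers the full bundled adalimumab panel.
"""

from collections import Counter

from biosimilarity import AttributeDefinition, RiskConfig, classify_cqa
from biosimilarity.adalimumab import tier_panel
from biosimilarity.report import tier_label

config = RiskConfig(mandatory_cqa=frozenset({"Residual DNA"}))

examples = [
    # impact and uncertainty are ordinal scores; the risk score is their
    # product, filtered at the configured CQA cutoff (default 16)
    AttributeDefinition("High-molecular-weight aggregates",
                        impact=16, uncertainty=3, quantitative=True),
    AttributeDefinition("High mannose", impact=2, uncertainty=3,
                        quantitative=True),
    AttributeDefinition("Residual DNA", impact=12, uncertainty=1,
                        quantitative=True, trace_analyte=True),
]

print("attribute                              score  rank      CQA")
for defn in examples:
    a = classify_cqa(defn, config)
    print(f"{a.attribute:38s} {a.risk_score:5.0f}  {a.risk_rank:9s} {a.is_cqa}")
# Aggregates score 48 -> High-risk CQA; high mannose scores 6 -> non-CQA;
# residual DNA scores only 12 but is a CQA by the mandatory-impurity rule.

tiers = tier_panel()
counts = Counter(tier_label(t.tier, t.annotation) for t in tiers)
print(f"\nbundled panel: {len(tiers)} (attribute, assay) readouts")
for label in ("1", "2", "3", "3*", "3#"):
    print(f"  tier {label:3s} {counts[label]:3d}")
# Tier 1 holds only the MOA-direct TNFa readouts; 3* marks qualitative
# assays and 3# trace-level analytes, which skip interval statistics.
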