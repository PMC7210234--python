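"""Risk ranking and filtering (RRF) of quality attributes, and tier assignment.

Criticality of each quality attribute is scored by the RRF scheme used in
QbD-style biosimilar development: an ordinal *impact* score (consequence of
the attribute drifting, for efficacy/PK/safety/immunogenicity) is multiplied
by an ordinal *uncertainty* score (how well that impact is understood) to
give a risk score.  Attributes at or above a cutoff — or on a mandatory
list, such as process-related impurities whose toxicity makes them CQAs
regardless of uncertainty — are critical quality attributes (CQAs).

Tier assignment then routes each (attribute, assay) readout to a similarity
procedure:

* tier 1 — equivalence testing; reserved for attributes with a direct
  impact on the primary mechanism of action;
* tier 2 — quality-range comparison; moderate-to-high-risk quantitative
  readouts;
* tier 3 — descriptive/visual comparison; low-risk readouts, plus any
  readout that is qualitative (annotated ``*``) or measures a trace-level
  analyte (annotated ``#``), whatever its risk rank.

A per-(attribute, assay) override table allows a tier to be forced where a
development program's judgement departs from the general rule; overrides
may only demote (tier 1 remains reserved for MOA-direct attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .lots import AttributeDefinition

RANKS = ("Low", "Moderate", "High")

# Ordinal scales of the Roche/Genentech-style RRF framework.  The gaps are
# intentional: they separate adjacent categories multiplicatively so that
# rank cut-points on the product are unambiguous.
DEFAULT_IMPACT_SCALE = (2, 4, 12, 16, 20)
DEFAULT_UNCERTAINTY_SCALE = (1, 2, 3, 5, 7)


class ScaleError(ValueError):
    """A score is not a member of the configured ordinal scale."""


@dataclass(frozen=True)
class RiskConfig:
    """Scales, cut-points, and overrides for RRF scoring and tiering.

    ``rank_cutpoints`` is ``(moderate_min, high_min)`` on the risk score;
    ``cqa_cutoff`` is the minimum risk score for CQA status.  Defaults put
    any attribute with at least mid-scale impact and non-trivial
    uncertainty into Moderate, and the CQA filter at the Moderate line.
    ``mandatory_cqa`` lists attribute names that are CQAs regardless of
    score.  ``tier_overrides`` maps (attribute, assay) to a forced tier.
    """

    impact_scale: tuple[int, ...] = DEFAULT_IMPACT_SCALE
    uncertainty_scale: tuple[int, ...] = DEFAULT_UNCERTAINTY_SCALE
    cqa_cutoff: float = 16.0
    rank_cutpoints: tuple[float, float] = (16.0, 48.0)
    mandatory_cqa: frozenset[str] = frozenset()
    tier_overrides: Mapping[tuple[str, str], int] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        lo, hi = self.rank_cutpoints
        if not lo <= hi:
            raise ValueError("rank cut-points must be non-decreasing")


DEFAULT_RISK_CONFIG = RiskConfig()


@dataclass(frozen=True)
class RiskAssessment:
    attribute: str
    impact: int
    uncertainty: int
    risk_score: float
    risk_rank: str
    is_cqa: bool


@dataclass(frozen=True)
class TierAssignment:
    attribute: str
    assay: str
    tier: int
    annotation: str  # "none" | "star" | "hash"
    rationale: str


def _check_scale(value: int, scale: Sequence[int], name: str) -> None:
    if value not in scale:
        raise ScaleError(
            f"{name} score {value} not on the configured scale "
            f"{tuple(scale)}"
        )


def risk_score(
    impact: int,
    uncertainty: int,
    config: RiskConfig = DEFAULT_RISK_CONFIG,
) -> float:
    """Risk score: the exact product of impact and uncertainty scores."""
    _check_scale(impact, config.impact_scale, "impact")
    _check_scale(uncertainty, config.uncertainty_scale, "uncertainty")
    return float(impact * uncertainty)


def rank_risk(score: float, config: RiskConfig = DEFAULT_RISK_CONFIG) -> str:
    moderate_min, high_min = config.rank_cutpoints
    if score >= high_min:
        return "High"
    if score >= moderate_min:
        return "Moderate"
    return "Low"


def classify_cqa(
    defn: AttributeDefinition,
    config: RiskConfig = DEFAULT_RISK_CONFIG,
) -> RiskAssessment:
    """Score an attribute and decide CQA status.

    An attribute is a CQA when its risk score reaches ``cqa_cutoff`` or
    when it is on the mandatory-CQA list (used for process-related
    impurities, which are critical on toxicity grounds even when their
    uncertainty score is low).
    """
    score = risk_score(defn.impact, defn.uncertainty, config)
    mandatory = defn.attribute in config.mandatory_cqa
    return RiskAssessment(
        attribute=defn.attribute,
        impact=defn.impact,
        uncertainty=defn.uncertainty,
        risk_score=score,
        risk_rank=rank_risk(score, config),
        is_cqa=score >= config.cqa_cutoff or mandatory,
    )


def assign_tier(
    defn: AttributeDefinition,
    risk_rank: str,
    config: RiskConfig = DEFAULT_RISK_CONFIG,
) -> TierAssignment:
    """Assign one (attribute, assay) readout to a similarity tier."""
    if risk_rank not in RANKS:
        raise ValueError(f"risk_rank must be one of {RANKS}, got {risk_rank!r}")

    if defn.moa_direct:
        tier, rationale = 1, "direct impact on primary MOA"
    else:
        override = config.tier_overrides.get((defn.attribute, defn.assay))
        if override is not None:
            if override == 1:
                raise ValueError(
                    "tier 1 is reserved for MOA-direct attributes; "
                    f"cannot force ({defn.attribute!r}, {defn.assay!r}) to 1"
                )
            tier, rationale = override, "per-attribute override"
        elif (
            risk_rank in ("High", "Moderate")
            and defn.quantitative
            and not defn.trace_analyte
            and not defn.qualitative_assay
        ):
            tier, rationale = 2, f"{risk_rank} risk, quantitative assay"
        else:
            tier, rationale = 3, _tier3_rationale(defn, risk_rank)

    if tier == 3 and defn.qualitative_assay:
        annotation = "star"
    elif tier == 3 and defn.trace_analyte:
        annotation = "hash"
    else:
        annotation = "none"
    return TierAssignment(
        attribute=defn.attribute,
        assay=defn.assay,
        tier=tier,
        annotation=annotation,
        rationale=rationale,
    )


def _tier3_rationale(defn: AttributeDefinition, risk_rank: str) -> str:
    if defn.qualitative_assay:
        return f"qualitative assay despite {risk_rank} risk"
    if defn.trace_analyte:
        return f"trace-level analyte despite {risk_rank} risk"
    return f"{risk_rank} risk"


def read_tier_table(source) -> list[TierAssignment]:
    """Read tier assignments from CSV (columns attribute, assay, tier,
    annotation; annotation and assay optional, extra columns ignored)."""
    import pandas as pd

    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "attribute" not in df.columns or "tier" not in df.columns:
        raise ValueError("tier table needs 'attribute' and 'tier' columns")
    out = []
    for _, row in df.iterrows():
        out.append(
            TierAssignment(
                attribute=row["attribute"].strip(),
                assay=row["assay"].strip() if "assay" in df.columns else "",
                tier=int(row["tier"]),
                annotation=(
                    row["annotation"].strip() or "none"
                    if "annotation" in df.columns
                    else "none"
                ),
                rationale=(
                    row["rationale"].strip()
                    if "rationale" in df.columns
                    else ""
                ),
            )
        )
    return out


def assign_tiers(
    definitions: Iterable[AttributeDefinition],
    risk_ranks: Mapping[tuple[str, str], str] | None = None,
    config: RiskConfig = DEFAULT_RISK_CONFIG,
) -> list[TierAssignment]:
    """Tier a whole attribute panel.

    ``risk_ranks`` may supply ranks directly, keyed by (attribute, assay);
    absent entries are computed from the definition's impact/uncertainty
    scores through the configured cut-points.
    """
    risk_ranks = risk_ranks or {}
    out = []
    for defn in definitions:
        rank = risk_ranks.get((defn.attribute, defn.assay))
        if rank is None:
            rank = rank_risk(
                risk_score(defn.impact, defn.uncertainty, config), config
            )
        out.append(assign_tier(defn, rank, config))
    return out
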