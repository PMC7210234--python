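"""Tier-specific statistical similarity procedures.

Three procedures, one per tier of criticality:

* **Tier 1 — equivalence (TOST).**  Two one-sided t-tests at one-sided
  size α, carried out through the equivalent confidence-interval rule: the
  two-sided 100(1−2α)% interval for the mean difference (test − reference)
  must lie strictly inside the margin (−k₁·SD_R, +k₁·SD_R), where SD_R is
  the *reference-product* sample SD.  Defaults k₁ = 1.5, α = 0.05 give the
  conventional "90% CI inside ±1.5 SD_R" rule.

* **Tier 2 — quality range.**  The range is the reference mean ± k₂·SD_R
  (default k₂ = 3); the test product passes when at least ``pass_fraction``
  (default 90%) of its lots fall inside the closed interval.  Upper-sided
  mode, (−∞, mean + k₂·SD_R], serves impurity-style attributes where only
  an excess matters.

* **Tier 3 — descriptive comparison.**  In place of a subjective visual
  call, a reproducible numeric descriptor: the overlap of the two lot
  ranges divided by their union, plus a three-way flag — ``lower`` /
  ``higher`` only when the ranges are disjoint, ``similar`` otherwise.

Margins and ranges are always anchored to reference-product variability,
never to test-product or pooled variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .criticality import TierAssignment
from .lots import (
    AttributeDefinition,
    LotTable,
    SummaryStats,
    UnknownKeyError,
    summary_stats,
)


class DegenerateSpreadError(ValueError):
    """Reference lots have zero sample SD: margin/range would be empty."""


class InsufficientLotsError(ValueError):
    """Too few lots for the requested procedure."""


@dataclass(frozen=True)
class EquivalenceResult:
    attribute: str
    mean_diff: float
    ci_low: float
    ci_high: float
    sd_ref: float
    margin: float
    alpha: float
    df: float
    variance_mode: str
    passed: bool


@dataclass(frozen=True)
class QualityRangeResult:
    attribute: str
    qr_low: float
    qr_high: float
    n_inside: int
    n_test: int
    fraction_inside: float
    passed: bool


@dataclass(frozen=True)
class DescriptiveComparison:
    attribute: str
    test_summary: SummaryStats
    ref_summary: SummaryStats
    range_overlap: float
    flag: str  # "similar" | "lower" | "higher"


def _as_sample(values: Sequence[float] | np.ndarray, arm: str) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InsufficientLotsError(f"{arm} sample must be a non-empty 1-d array")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{arm} sample contains non-finite values")
    return x


def tost_equivalence(
    test: Sequence[float],
    ref: Sequence[float],
    k1: float = 1.5,
    alpha: float = 0.05,
    variance_mode: str = "welch",
    attribute: str = "",
) -> EquivalenceResult:
    """Tier-1 equivalence test via the confidence-interval inclusion rule.

    Equivalent to two one-sided two-sample t-tests of size ``alpha``
    against the margins ∓``k1``·SD_R: similarity is declared iff the
    two-sided 100(1−2α)% interval for mean(test) − mean(reference) lies
    strictly inside the open interval (−margin, +margin).

    ``variance_mode`` selects the interval construction: ``"welch"``
    (unequal variances, Welch–Satterthwaite df — the default) or
    ``"pooled"`` (classical equal-variance t with n₁+n₂−2 df).
    """
    t_arr, r_arr = _as_sample(test, "test"), _as_sample(ref, "reference")
    if t_arr.size < 3 or r_arr.size < 3:
        raise InsufficientLotsError(
            f"equivalence testing needs >=3 lots per product "
            f"(got {t_arr.size} test, {r_arr.size} reference)"
        )
    sd_ref = float(np.std(r_arr, ddof=1))
    if sd_ref == 0.0:
        raise DegenerateSpreadError(
            "reference lots are identical; the equivalence margin is degenerate"
        )
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")

    n1, n2 = t_arr.size, r_arr.size
    v1, v2 = float(np.var(t_arr, ddof=1)), float(np.var(r_arr, ddof=1))
    diff = float(np.mean(t_arr) - np.mean(r_arr))

    if variance_mode == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        if se == 0.0:
            raise DegenerateSpreadError("both samples have zero variance")
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    elif variance_mode == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0.0:
            raise DegenerateSpreadError("pooled variance is zero")
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    tcrit = float(stats.t.ppf(1.0 - alpha, df))
    half = tcrit * se
    margin = k1 * sd_ref
    ci_low, ci_high = diff - half, diff + half
    return EquivalenceResult(
        attribute=attribute,
        mean_diff=diff,
        ci_low=ci_low,
        ci_high=ci_high,
        sd_ref=sd_ref,
        margin=margin,
        alpha=alpha,
        df=df,
        variance_mode=variance_mode,
        passed=bool(ci_low > -margin and ci_high < margin),
    )


def quality_range(
    test: Sequence[float],
    ref: Sequence[float],
    k2: float = 3.0,
    pass_fraction: float = 0.9,
    sidedness: str = "two",
    attribute: str = "",
) -> QualityRangeResult:
    """Tier-2 quality-range comparison.

    The range is [mean_R − k₂·SD_R, mean_R + k₂·SD_R] (closed interval;
    a lot exactly on a bound counts as inside).  ``sidedness="upper"``
    uses (−∞, mean_R + k₂·SD_R] for one-sided impurity attributes.
    Similarity requires fraction_inside ≥ ``pass_fraction`` — the
    comparison is exact, so at the default 0.9 a 6-lot test product must
    place all 6 lots inside (5/6 ≈ 0.833 fails).
    """
    t_arr, r_arr = _as_sample(test, "test"), _as_sample(ref, "reference")
    if r_arr.size < 3:
        raise InsufficientLotsError(
            f"quality range needs >=3 reference lots (got {r_arr.size})"
        )
    sd_ref = float(np.std(r_arr, ddof=1))
    if sd_ref == 0.0:
        raise DegenerateSpreadError(
            "reference lots are identical; the quality range is degenerate"
        )
    if sidedness not in ("two", "upper"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    mean_ref = float(np.mean(r_arr))
    qr_high = mean_ref + k2 * sd_ref
    qr_low = -math.inf if sidedness == "upper" else mean_ref - k2 * sd_ref

    inside = (t_arr >= qr_low) & (t_arr <= qr_high)
    n_inside = int(np.count_nonzero(inside))
    fraction = n_inside / t_arr.size
    return QualityRangeResult(
        attribute=attribute,
        qr_low=qr_low,
        qr_high=qr_high,
        n_inside=n_inside,
        n_test=int(t_arr.size),
        fraction_inside=fraction,
        passed=bool(fraction >= pass_fraction),
    )


def tier3_compare(
    test: Sequence[float],
    ref: Sequence[float],
    attribute: str = "",
) -> DescriptiveComparison:
    """Tier-3 descriptive comparison of the two lot ranges.

    ``range_overlap`` is overlap length / union length of the [min, max]
    intervals (1.0 when both ranges collapse to the same point).  The flag
    is ``lower``/``higher`` only when the ranges are disjoint — mirroring
    the one unambiguous outcome a visual comparison can give — and
    ``similar`` otherwise.
    """
    t_arr, r_arr = _as_sample(test, "test"), _as_sample(ref, "reference")
    ts, rs = summary_stats(t_arr), summary_stats(r_arr)
    overlap = max(0.0, min(ts.max, rs.max) - max(ts.min, rs.min))
    union = max(ts.max, rs.max) - min(ts.min, rs.min)
    if union == 0.0:
        ratio = 1.0  # both ranges are the same single point
    else:
        ratio = overlap / union
    if ts.max < rs.min:
        flag = "lower"
    elif ts.min > rs.max:
        flag = "higher"
    else:
        flag = "similar"
    return DescriptiveComparison(
        attribute=attribute,
        test_summary=ts,
        ref_summary=rs,
        range_overlap=ratio,
        flag=flag,
    )


@dataclass(frozen=True)
class SimilarityConfig:
    """Constants of the three procedures, with the conventional defaults."""

    k1: float = 1.5
    k2: float = 3.0
    alpha: float = 0.05
    pass_fraction: float = 0.9
    variance_mode: str = "welch"

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("margin multipliers must be positive")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.0 < self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SimilarityRow:
    attribute: str
    assay: str
    tier: int
    annotation: str
    evaluated: bool
    decision: str  # pass | fail | similar | lower | higher | not evaluated
    result: object | None


@dataclass
class SimilarityReport:
    rows: list[SimilarityRow] = field(default_factory=list)
    config: SimilarityConfig = field(default_factory=SimilarityConfig)

    @property
    def n_pass(self) -> int:
        return sum(r.decision in ("pass", "similar") for r in self.rows)

    @property
    def n_fail(self) -> int:
        return sum(r.decision == "fail" for r in self.rows)

    @property
    def n_flagged(self) -> int:
        return sum(r.decision in ("lower", "higher") for r in self.rows)

    @property
    def n_not_evaluated(self) -> int:
        return sum(not r.evaluated for r in self.rows)


def run_similarity(
    lots: LotTable,
    tiers: Iterable[TierAssignment],
    config: SimilarityConfig = SimilarityConfig(),
    definitions: Mapping[str, AttributeDefinition] | None = None,
) -> SimilarityReport:
    """Apply the tier-appropriate procedure to every tiered readout.

    Report rows follow the tier-table order.  A tiered attribute with no
    lot data for either product — or whose data violate a procedure's
    preconditions — is reported as ``not evaluated`` rather than raising.
    ``definitions`` (keyed by attribute name) supplies the ``one_sided``
    flag that switches tier-2 attributes to the upper-sided quality range.
    """
    definitions = definitions or {}
    rows: list[SimilarityRow] = []
    for ta in tiers:
        try:
            test = lots.values(ta.attribute, "test")
            ref = lots.values(ta.attribute, "reference")
        except UnknownKeyError:
            rows.append(
                SimilarityRow(
                    ta.attribute, ta.assay, ta.tier, ta.annotation,
                    evaluated=False, decision="not evaluated", result=None,
                )
            )
            continue
        try:
            result: object
            if ta.tier == 1:
                res = tost_equivalence(
                    test, ref,
                    k1=config.k1, alpha=config.alpha,
                    variance_mode=config.variance_mode,
                    attribute=ta.attribute,
                )
                decision, result = ("pass" if res.passed else "fail"), res
            elif ta.tier == 2:
                defn = definitions.get(ta.attribute)
                sidedness = "upper" if defn and defn.one_sided else "two"
                qr = quality_range(
                    test, ref,
                    k2=config.k2, pass_fraction=config.pass_fraction,
                    sidedness=sidedness, attribute=ta.attribute,
                )
                decision, result = ("pass" if qr.passed else "fail"), qr
            else:
                cmp_ = tier3_compare(test, ref, attribute=ta.attribute)
                decision, result = cmp_.flag, cmp_
            rows.append(
                SimilarityRow(
                    ta.attribute, ta.assay, ta.tier, ta.annotation,
                    evaluated=True, decision=decision, result=result,
                )
            )
        except (DegenerateSpreadError, InsufficientLotsError):
            rows.append(
                SimilarityRow(
                    ta.attribute, ta.assay, ta.tier, ta.annotation,
                    evaluated=False, decision="not evaluated", result=None,
                )
            )
    return SimilarityReport(rows=rows, config=config)
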