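# Methods

## Data model

The sampling unit is the manufacturing lot. Measurements live in a long
(tidy) table — one row per (product, lot, attribute) — because attributes
are routinely measured on unequal numbers of lots, and a wide layout
would force missing-value semantics the procedures do not have. Products
carry role labels, `test` and `reference`. Units are opaque strings
checked for per-attribute consistency; there is no unit conversion
(comparisons are like-for-like assays), and missing values are rejected
rather than imputed. Summary SDs use the n−1 denominator throughout:
reference lots are treated as a sample from the batch process, and both
the equivalence margin and the quality range are defined in terms of
that process SD.

## Criticality scoring and tiering

Risk ranking and filtering multiplies an ordinal impact score by an
ordinal uncertainty score. The default scales — impact
{2, 4, 12, 16, 20}, uncertainty {1, 2, 3, 5, 7} — follow the widely used
industrial RRF framework; their irregular spacing keeps products of
adjacent categories distinct. Score cut-points are configuration:
CQA cutoff 16 (any at-least-moderate impact with non-trivial
uncertainty), rank cut-points Moderate ≥ 16 and High ≥ 48. These
defaults matter only when ranks are computed from scores; the bundled
panel supplies published ranks directly. A mandatory-CQA list covers
attributes that are critical on toxicity or immunogenicity grounds even
at a low uncertainty score (process-related impurities); `is_cqa` is
monotone non-decreasing in both scores by construction.

The tier rule is: tier 1 iff the attribute directly drives the primary
mechanism of action; else tier 2 for Moderate/High-rank quantitative
readouts that are neither qualitative nor trace-level; else tier 3.
Tier-3 annotations are driven by the assay-nature flags alone (`*`
qualitative, `#` trace) whatever the rank — the bundled panel contains a
Low-rank qualitative readout (isoelectric point) that carries the `*`
mark, so conditioning the mark on rank would mis-render it. Tiers attach
to (attribute, assay) pairs: the same attribute measured by two methods
can legitimately sit in different tiers (e.g. size variants by
quantitative SEC-UV in tier 2, by qualitative SEC-MALS in tier 3). The
rule cannot produce the bundled panel's two particle rows (Moderate,
quantitative, yet tier 3); these are carried in an explicit override
table, and overrides may only demote — tier 1 stays reserved for
MOA-direct attributes. How a tier-2 attribute measured by two assays
should be reconciled if the assays disagree is left to the report reader;
the package evaluates and reports each readout separately.

## Tier-1 equivalence

The TOST decision is implemented through its confidence-interval
equivalent: pass iff the two-sided 100(1−2α)% t interval for
mean(test) − mean(reference) lies strictly inside (−k₁·SD_R, +k₁·SD_R),
with defaults k₁ = 1.5, α = 0.05. The interval defaults to the
Welch–Satterthwaite construction — lot-to-lot variances of a biosimilar
candidate and an originator have no reason to be equal — with a
pooled-variance option for guideline-style comparisons; the two coincide
when the arms share n and sample variance. Strict inequality at the
margin is a fixed, testable boundary convention (ties have probability
zero for continuous data). The margin uses the reference sample SD only,
never pooled or test-product variability, and no small-sample correction
is applied for estimating SD_R from ~10 lots; the operating consequences
of that choice are quantified by simulation rather than adjusted away
(see below). Degenerate inputs raise: fewer than 3 lots in either arm,
or a zero reference SD.

## Tier-2 quality range

Range [mean_R − k₂·SD_R, mean_R + k₂·SD_R] with k₂ = 3; membership uses
the closed interval, so a lot exactly on a bound is inside. The pass
criterion `fraction_inside ≥ 0.9` is applied exactly: at n_test = 6,
5/6 ≈ 0.833 fails and all 6 lots must be inside. One-sided attributes
(impurities, fragments) use (−∞, mean_R + k₂·SD_R].

## Tier-3 descriptive comparison

Published practice is a visual call; for reproducibility the package
reports the overlap of the two [min, max] lot ranges divided by their
union (defined as 1 when both ranges collapse to the same point), and a
flag that is `lower`/`higher` only when the ranges are disjoint — the
one configuration a visual comparison can classify unambiguously — and
`similar` otherwise. All three procedures are invariant under affine
rescaling x → ax + b (a > 0) of both products, verified by test.

## Operating-characteristics simulation

Lots are drawn i.i.d. normal per product; the configured procedure is
applied per replicate; the pass rate and its binomial Monte-Carlo SE are
reported. Normality reflects the kind of continuous assay readouts the
rules are applied to, and matches the implicit assumption of SD-based
margins; a lognormal option (parameterised by arithmetic mean and SD)
covers skewed impurity measurements. Seed policy: replicate r of a
scenario with seed s uses `SeedSequence([s, r])`, so verdicts are
bit-reproducible replicate-for-replicate; power-curve points derive
their seed from the *value* of the shift, so duplicated shifts give
identical rows. Replicates whose reference lots collapse to zero sample
SD cannot support a margin; they count as failures and are tallied.

`margin_mode` separates two questions. `estimated` (default) is the
procedure as practised: the margin or range is rebuilt from each
replicate's reference sample SD. `known` fixes the acceptance limits
from the scenario's true parameters. The distinction is material: at a
true shift equal to 1.5 σ_R, the known-margin tier-1 pass rate is the
one-sided test size (~0.05, asymptotically Φ(−z₀.₉₅) exactly), while
re-estimating the margin from the reference lots inflates it to ≈ 0.094
in the large-n limit (simulation here reproduces both numbers). The
package reports this rather than applying any margin correction, since
the decision rule under study prescribes none. No closed-form power for
the unknown-σ TOST is attempted; Monte Carlo is the contract.

## Synthetic lot generator and the bundled study fixture

The generator draws each (product, attribute) cell from its own seed
substream (keyed by a stable hash of the labels), so extending a spec
never perturbs existing draws; lot ids T01…/R01… are shared across
attributes within a product, as in a design assaying every lot on the
full panel. `sd = 0` yields exact means. CSV output can round to each
attribute's printed precision while full precision is retained in
memory.

The bundled fixture emulates a published adalimumab-biosimilar exercise:
6 test vs 10 reference lots across five glycoform percentages, with
per-product means taken from the published `mean (range)` summaries and
SDs reconstructed as (max − min)/4 — the range of 6–10 normal draws
spans roughly 3–4 SDs, so range/4 is a documented approximation, never a
published value, and per-lot values are a fixture choice, not ground
truth. Whether published ranges are min–max over lots or over replicate
injections is unstated in such tables; they are treated as min–max over
lots. Two trace-level glycan quantities near the detection limit are
excluded from the fixture. Attributes are generated independently;
real glycoform fractions co-vary, so passing fixture tests demonstrates
the decision machinery, not multivariate realism.

The fixture comes in two flavours. `glycan_scenario` is the faithful
emulation with every attribute at its per-product published parameters.
Because two of its attributes have genuinely different published means
(galactosylation differs by ≈ 2.3 reference SDs), independent redraws of
that scenario produce disjoint ranges for them in a non-trivial fraction
of seeds — faithful to the between-product differences, but noisy as a
regression target. `hm_shift_scenario` therefore isolates the
qualitative signature: only high-mannose content (%HM, means 2.5 vs 8.0,
disjoint ranges in essentially every draw) keeps its per-product
parameters, and all other attributes are drawn with the reference
parameters for both products, making "%HM lower, everything else
similar" the expected verdict pattern in ≥ 90% of seeded runs.

## Problem sizes and numerical conventions

Test-suite and acceptance computations use: 2000 replicates for interval
coverage at zero shift, 1000 randomized small-sample cases (n ∈ [3, 12])
for exact agreement with first-principles recomputation, 100 seeded
fixture runs for the verdict pattern, and 1500 replicates at n = 200 per
arm for the size-at-margin check — sizes chosen so each estimate's
Monte-Carlo SE is small against the property being checked. Lot-summary
means are clamped into [min, max] to absorb one-ulp summation rounding;
report tables round statistics to 6 decimals. t quantiles come from
scipy; statsmodels appears only in tests as an independent oracle for
the Welch interval and TOST p-values.

## Known limitations

No multiplicity adjustment across attributes (the tiered framework
applies none); no Bayesian or min–max-scaled alternatives; no assay
raw-data parsing; no correlated multi-attribute generation; descriptive
tier-3 flags are range-based and deliberately coarse.
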