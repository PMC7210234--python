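"""Lot-level measurement tables and attribute metadata.

The sampling unit of every statistic in this package is the manufacturing
lot (batch).  Measurements are kept in a long/tidy layout — one row per
(product, lot, attribute) — so that attributes measured on different
numbers of lots coexist without missing-value semantics.  Products are
identified by their *role* in the comparison: ``"test"`` (the biosimilar
candidate) and ``"reference"`` (the licensed originator).

Values are continuous assay readouts in attribute-specific units; units
are opaque strings compared for equality only.  Missing or non-numeric
values are rejected at parse time — none of the downstream procedures has
an imputation step.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PRODUCT_ROLES = ("test", "reference")

DEFAULT_SCHEMA: Mapping[str, str] = {
    "product": "product",
    "lot_id": "lot_id",
    "attribute": "attribute",
    "value": "value",
    "unit": "unit",
}


class LotTableError(ValueError):
    """Base class for lot-table validation failures."""


class SchemaError(LotTableError):
    """A required column is missing from the input stream."""


class RowParseError(LotTableError):
    """A row carries a non-numeric or non-finite value."""


class DuplicateMeasurementError(LotTableError):
    """Two rows share the same (product, lot_id, attribute) key."""


class UnitMismatchError(LotTableError):
    """An attribute is reported in more than one unit."""


class UnknownKeyError(KeyError):
    """Lookup of an attribute/product combination absent from the table."""


@dataclass(frozen=True)
class LotMeasurement:
    """A single continuous readout for one lot of one product."""

    product: str
    lot_id: str
    attribute: str
    value: float
    unit: str = ""

    def __post_init__(self) -> None:
        if self.product not in PRODUCT_ROLES:
            raise LotTableError(
                f"product must be one of {PRODUCT_ROLES}, got {self.product!r}"
            )
        if not math.isfinite(self.value):
            raise RowParseError(
                f"non-finite value {self.value!r} for "
                f"({self.product}, {self.lot_id}, {self.attribute})"
            )


@dataclass
class LotTable:
    """Ordered collection of lot measurements for a two-product comparison."""

    measurements: list[LotMeasurement] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        units: dict[str, str] = {}
        for m in self.measurements:
            key = (m.product, m.lot_id, m.attribute)
            if key in seen:
                raise DuplicateMeasurementError(
                    f"duplicate measurement for {key}"
                )
            seen.add(key)
            if m.attribute in units and units[m.attribute] != m.unit:
                raise UnitMismatchError(
                    f"attribute {m.attribute!r} reported in both "
                    f"{units[m.attribute]!r} and {m.unit!r}"
                )
            units.setdefault(m.attribute, m.unit)

    def __len__(self) -> int:
        return len(self.measurements)

    def attributes(self) -> list[str]:
        """Attribute names in first-appearance order."""
        out: list[str] = []
        for m in self.measurements:
            if m.attribute not in out:
                out.append(m.attribute)
        return out

    def unit(self, attribute: str) -> str:
        for m in self.measurements:
            if m.attribute == attribute:
                return m.unit
        raise UnknownKeyError(attribute)

    def values(self, attribute: str, product: str) -> np.ndarray:
        """All lot values for (attribute, product), in table order."""
        vals = [
            m.value
            for m in self.measurements
            if m.attribute == attribute and m.product == product
        ]
        if not vals:
            raise UnknownKeyError(
                f"no lots for attribute {attribute!r}, product {product!r}"
            )
        return np.asarray(vals, dtype=float)

    def has_both_products(self, attribute: str) -> bool:
        present = {
            m.product for m in self.measurements if m.attribute == attribute
        }
        return set(PRODUCT_ROLES) <= present

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.product, m.lot_id, m.attribute, m.value, m.unit)
                for m in self.measurements
            ],
            columns=list(DEFAULT_SCHEMA),
        )


@dataclass(frozen=True)
class AttributeDefinition:
    """Criticality inputs and assay-nature flags for one quality attribute.

    ``impact`` and ``uncertainty`` are ordinal scores on the configured
    risk-ranking scales.  The boolean flags describe the (attribute, assay)
    readout: ``moa_direct`` marks a direct mechanism-of-action attribute
    (reserved for tier 1), ``quantitative``/``qualitative_assay`` describe
    the nature of the readout, ``trace_analyte`` marks analytes present at
    levels too low for meaningful interval statistics, and ``one_sided``
    marks impurity-style attributes where only an upper bound matters.
    """

    attribute: str
    impact: int = 0
    uncertainty: int = 0
    assay: str = ""
    moa_direct: bool = False
    quantitative: bool = False
    qualitative_assay: bool = False
    trace_analyte: bool = False
    one_sided: bool = False
    unit: str = ""

    def __post_init__(self) -> None:
        if self.quantitative and self.qualitative_assay:
            raise ValueError(
                f"{self.attribute!r}/{self.assay!r}: an assay readout cannot "
                "be both quantitative and qualitative"
            )


@dataclass(frozen=True)
class SummaryStats:
    """Per-product lot summary: n, mean, sample SD, min, max."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def format_mean_range(self, decimals: int = 1) -> str:
        """Render in ``mean (min–max)`` style, e.g. ``"2.5 (2.2–2.9)"``."""
        f = f"{{:.{decimals}f}}"
        return (
            f"{f.format(self.mean)} "
            f"({f.format(self.min)}–{f.format(self.max)})"
        )


def summary_stats(values: Sequence[float] | np.ndarray) -> SummaryStats:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UnknownKeyError("cannot summarize an empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    lo, hi = float(np.min(x)), float(np.max(x))
    # clamp: summation rounding can push the mean past min/max by one ulp
    mean = min(max(float(np.mean(x)), lo), hi)
    return SummaryStats(n=int(x.size), mean=mean, sd=sd, min=lo, max=hi)


def summarize_attribute(
    table: LotTable, attribute: str, product: str
) -> SummaryStats:
    """Summary statistics over one product's lots for one attribute.

    The SD is the sample standard deviation (n−1 denominator): reference
    lots are treated as a sample from the batch process, which is the
    convention both the equivalence margin and the quality range rely on.
    """
    return summary_stats(table.values(attribute, product))


def read_lot_table(
    source: str | IO[str],
    schema: Mapping[str, str] | None = None,
    provenance: str = "",
) -> LotTable:
    """Parse a long-format lot CSV into a :class:`LotTable`.

    Parameters
    ----------
    source
        Path or text stream of a comma-delimited, UTF-8, header-first CSV.
    schema
        Mapping from canonical field names (``product``, ``lot_id``,
        ``attribute``, ``value``, ``unit``) to the column names actually
        present; defaults to the identity mapping.  ``unit`` may be
        omitted from the file.
    """
    schema = dict(DEFAULT_SCHEMA) | dict(schema or {})
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = ["product", "lot_id", "attribute", "value"]
    for key in required:
        if schema[key] not in df.columns:
            raise SchemaError(f"missing required column {schema[key]!r}")
    has_unit = schema["unit"] in df.columns

    measurements: list[LotMeasurement] = []
    for idx, row in df.iterrows():
        raw = row[schema["value"]].strip()
        try:
            value = float(raw)
        except ValueError:
            # +2: header line plus 1-based numbering
            raise RowParseError(
                f"line {int(idx) + 2}: non-numeric value {raw!r} for "
                f"attribute {row[schema['attribute']]!r}"
            ) from None
        if not math.isfinite(value):
            raise RowParseError(
                f"line {int(idx) + 2}: non-finite value {raw!r}"
            )
        measurements.append(
            LotMeasurement(
                product=row[schema["product"]].strip(),
                lot_id=row[schema["lot_id"]].strip(),
                attribute=row[schema["attribute"]].strip(),
                value=value,
                unit=row[schema["unit"]].strip() if has_unit else "",
            )
        )
    return LotTable(measurements=measurements, provenance=provenance)


def write_lot_table(
    table: LotTable,
    dest: str | IO[str] | None = None,
    decimals: Mapping[str, int] | None = None,
) -> str | None:
    """Write a lot table as the standard five-column CSV.

    ``decimals`` optionally maps attribute names to a number of decimal
    places; matching values are rendered at that printed precision (other
    values use ``repr``-style full precision).  Returns the CSV text when
    ``dest`` is None.
    """
    decimals = decimals or {}
    buf = io.StringIO()
    buf.write(",".join(DEFAULT_SCHEMA) + "\n")
    for m in table.measurements:
        if m.attribute in decimals:
            val = f"{m.value:.{decimals[m.attribute]}f}"
        else:
            val = repr(m.value)
        buf.write(f"{m.product},{m.lot_id},{m.attribute},{val},{m.unit}\n")
    text = buf.getvalue()
    if dest is None:
        return text
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        dest.write(text)
    return None


def round_lot_table(
    table: LotTable, decimals: Mapping[str, int]
) -> LotTable:
    """Copy of ``table`` with values rounded to per-attribute precision."""
    rounded = [
        replace(m, value=round(m.value, decimals[m.attribute]))
        if m.attribute in decimals
        else m
        for m in table.measurements
    ]
    return LotTable(measurements=rounded, provenance=table.provenance)


def read_attribute_definitions(
    source: str | IO[str],
) -> list[AttributeDefinition]:
    """Read attribute metadata from CSV mirroring AttributeDefinition fields.

    Boolean flag columns accept 1/0, true/false, yes/no (case-insensitive);
    absent columns default to False/0/"".
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "attribute" not in df.columns:
        raise SchemaError("missing required column 'attribute'")

    def flag(row: pd.Series, col: str) -> bool:
        if col not in row.index or not str(row[col]).strip():
            return False
        token = str(row[col]).strip().lower()
        if token in {"1", "true", "yes", "y"}:
            return True
        if token in {"0", "false", "no", "n"}:
            return False
        raise RowParseError(f"column {col!r}: cannot parse flag {row[col]!r}")

    def score(row: pd.Series, col: str) -> int:
        if col not in row.index or not str(row[col]).strip():
            return 0
        return int(float(row[col]))

    defs = []
    for _, row in df.iterrows():
        defs.append(
            AttributeDefinition(
                attribute=row["attribute"].strip(),
                impact=score(row, "impact"),
                uncertainty=score(row, "uncertainty"),
                assay=row["assay"].strip() if "assay" in row.index else "",
                moa_direct=flag(row, "moa_direct"),
                quantitative=flag(row, "quantitative"),
                qualitative_assay=flag(row, "qualitative_assay"),
                trace_analyte=flag(row, "trace_analyte"),
                one_sided=flag(row, "one_sided"),
                unit=row["unit"].strip() if "unit" in row.index else "",
            )
        )
    return defs
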