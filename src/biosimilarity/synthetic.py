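"""Seeded synthetic lot-data generator.

Emulates the data structure the similarity pipeline consumes: a small
number of manufactured lots per product, each measured once per quality
attribute, with batch-to-batch variation modelled as independent normal
(or, for impurity-style attributes, lognormal) draws around a per-product
true mean.  Attributes are generated independently — real glycoform
fractions co-vary (they sum within a profile), which this generator does
not attempt to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lots import LotMeasurement, LotTable

_PREFIX = {"test": "T", "reference": "R"}


@dataclass(frozen=True)
class AttributeSpec:
    """Generating parameters for one (product, attribute) cell."""

    attribute: str
    product: str
    mean: float
    sd: float
    n: int
    distribution: str = "normal"
    unit: str = "%"
    decimals: int | None = None  # printed precision for CSV output

    def __post_init__(self) -> None:
        if self.product not in _PREFIX:
            raise ValueError(f"product must be test|reference, got {self.product!r}")
        if self.sd < 0:
            raise ValueError(f"{self.attribute!r}: sd must be >= 0")
        if self.n < 1:
            raise ValueError(f"{self.attribute!r}: n must be >= 1")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass(frozen=True)
class GenerationSpec:
    entries: tuple[AttributeSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [(e.product, e.attribute) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (product, attribute) entries")

    def decimals_map(self) -> dict[str, int]:
        """Per-attribute printed precision, for CSV rendering."""
        return {
            e.attribute: e.decimals
            for e in self.entries
            if e.decimals is not None
        }


def generate_lots(spec: GenerationSpec) -> LotTable:
    """Draw a :class:`LotTable` from a generation spec.

    Lot ids are deterministic (``T01``, ``T02``, … / ``R01``, …) and shared
    across attributes within a product, mirroring a design where every lot
    is assayed on the full attribute panel.  Each (product, attribute)
    cell draws from its own seed substream, so adding or reordering
    entries does not perturb the draws of the others.  ``sd = 0`` yields
    lots exactly equal to the mean.
    """
    measurements: list[LotMeasurement] = []
    for e in spec.entries:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [spec.seed, _entry_key(e.product, e.attribute)]
            )
        )
        if e.sd == 0.0:
            values = np.full(e.n, e.mean, dtype=float)
        elif e.distribution == "normal":
            values = rng.normal(e.mean, e.sd, size=e.n)
        else:
            s2 = np.log1p((e.sd / e.mean) ** 2)
            values = rng.lognormal(np.log(e.mean) - s2 / 2.0, np.sqrt(s2), size=e.n)
        prefix = _PREFIX[e.product]
        for i, v in enumerate(values, start=1):
            measurements.append(
                LotMeasurement(
                    product=e.product,
                    lot_id=f"{prefix}{i:02d}",
                    attribute=e.attribute,
                    value=float(v),
                    unit=e.unit,
                )
            )
    return LotTable(
        measurements=measurements,
        provenance=f"synthetic draw, seed={spec.seed}",
    )


def _entry_key(product: str, attribute: str) -> int:
    # stable 31-bit substream key per (product, attribute)
    import hashlib

    digest = hashlib.blake2b(
        f"{product}\x00{attribute}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "little") & 0x7FFFFFFF


def spec_from_mean_range(
    attribute: str,
    product: str,
    mean: float,
    lo: float,
    hi: float,
    n: int,
    unit: str = "%",
    decimals: int | None = None,
) -> AttributeSpec:
    """Build an entry from a published ``mean (min–max)`` summary.

    The SD is reconstructed as (max − min)/4: the range of roughly 6–10
    normal draws spans about 3–4 SDs, so range/4 is a serviceable — and
    clearly approximate — plug-in when only the range is printed.
    """
    if not lo <= mean <= hi:
        raise ValueError(f"{attribute!r}: mean must lie within [lo, hi]")
    return AttributeSpec(
        attribute=attribute,
        product=product,
        mean=mean,
        sd=(hi - lo) / 4.0,
        n=n,
        unit=unit,
        decimals=decimals,
    )
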