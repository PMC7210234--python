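"""Run configuration: one JSON document covering every tunable constant.

Precedence is CLI flag > config file > built-in default; the effective
configuration is echoed into logs and report headers so that any run can
be reproduced from its artefacts alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import IO, Any, Mapping

from .criticality import (
    DEFAULT_IMPACT_SCALE,
    DEFAULT_UNCERTAINTY_SCALE,
    RiskConfig,
)
from .similarity import SimilarityConfig


@dataclass
class RunConfig:
    """Procedure constants, risk scales, and run-level settings."""

    k1: float = 1.5
    k2: float = 3.0
    alpha: float = 0.05
    pass_fraction: float = 0.9
    variance_mode: str = "welch"
    impact_scale: tuple[int, ...] = DEFAULT_IMPACT_SCALE
    uncertainty_scale: tuple[int, ...] = DEFAULT_UNCERTAINTY_SCALE
    cqa_cutoff: float = 16.0
    rank_cutpoints: tuple[float, float] = (16.0, 48.0)
    mandatory_cqa: tuple[str, ...] = ()
    tier_overrides: dict[str, int] = field(default_factory=dict)
    # overrides are keyed "attribute|assay" in JSON for portability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("multipliers k1 and k2 must be > 0")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if not 0.0 < self.pass_fraction <= 1.0:
            raise ValueError("pass_fraction must lie in (0, 1]")

    # -- views onto the per-module configs -----------------------------
    def similarity_config(self) -> SimilarityConfig:
        return SimilarityConfig(
            k1=self.k1,
            k2=self.k2,
            alpha=self.alpha,
            pass_fraction=self.pass_fraction,
            variance_mode=self.variance_mode,
        )

    def risk_config(self) -> RiskConfig:
        overrides = {
            tuple(key.split("|", 1)): tier
            for key, tier in self.tier_overrides.items()
        }
        return RiskConfig(
            impact_scale=tuple(self.impact_scale),
            uncertainty_scale=tuple(self.uncertainty_scale),
            cqa_cutoff=self.cqa_cutoff,
            rank_cutpoints=tuple(self.rank_cutpoints),
            mandatory_cqa=frozenset(self.mandatory_cqa),
            tier_overrides=overrides,  # type: ignore[arg-type]
        )

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["impact_scale"] = list(self.impact_scale)
        d["uncertainty_scale"] = list(self.uncertainty_scale)
        d["rank_cutpoints"] = list(self.rank_cutpoints)
        d["mandatory_cqa"] = list(self.mandatory_cqa)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        kwargs: dict[str, Any] = dict(data)
        for key in ("impact_scale", "uncertainty_scale", "rank_cutpoints",
                    "mandatory_cqa"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, source: str | IO[str]) -> "RunConfig":
        if isinstance(source, str):
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        else:
            data = json.load(source)
        return cls.from_dict(data)

    def to_json(self, dest: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if dest is not None:
            with open(dest, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text
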