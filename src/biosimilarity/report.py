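"""Rendering of similarity reports as CSV and markdown.

Both formats carry identical decision content; the CSV embeds the
effective configuration as ``#``-prefixed comment lines, the markdown as
a bulleted header block, so every report is auditable on its own.
Summary cells use the ``mean (min–max)`` display convention of lot
comparison tables, e.g. ``2.5 (2.2–2.9)``.
"""

from __future__ import annotations

import io
from typing import Mapping

import pandas as pd

from .similarity import (
    DescriptiveComparison,
    EquivalenceResult,
    QualityRangeResult,
    SimilarityReport,
)

COLUMNS = [
    "attribute", "assay", "risk_rank", "tier", "annotation", "decision",
    "mean_diff", "ci_low", "ci_high", "margin",
    "qr_low", "qr_high", "n_inside", "n_test", "fraction_inside",
    "range_overlap", "test_summary", "ref_summary",
]

_ANNOTATION_MARK = {"none": "", "star": "*", "hash": "#"}


class FormatError(ValueError):
    """Unknown report output format."""


def tier_label(tier: int, annotation: str) -> str:
    """Human-facing tier label, e.g. ``3*`` for qualitative tier-3 rows."""
    return f"{tier}{_ANNOTATION_MARK.get(annotation, '')}"


def report_frame(
    report: SimilarityReport,
    risk_ranks: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Flatten a similarity report into a tidy one-row-per-readout frame."""
    risk_ranks = risk_ranks or {}
    records = []
    for row in report.rows:
        rec: dict[str, object] = {c: "" for c in COLUMNS}
        rec.update(
            attribute=row.attribute,
            assay=row.assay,
            risk_rank=risk_ranks.get((row.attribute, row.assay), ""),
            tier=row.tier,
            annotation=row.annotation,
            decision=row.decision,
        )
        res = row.result
        if isinstance(res, EquivalenceResult):
            rec.update(
                mean_diff=round(res.mean_diff, 6),
                ci_low=round(res.ci_low, 6),
                ci_high=round(res.ci_high, 6),
                margin=round(res.margin, 6),
            )
        elif isinstance(res, QualityRangeResult):
            rec.update(
                qr_low=round(res.qr_low, 6),
                qr_high=round(res.qr_high, 6),
                n_inside=res.n_inside,
                n_test=res.n_test,
                fraction_inside=round(res.fraction_inside, 6),
            )
        elif isinstance(res, DescriptiveComparison):
            rec.update(
                range_overlap=round(res.range_overlap, 6),
                test_summary=res.test_summary.format_mean_range(),
                ref_summary=res.ref_summary.format_mean_range(),
            )
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=COLUMNS)


def _config_lines(report: SimilarityReport) -> list[str]:
    cfg = report.config
    return [
        f"k1: {cfg.k1}",
        f"k2: {cfg.k2}",
        f"alpha: {cfg.alpha}",
        f"pass_fraction: {cfg.pass_fraction}",
        f"variance_mode: {cfg.variance_mode}",
        f"rows: {len(report.rows)} (pass/similar {report.n_pass}, "
        f"fail {report.n_fail}, flagged {report.n_flagged}, "
        f"not evaluated {report.n_not_evaluated})",
    ]


def render_report(
    report: SimilarityReport,
    fmt: str = "csv",
    risk_ranks: Mapping[tuple[str, str], str] | None = None,
) -> str:
    """Render a similarity report; ``fmt`` is ``"csv"`` or ``"markdown"``."""
    frame = report_frame(report, risk_ranks)
    if fmt == "csv":
        buf = io.StringIO()
        for line in _config_lines(report):
            buf.write(f"# {line}\n")
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "markdown":
        lines = ["# Analytical similarity report", ""]
        lines += [f"- {line}" for line in _config_lines(report)]
        lines.append("")
        header = COLUMNS
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "|".join(" --- " for _ in header) + "|")
        for _, row in frame.iterrows():
            lines.append(
                "| " + " | ".join(str(row[c]) for c in header) + " |"
            )
        lines.append("")
        return "\n".join(lines)
    raise FormatError(f"unknown report format {fmt!r}; use csv or markdown")


def parse_report_csv(text: str) -> pd.DataFrame:
    """Read back a rendered CSV report (comment header ignored)."""
    return pd.read_csv(
        io.StringIO(text), comment="#", dtype=str, keep_default_na=False
    )


def parse_report_markdown(text: str) -> pd.DataFrame:
    """Read back a rendered markdown report's table."""
    rows = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.startswith("|"):
            continue
        cells = [c.strip() for c in line.strip("|").split("|")]
        if header is None:
            header = [c for c in cells]
        elif set("".join(cells)) <= {"-", " ", ""}:
            continue
        else:
            rows.append(cells)
    if header is None:
        return pd.DataFrame(columns=COLUMNS)
    return pd.DataFrame(rows, columns=header)
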