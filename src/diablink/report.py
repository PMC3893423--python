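"""Plain-text and CSV rendering of validation results.

The text report mirrors the layout of a published validation table: the 2x2
counts, a separate "uncertain" row, and the five agreement statistics —
percentages to one decimal place, kappa to two.  A machine-readable CSV of
all statistics (raw proportions, not rounded) is written alongside.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .agreement import TypeCrosstab, ValidationResult


def fmt_pct(value: float) -> str:
    return "undefined" if math.isnan(value) else f"{100 * value:.1f}%"


def fmt_kappa(value: float) -> str:
    return "undefined" if math.isnan(value) else f"{value:.2f}"


def _render_block(result: ValidationResult) -> str:
    t = result.table
    rows = [
        ("self-report diabetes", t.tp, t.fp, t.tp + t.fp),
        ("self-report non-diabetes", t.fn, t.tn, t.fn + t.tn),
        ("total", t.tp + t.fn, t.fp + t.tn, t.total),
        ("uncertain*", *result.uncertain_row, sum(result.uncertain_row)),
    ]
    lines = [f"== {result.label} ==", ""]
    header = f"{'':28s}{'criterion +':>14s}{'criterion -':>14s}{'total':>12s}"
    lines.append(header)
    for name, pos, neg, total in rows:
        lines.append(f"{name:28s}{pos:>14,d}{neg:>14,d}{total:>12,d}")
    s = result.stats
    lines.append("")
    lines.append(
        f"sensitivity {fmt_pct(s.sensitivity)}  specificity {fmt_pct(s.specificity)}  "
        f"PPV {fmt_pct(s.ppv)}  NPV {fmt_pct(s.npv)}  kappa {fmt_kappa(s.kappa)}"
    )
    lines.append("* uncertain-status participants are excluded from the statistics")
    return "\n".join(lines)


def _render_crosstab(crosstab: TypeCrosstab) -> str:
    lines = ["== algorithm diabetes type vs hospital-coded type ==", ""]
    cols = list(crosstab.counts.columns)
    header = f"{'algorithm type':20s}" + "".join(f"{c:>20s}" for c in cols) + f"{'row agreement':>16s}"
    lines.append(header)
    agreement = crosstab.row_agreement
    for row in crosstab.counts.index:
        cells = "".join(f"{int(crosstab.counts.at[row, c]):>20,d}" for c in cols)
        lines.append(f"{row:20s}" + cells + f"{fmt_pct(agreement[row]):>16s}")
    return "\n".join(lines)


def render_report(
    results: list[ValidationResult], crosstab: TypeCrosstab | None = None
) -> str:
    blocks = [_render_block(r) for r in results]
    if crosstab is not None:
        blocks.append(_render_crosstab(crosstab))
    return "\n\n".join(blocks) + "\n"


def write_report(
    results: list[ValidationResult],
    path: str | Path,
    crosstab: TypeCrosstab | None = None,
) -> None:
    """Write the plain-text report; raises on an unwritable path."""
    if not results:
        raise ValueError("write_report requires at least one validation result")
    Path(path).write_text(render_report(results, crosstab), encoding="utf-8")


def stats_frame(results: list[ValidationResult]) -> pd.DataFrame:
    records = []
    for r in results:
        row = {
            "source": r.source,
            "tp": r.table.tp,
            "fp": r.table.fp,
            "fn": r.table.fn,
            "tn": r.table.tn,
            "uncertain_positive": r.uncertain_row[0],
            "uncertain_negative": r.uncertain_row[1],
        }
        row.update(r.stats.as_dict())
        records.append(row)
    return pd.DataFrame.from_records(records)


def write_stats_csv(results: list[ValidationResult], path: str | Path) -> None:
    stats_frame(results).to_csv(path, index=False)
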