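"""Aggregate a resolved dietary pattern into weekly and per-capita-day WFs.

The aggregation is a mass-weighted sum: each category contributes
``(production g/week / 1000) × WF/kg`` componentwise, and the pattern total
is the sum over categories. Derived views are per-capita/day values
(weekly / 7), green/blue/grey component shares, and the contribution of
food groups (or the animal/plant/other partition) to the total.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import WFVector, ZERO_WF, round_half_away, wf_scale, wf_sum
from .pattern import DietEntry, DietaryPattern


class ReportError(ValueError):
    """Raised for degenerate report requests (e.g. shares of a zero total)."""


@dataclass(frozen=True)
class WFReport:
    """Per-entry and aggregate weekly WF of one dietary pattern.

    Fractions are stored at full precision; rounding happens only at
    rendering time.
    """

    pattern_name: str
    per_entry: tuple[tuple[str, WFVector], ...]
    weekly_total: WFVector
    per_capita_day: WFVector
    component_shares: tuple[float, float, float]
    group_contributions: Mapping[str, float]

    def entry_weekly(self, category: str) -> WFVector:
        for cat, v in self.per_entry:
            if cat == category:
                return v
        raise KeyError(category)


def entry_weekly_wf(e: DietEntry) -> WFVector:
    """Weekly WF of one entry: production mass (kg/week) times WF/kg."""
    return wf_scale(e.wf_per_kg, e.g_per_week_production / 1000.0)


def per_capita_day(weekly: WFVector) -> WFVector:
    """Convert a weekly WF to a per-capita/day WF."""
    return wf_scale(weekly, 1.0 / 7.0)


def component_shares(weekly_total: WFVector) -> tuple[float, float, float]:
    """Green/blue/grey fractions of the total WF; sums to 1."""
    t = weekly_total.total
    if t <= 0:
        raise ReportError("component shares undefined for a zero total WF")
    return (weekly_total.green / t, weekly_total.blue / t, weekly_total.grey / t)


def group_contribution(
    entries: Sequence[tuple[str, WFVector]],
    partition: Mapping[str, str],
) -> dict[str, float]:
    """Fraction of the weekly total attributable to each group.

    ``partition`` maps every entry category to a group label; fractions sum
    to 1 over the partition. An uncovered entry is an error: a silently
    dropped category would deflate every other group's share.
    """
    uncovered = [cat for cat, _ in entries if cat not in partition]
    if uncovered:
        raise ReportError(f"partition does not cover entries: {uncovered}")
    total = sum(v.total for _, v in entries)
    if total <= 0:
        raise ReportError("group contributions undefined for a zero total WF")
    out: dict[str, float] = {}
    for cat, v in entries:
        out[partition[cat]] = out.get(partition[cat], 0.0) + v.total / total
    return out


def pattern_weekly_wf(
    p: DietaryPattern,
    partition: Optional[Mapping[str, str]] = None,
) -> WFReport:
    """Compute the full WF report of a pattern.

    By default the contribution partition is each entry's
    animal/plant/other classification; pass ``partition`` to group
    categories differently (e.g. by guideline food group).
    """
    per_entry = tuple((e.category, entry_weekly_wf(e)) for e in p.entries)
    weekly = wf_sum([v for _, v in per_entry])
    part = partition if partition is not None else {e.category: e.classification for e in p.entries}
    return WFReport(
        pattern_name=p.name,
        per_entry=per_entry,
        weekly_total=weekly,
        per_capita_day=per_capita_day(weekly),
        component_shares=component_shares(weekly) if weekly.total > 0 else (0.0, 0.0, 0.0),
        group_contributions=group_contribution(per_entry, part) if weekly.total > 0 else {},
    )


TABLE_COLUMNS = [
    "category",
    "serving_g_edible",
    "servings_per_week",
    "g_per_week",
    "wf_green_l_per_kg",
    "wf_blue_l_per_kg",
    "wf_grey_l_per_kg",
    "wf_total_l_per_kg",
    "weekly_green_l",
    "weekly_blue_l",
    "weekly_grey_l",
    "weekly_total_l",
]


def render_table(p: DietaryPattern, report: Optional[WFReport] = None) -> str:
    """Render a pattern as CSV in the standard report layout.

    Columns: serving size, servings/week, production g/week, per-kg WF
    (green/blue/grey/total) and weekly WF (green/blue/grey/total), plus a
    Total row. Masses and WF cells are rendered as integers
    (half-away-from-zero); servings keep one decimal.
    """
    if report is None:
        report = pattern_weekly_wf(p)
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(TABLE_COLUMNS)
    for e in p.entries:
        weekly = report.entry_weekly(e.category)
        w.writerow(
            [
                e.category,
                round_half_away(e.serving_size_g_edible),
                f"{e.servings_per_week:g}",
                round_half_away(e.g_per_week_production),
                round_half_away(e.wf_per_kg.green),
                round_half_away(e.wf_per_kg.blue),
                round_half_away(e.wf_per_kg.grey),
                round_half_away(e.wf_per_kg.total),
                round_half_away(weekly.green),
                round_half_away(weekly.blue),
                round_half_away(weekly.grey),
                round_half_away(weekly.total),
            ]
        )
    t = report.weekly_total
    w.writerow(
        ["Total", "", "", "", "", "", "", "",
         round_half_away(t.green), round_half_away(t.blue), round_half_away(t.grey),
         round_half_away(t.total)]
    )
    return buf.getvalue()


def parse_table(text: str) -> tuple[tuple[tuple[str, WFVector], ...], WFVector]:
    """Parse a render_table CSV back into (per-entry weekly WFs, total).

    Inverse of :func:`render_table` up to the integer rounding of cells.
    """
    reader = csv.reader(_io.StringIO(text))
    header = next(reader)
    if header != TABLE_COLUMNS:
        raise ReportError(f"unexpected table header: {header}")
    entries: list[tuple[str, WFVector]] = []
    total = ZERO_WF
    for row in reader:
        vec = WFVector(float(row[8]), float(row[9]), float(row[10]))
        if row[0] == "Total":
            total = vec
        else:
            entries.append((row[0], vec))
    return tuple(entries), total


def render_empty_table() -> str:
    """Header plus a zero Total row, for patterns with nothing to report."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(TABLE_COLUMNS)
    w.writerow(["Total", "", "", "", "", "", "", "", 0, 0, 0, 0])
    return buf.getvalue()
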