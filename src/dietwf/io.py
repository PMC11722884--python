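"""Readers and writers for the package's CSV / JSON / YAML interchange formats.

CSV is the interchange format for tabular data (food databases, reports);
YAML or JSON for pattern specifications. All numeric I/O is
locale-independent; thousands separators in published tables are handled
only by the packaged fixture loader and never emitted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .model import Conversions, FoodRecord, ValidationError, WFVector
from .pipeline import WFReport

FOOD_DB_COLUMNS = [
    "name",
    "green_l_per_kg",
    "blue_l_per_kg",
    "grey_l_per_kg",
    "edible_fraction",
    "kcal_per_100g",
    "protein_per_100g",
]


class FormatError(ValueError):
    """Raised for malformed input files, with line context where possible."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and constants for one CLI run."""

    foods_path: Optional[Path] = None
    pattern_path: Optional[Path] = None
    composition_path: Optional[Path] = None
    out_path: Optional[Path] = None
    target_kcal_per_day: Optional[float] = None
    conversions: Conversions = field(default_factory=Conversions)
    log_level: str = "INFO"


def read_food_db(path: Union[str, Path]) -> list[FoodRecord]:
    """Read a food WF database CSV into validated records.

    Required columns: name, green/blue/grey L per kg; optional:
    edible_fraction (default 1), kcal_per_100g, protein_per_100g,
    aquaculture_fraction (empty = unknown/not applicable). Malformed rows
    are reported with their line number.
    """
    df = pd.read_csv(path)
    missing = [c for c in FOOD_DB_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                FoodRecord(
                    name=str(row["name"]),
                    wf_per_kg=WFVector(
                        float(row["green_l_per_kg"]),
                        float(row["blue_l_per_kg"]),
                        float(row["grey_l_per_kg"]),
                    ),
                    edible_fraction=_opt(row, "edible_fraction", 1.0),
                    kcal_per_100g=_opt(row, "kcal_per_100g"),
                    protein_per_100g=_opt(row, "protein_per_100g"),
                    aquaculture_fraction=_opt(row, "aquaculture_fraction"),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from None
    return records


def _opt(row, key, default=None):
    if key not in row or pd.isna(row[key]):
        return default
    return float(row[key])


def write_food_db(path: Union[str, Path], foods: list[FoodRecord]) -> None:
    rows = []
    for f in foods:
        rows.append(
            {
                "name": f.name,
                "green_l_per_kg": f.wf_per_kg.green,
                "blue_l_per_kg": f.wf_per_kg.blue,
                "grey_l_per_kg": f.wf_per_kg.grey,
                "edible_fraction": f.edible_fraction,
                "kcal_per_100g": f.kcal_per_100g,
                "protein_per_100g": f.protein_per_100g,
                "aquaculture_fraction": f.aquaculture_fraction,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pattern_spec(path: Union[str, Path]) -> dict:
    """Read and validate a pattern specification (YAML or JSON).

    Returns the raw spec dict consumed by :func:`dietwf.pattern.build_pattern`.
    Each entry needs a category, a serving size, and either servings_per_week
    or a servings_per_day_min/max range.
    """
    path = Path(path)
    text = path.read_text()
    spec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(spec, dict) or "entries" not in spec:
        raise FormatError(f"{path}: pattern spec must be a mapping with an 'entries' list")
    seen = set()
    for e in spec["entries"]:
        cat = e.get("category")
        if not cat:
            raise FormatError(f"{path}: entry without a category")
        if cat in seen:
            raise FormatError(f"{path}: duplicate category {cat!r}")
        seen.add(cat)
        if "serving_g_edible" not in e:
            raise FormatError(f"{path}: entry {cat!r} lacks serving_g_edible")
        has_week = "servings_per_week" in e
        has_range = "servings_per_day_min" in e and "servings_per_day_max" in e
        if not (has_week or has_range):
            raise FormatError(
                f"{path}: entry {cat!r} needs servings_per_week or a servings_per_day range"
            )
    return spec


def write_pattern_spec(path: Union[str, Path], spec: dict) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec, indent=2))
    else:
        path.write_text(yaml.safe_dump(spec, sort_keys=False))


def read_composition(path: Union[str, Path]) -> dict[str, float]:
    """CSV with columns category,kcal_per_100g -> lookup mapping."""
    df = pd.read_csv(path)
    for col in ("category", "kcal_per_100g"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df["category"].astype(str), df["kcal_per_100g"].astype(float)))


def write_composition(path: Union[str, Path], comp: Mapping[str, float]) -> None:
    pd.DataFrame(
        {"category": list(comp.keys()), "kcal_per_100g": list(comp.values())}
    ).to_csv(path, index=False)


def report_to_dict(r: WFReport) -> dict:
    """Full-precision JSON-serialisable view of a report."""
    return {
        "pattern": r.pattern_name,
        "per_entry": [
            {"category": cat, "green": v.green, "blue": v.blue, "grey": v.grey, "total": v.total}
            for cat, v in r.per_entry
        ],
        "weekly_total": {
            "green": r.weekly_total.green,
            "blue": r.weekly_total.blue,
            "grey": r.weekly_total.grey,
            "total": r.weekly_total.total,
        },
        "per_capita_day": {
            "green": r.per_capita_day.green,
            "blue": r.per_capita_day.blue,
            "grey": r.per_capita_day.grey,
            "total": r.per_capita_day.total,
        },
        "component_shares": {
            "green": r.component_shares[0],
            "blue": r.component_shares[1],
            "grey": r.component_shares[2],
        },
        "group_contributions": dict(sorted(r.group_contributions.items())),
    }


def write_report_json(path: Union[str, Path], r: WFReport) -> None:
    Path(path).write_text(json.dumps(report_to_dict(r), indent=2, sort_keys=True) + "\n")
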