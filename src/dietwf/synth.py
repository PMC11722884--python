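"""Synthetic food databases and dietary patterns, plus the packaged fixtures.

The generator emulates the structural properties real food WF data shows:
per-kg totals are positive and strongly right-skewed (log-normal; tabulated
diet values span roughly 270 to 15,000 L/kg), and the green/blue/grey split
is dominated by green water (national diet mixes run ~75-80% green), which
a Dirichlet split with concentrations ~(7.7, 1.2, 1.1) reproduces in
expectation. Patterns draw serving sizes and weekly frequencies inside the
ranges national guidelines actually use.

The three packaged fixtures are the Italian, US and Spanish
guideline patterns with their published per-category WF values, shipped as
CSV so they can be inspected and diffed (see ``dietwf/data/``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import FoodRecord, ValidationError, WFVector
from .pattern import DietEntry, DietaryPattern

FIXTURE_NAMES = ("italy", "usa", "spain")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic generator.

    wf_log_mean/wf_log_sd parametrise the log-normal per-kg WF total
    (defaults give a median of ~1500 L/kg with a heavy right tail);
    component_dirichlet splits the total into green/blue/grey (defaults
    target a ~77/12/11 mix); ranges are uniform draws.
    """

    n_foods: int = 30
    n_categories: int = 12
    wf_log_mean: float = 7.3
    wf_log_sd: float = 1.0
    component_dirichlet: tuple[float, float, float] = (7.7, 1.2, 1.1)
    edible_fraction_range: tuple[float, float] = (0.6, 1.0)
    kcal_range: tuple[float, float] = (20.0, 900.0)
    protein_range: tuple[float, float] = (0.5, 30.0)
    serving_g_range: tuple[float, float] = (5.0, 250.0)
    servings_week_range: tuple[float, float] = (0.4, 24.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foods < 0 or self.n_categories < 0:
            raise ValidationError("counts must be >= 0")
        if self.wf_log_sd <= 0:
            raise ValidationError("wf_log_sd must be positive")
        if any(a <= 0 for a in self.component_dirichlet):
            raise ValidationError("Dirichlet concentrations must be positive")
        lo, hi = self.edible_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValidationError("edible_fraction_range must lie in (0, 1]")
        for name in ("kcal_range", "protein_range", "serving_g_range", "servings_week_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi):
                raise ValidationError(f"{name} must be a nonnegative (lo, hi) range")


def gen_food_db(cfg: SynthConfig) -> list[FoodRecord]:
    """Draw a reproducible synthetic food WF database."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_foods == 0:
        return []
    totals = rng.lognormal(cfg.wf_log_mean, cfg.wf_log_sd, size=cfg.n_foods)
    shares = rng.dirichlet(cfg.component_dirichlet, size=cfg.n_foods)
    edible = rng.uniform(*cfg.edible_fraction_range, size=cfg.n_foods)
    kcal = rng.uniform(*cfg.kcal_range, size=cfg.n_foods)
    protein = rng.uniform(*cfg.protein_range, size=cfg.n_foods)
    records = []
    for i in range(cfg.n_foods):
        g, b, gr = totals[i] * shares[i]
        records.append(
            FoodRecord(
                name=f"food_{i:03d}",
                wf_per_kg=WFVector(g, b, gr),
                edible_fraction=float(edible[i]),
                kcal_per_100g=float(kcal[i]),
                protein_per_100g=float(protein[i]),
            )
        )
    return records


def gen_pattern(
    cfg: SynthConfig, db: list[FoodRecord]
) -> tuple[DietaryPattern, dict]:
    """Draw a synthetic pattern over a food database.

    Returns the resolved pattern and a raw min/max spec dict (the format
    ``io.read_pattern_spec`` yields) whose per-day serving ranges bracket
    the resolved servings — for exercising min/max averaging and energy
    rescaling downstream.
    """
    if not db:
        raise ValidationError("gen_pattern needs a nonempty food database")
    rng = np.random.default_rng(cfg.seed + 1)
    n = min(cfg.n_categories, len(db))
    chosen = rng.choice(len(db), size=n, replace=False)
    classes = ("animal", "plant", "other")
    entries = []
    spec_entries = []
    for j, i in enumerate(chosen):
        food = db[int(i)]
        serving = float(rng.uniform(*cfg.serving_g_range))
        servings_week = float(rng.uniform(*cfg.servings_week_range))
        g_week = serving * servings_week / food.edible_fraction
        category = f"category_{j:02d}"
        entries.append(
            DietEntry(
                category=category,
                serving_size_g_edible=serving,
                servings_per_week=servings_week,
                g_per_week_production=g_week,
                wf_per_kg=food.wf_per_kg,
                classification=classes[int(rng.integers(0, 3))],
            )
        )
        per_day = servings_week / 7.0
        spec_entries.append(
            {
                "category": category,
                "food": food.name,
                "serving_g_edible": serving,
                "servings_per_day_min": per_day * 0.8,
                "servings_per_day_max": per_day * 1.2,
                "edible_fraction": food.edible_fraction,
                "classification": entries[-1].classification,
            }
        )
    pattern = DietaryPattern(name=f"synthetic_{cfg.seed}", entries=tuple(entries))
    spec = {
        "name": f"synthetic_{cfg.seed}_minmax",
        "target_kcal_per_day": 2000.0,
        "entries": spec_entries,
    }
    return pattern, spec


def gen_composition(p: DietaryPattern, db: list[FoodRecord], spec: Optional[dict] = None) -> dict[str, float]:
    """kcal/100 g lookup for a synthetic pattern, keyed by category."""
    by_name = {f.name: f for f in db}
    comp: dict[str, float] = {}
    if spec is not None:
        for e in spec["entries"]:
            comp[e["category"]] = by_name[e["food"]].kcal_per_100g
    else:
        for e, f in zip(p.entries, db):
            comp[e.category] = f.kcal_per_100g
    return comp


@dataclass(frozen=True)
class Fixture:
    """A packaged guideline pattern with its published WF bookkeeping.

    ``pattern`` carries effective per-kg WFs (weekly WF / weekly mass), so
    mass x WF/kg reproduces each published weekly cell exactly; ``foods``
    carries the published per-kg columns (for several group rows these are
    simple member means and deliberately differ from the effective values —
    see the ``flags`` notes); ``food_groups`` maps categories to the
    guideline food groups for contribution analyses.
    """

    name: str
    pattern: DietaryPattern
    foods: tuple[FoodRecord, ...]
    food_groups: Mapping[str, str]
    flags: Mapping[str, str] = field(default_factory=dict)

    @property
    def food_map(self) -> dict[str, FoodRecord]:
        return {f.name: f for f in self.foods}


def _reconciled_weekly(row: pd.Series) -> WFVector:
    """Published weekly components, rescaled to sum to the row-total cell.

    Published component cells are independently rounded integers whose sum
    can differ from the row's (less-rounded) total cell by ~1 L; anchoring
    on the total keeps pattern sums consistent with the published grand
    totals.
    """
    g, b, gr = float(row.weekly_green_l), float(row.weekly_blue_l), float(row.weekly_grey_l)
    s = g + b + gr
    total = float(row.weekly_total_l)
    if s <= 0:
        return WFVector(0.0, 0.0, 0.0)
    k = total / s
    return WFVector(g * k, b * k, gr * k)


def load_fixture(name: str) -> Fixture:
    """Load one of the packaged guideline patterns ("italy", "usa", "spain")."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    with resources.files("dietwf.data").joinpath(f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh)
    entries = []
    foods = []
    groups: dict[str, str] = {}
    flags: dict[str, str] = {}
    for _, row in df.iterrows():
        weekly = _reconciled_weekly(row)
        mass_kg = float(row.g_per_week) / 1000.0
        wf_eff = WFVector(weekly.green / mass_kg, weekly.blue / mass_kg, weekly.grey / mass_kg)
        edible = float(row.serving_g_edible) * float(row.servings_per_week)
        entries.append(
            DietEntry(
                category=row.category,
                serving_size_g_edible=float(row.serving_g_edible),
                servings_per_week=float(row.servings_per_week),
                g_per_week_production=float(row.g_per_week),
                wf_per_kg=wf_eff,
                classification=row.classification,
            )
        )
        foods.append(
            FoodRecord(
                name=row.category,
                wf_per_kg=WFVector(
                    float(row.green_l_per_kg), float(row.blue_l_per_kg), float(row.grey_l_per_kg)
                ),
                edible_fraction=min(1.0, edible / float(row.g_per_week)) if row.g_per_week else 1.0,
            )
        )
        groups[row.category] = row.food_group
        if isinstance(row.note, str) and row.note:
            flags[row.category] = row.note
    pattern = DietaryPattern(name=name, entries=tuple(entries), target_kcal_per_day=2000.0)
    return Fixture(
        name=name, pattern=pattern, foods=tuple(foods), food_groups=groups, flags=flags
    )
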