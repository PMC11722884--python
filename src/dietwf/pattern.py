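"""Build fully resolved dietary patterns from guideline-style specifications.

A food-based dietary guideline (FBDG) prescribes, per food group, a serving
size in grams of edible portion and a consumption frequency. Resolving such
a specification into something a water-footprint pipeline can aggregate
requires:

* converting edible weight to production weight (WF databases price the raw
  product; e.g. fruit with peel and stone),
* averaging member foods into a group WF/kg when the guideline names a
  group rather than a single food,
* for guidelines that give serving *ranges* (the Spanish ones), averaging a
  minimum and a maximum pattern and proportionally rescaling the servings
  to a target energy intake (2000 kcal/day) using a food-composition table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .model import (
    Conversions,
    DEFAULT_CONVERSIONS,
    FoodRecord,
    GroupWeighting,
    ValidationError,
    WFVector,
    effective_seafood_mass,
    group_wf,
)

CLASSIFICATIONS = ("animal", "plant", "other")

#: Default mapping from food-group identifiers to the animal/plant/other
#: partition used for contribution analyses. "other" covers discretionary
#: ("indulgence") items — sugar, jam, alcohol and calorie-limit allowances;
#: fats (including butter) ride with the plant-side oils group.
DEFAULT_TAXONOMY: Mapping[str, str] = {
    "meat": "animal",
    "red meat": "animal",
    "white meat": "animal",
    "processed meat": "animal",
    "poultry": "animal",
    "eggs": "animal",
    "meat and eggs": "animal",
    "meat, poultry, eggs": "animal",
    "seafood": "animal",
    "fish": "animal",
    "fish/seafood": "animal",
    "processed fish": "animal",
    "dairy": "animal",
    "milk": "animal",
    "milk/yoghurt": "animal",
    "cheese": "animal",
    "soft cheese": "animal",
    "hard cheese": "animal",
    "sugar": "other",
    "jam": "other",
    "alcohol": "other",
    "wine/beer": "other",
    "wine": "other",
    "beer": "other",
    "indulgence": "other",
    "limit on calories": "other",
    # plant side is listed explicitly: an unmapped category is an error,
    # never a silent default
    "fruit": "plant",
    "fresh fruit": "plant",
    "vegetables": "plant",
    "leafy vegetables": "plant",
    "other vegetables": "plant",
    "green vegetables": "plant",
    "red and orange vegetables": "plant",
    "starchy vegetables": "plant",
    "cereals": "plant",
    "cereals and potatoes": "plant",
    "grains": "plant",
    "whole grains": "plant",
    "refined grains": "plant",
    "bread": "plant",
    "pasta": "plant",
    "potatoes": "plant",
    "pulses": "plant",
    "dry pulses": "plant",
    "nuts": "plant",
    "soy products": "plant",
    # fats ride with the plant-side oils group, butter included
    "fats": "plant",
    "butter": "plant",
    "oils": "plant",
    "vegetable oil": "plant",
    "extra virgin olive oil": "plant",
}


class ClassificationError(KeyError):
    """Raised when a category has no animal/plant/other assignment."""


class PatternError(ValueError):
    """Raised for invalid or unresolvable pattern specifications."""


@dataclass(frozen=True)
class DietEntry:
    """One resolved food category of a dietary pattern.

    serving_size_g_edible and servings_per_week describe the guideline
    recommendation; g_per_week_production is the production-weight mass the
    WF is charged on (>= edible mass since edible_fraction <= 1);
    wf_per_kg is the resolved per-kg WF of the category.
    """

    category: str
    serving_size_g_edible: float
    servings_per_week: float
    g_per_week_production: float
    wf_per_kg: WFVector
    classification: str

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError("DietEntry.category must be non-empty")
        if self.servings_per_week < 0:
            raise ValidationError(f"servings_per_week must be >= 0 for {self.category}")
        if self.serving_size_g_edible < 0:
            raise ValidationError(f"serving_size_g_edible must be >= 0 for {self.category}")
        edible = self.serving_size_g_edible * self.servings_per_week
        # 0.01 g slack absorbs rounding of printed serving-size cells
        if self.g_per_week_production + 1e-2 < edible:
            raise ValidationError(
                f"{self.category}: production mass {self.g_per_week_production} g/week is "
                f"below edible mass {edible} g/week (edible_fraction cannot exceed 1)"
            )
        if self.classification not in CLASSIFICATIONS:
            raise ValidationError(
                f"{self.category}: classification must be one of {CLASSIFICATIONS}, "
                f"got {self.classification!r}"
            )


@dataclass(frozen=True)
class DietaryPattern:
    """A named, ordered collection of resolved diet entries."""

    name: str
    entries: tuple[DietEntry, ...]
    target_kcal_per_day: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        if not self.entries:
            raise ValidationError(f"pattern {self.name!r} must have at least one entry")
        cats = [e.category for e in self.entries]
        dupes = {c for c in cats if cats.count(c) > 1}
        if dupes:
            raise ValidationError(f"pattern {self.name!r} has duplicate categories: {sorted(dupes)}")

    def __iter__(self):
        return iter(self.entries)

    def entry(self, category: str) -> DietEntry:
        for e in self.entries:
            if e.category == category:
                return e
        raise KeyError(category)


def edible_to_production(mass_edible_g: float, edible_fraction: float) -> float:
    """Convert edible weight to the production weight the WF is priced on."""
    if not (0.0 < edible_fraction <= 1.0):
        raise ValidationError(f"edible_fraction must be in (0, 1], got {edible_fraction!r}")
    if mass_edible_g < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_edible_g!r}")
    return mass_edible_g / edible_fraction


def classify_entry(category: str, taxonomy: Mapping[str, str] = DEFAULT_TAXONOMY) -> str:
    """Assign a category to the animal/plant/other partition.

    Lookup is case-insensitive on the exact name, then on whether a mapped
    group name occurs as a prefix of the category (so "Limit on calories
    for other use (240 kcal/day)" resolves through "limit on calories").
    Unmapped categories raise — there is no silent default, because a
    misclassified entry silently corrupts every contribution fraction.
    """
    key = category.strip().lower()
    if key in taxonomy:
        cls = taxonomy[key]
    else:
        matches = [v for k, v in taxonomy.items() if key.startswith(k)]
        if not matches:
            raise ClassificationError(f"category {category!r} not in taxonomy")
        cls = matches[0]
    if cls not in CLASSIFICATIONS:
        raise ValidationError(f"taxonomy maps {category!r} to invalid class {cls!r}")
    return cls


def average_min_max(spec_min: DietaryPattern, spec_max: DietaryPattern) -> DietaryPattern:
    """Average two serving-frequency variants of the same pattern.

    Used for guidelines that recommend serving ranges: a pattern built from
    the range minima and one from the maxima are averaged category by
    category (arithmetic mean of servings/week, hence of masses).
    """
    cats_min = [e.category for e in spec_min.entries]
    cats_max = {e.category for e in spec_max.entries}
    if set(cats_min) != cats_max:
        raise PatternError(
            f"category mismatch: {sorted(set(cats_min) ^ cats_max)} not present in both patterns"
        )
    entries = []
    for e_min in spec_min.entries:
        e_max = spec_max.entry(e_min.category)
        entries.append(
            replace(
                e_min,
                servings_per_week=(e_min.servings_per_week + e_max.servings_per_week) / 2.0,
                g_per_week_production=(e_min.g_per_week_production + e_max.g_per_week_production)
                / 2.0,
            )
        )
    return replace(spec_min, entries=tuple(entries))


def pattern_energy(p: DietaryPattern, comp: Mapping[str, float]) -> float:
    """Daily energy intake of a pattern, in kcal/day.

    ``comp`` maps each category to kcal per 100 g of edible weight (serving
    sizes are edible weights, so the lookup is on the edible side).
    """
    total_kcal_week = 0.0
    for e in p.entries:
        if e.category not in comp:
            raise PatternError(f"no composition record for category {e.category!r}")
        total_kcal_week += e.serving_size_g_edible * e.servings_per_week * comp[e.category] / 100.0
    return total_kcal_week / 7.0


def rescale_to_energy(
    p: DietaryPattern, comp: Mapping[str, float], target_kcal_per_day: float
) -> DietaryPattern:
    """Proportionally adjust servings/week so the pattern meets a target energy.

    Every entry is scaled by the same factor (serving *ratios* between
    entries are preserved exactly), so the pattern's food composition is
    unchanged — only its overall quantity.
    """
    current = pattern_energy(p, comp)
    if current <= 0:
        raise PatternError(f"pattern {p.name!r} has zero energy; cannot rescale")
    k = target_kcal_per_day / current
    entries = tuple(
        replace(
            e,
            servings_per_week=e.servings_per_week * k,
            g_per_week_production=e.g_per_week_production * k,
        )
        for e in p.entries
    )
    return replace(p, entries=entries, target_kcal_per_day=target_kcal_per_day)


# ---------------------------------------------------------------------------
# Resolution of raw guideline specs into DietaryPattern objects


def resolve_entry(
    category: str,
    serving_g_edible: float,
    servings_per_week: float,
    members: Sequence[tuple[FoodRecord, float]],
    weighting: GroupWeighting = GroupWeighting(),
    edible_fraction: Optional[float] = None,
    classification: Optional[str] = None,
    taxonomy: Mapping[str, str] = DEFAULT_TAXONOMY,
    is_seafood: bool = False,
    conversions: Conversions = DEFAULT_CONVERSIONS,
) -> DietEntry:
    """Resolve one guideline line into a DietEntry.

    ``members`` are the foods the group WF is averaged over (a single food
    for single-food categories). The edible fraction defaults to the
    simple mean of member fractions. Seafood categories charge only the
    aquaculture share of consumed mass.
    """
    wf = group_wf(members, weighting)
    if edible_fraction is None:
        edible_fraction = sum(f.edible_fraction for (f, _w) in members) / len(members)
    # Seafood: the wild-caught share carries 0 L/kg, so only the farmed
    # share of the recommended serving is charged; the entry then books the
    # charged serving so its mass arithmetic stays internally consistent.
    serving_g_charged = (
        effective_seafood_mass(serving_g_edible, conversions.aquaculture_fraction)
        if is_seafood
        else serving_g_edible
    )
    g_production = edible_to_production(serving_g_charged * servings_per_week, edible_fraction)
    cls = classification if classification is not None else classify_entry(category, taxonomy)
    return DietEntry(
        category=category,
        serving_size_g_edible=serving_g_charged,
        servings_per_week=servings_per_week,
        g_per_week_production=g_production,
        wf_per_kg=wf,
        classification=cls,
    )


def build_pattern(
    spec: Mapping,
    foods: Mapping[str, FoodRecord],
    *,
    composition: Optional[Mapping[str, float]] = None,
    conversions: Conversions = DEFAULT_CONVERSIONS,
    taxonomy: Mapping[str, str] = DEFAULT_TAXONOMY,
) -> DietaryPattern:
    """Build a DietaryPattern from a parsed spec dict (see io.read_pattern_spec).

    Entries giving ``servings_per_day_min``/``servings_per_day_max`` route
    through min/max averaging; if the spec carries ``target_kcal_per_day``
    and a composition table is available, the result is proportionally
    rescaled to that energy.
    """
    name = spec.get("name", "pattern")
    target = spec.get("target_kcal_per_day")
    raw_entries = spec.get("entries", [])
    if not raw_entries:
        raise PatternError(f"pattern spec {name!r} has no entries")

    has_range = any("servings_per_day_min" in e for e in raw_entries)

    def _resolve(servings_key) -> DietaryPattern:
        entries = []
        for e in raw_entries:
            member_names = e.get("members") or [e.get("food", e["category"])]
            try:
                records = [foods[m] for m in member_names]
            except KeyError as exc:
                raise PatternError(
                    f"entry {e['category']!r} references unknown food {exc.args[0]!r}"
                ) from None
            weighting = GroupWeighting(
                mode=e.get("weighting", "simple_mean"),
                weights=tuple(e["weights"]) if e.get("weights") else None,
            )
            default_weights = [
                w if w is not None else 1.0
                for w in (e.get("weights") or [1.0] * len(records))
            ]
            servings = servings_key(e)
            entries.append(
                resolve_entry(
                    category=e["category"],
                    serving_g_edible=float(e["serving_g_edible"]),
                    servings_per_week=float(servings),
                    members=list(zip(records, default_weights)),
                    weighting=weighting,
                    edible_fraction=e.get("edible_fraction"),
                    classification=e.get("classification"),
                    taxonomy=taxonomy,
                    is_seafood=bool(e.get("is_seafood", False)),
                    conversions=conversions,
                )
            )
        return DietaryPattern(name=name, entries=tuple(entries), target_kcal_per_day=target)

    if has_range:
        p_min = _resolve(lambda e: 7.0 * float(e.get("servings_per_day_min", 0.0)))
        p_max = _resolve(lambda e: 7.0 * float(e.get("servings_per_day_max", 0.0)))
        pattern = average_min_max(p_min, p_max)
    else:
        pattern = _resolve(lambda e: float(e["servings_per_week"]))

    if target is not None and composition is not None:
        pattern = rescale_to_energy(pattern, composition, float(target))
    return pattern
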