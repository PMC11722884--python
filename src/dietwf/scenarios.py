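"""Food-substitution scenarios: what does swapping food A for food B save?

Deltas follow the savings sign convention: a positive component means
water *saved* by the swap (the removed food used more than the added one).
Three constraints are supported:

* equal_mass — replace a given consumed mass of A with the same mass of B;
* equal_protein — replace the mass of A that provides the same protein as
  the added mass of B (protein densities from the food records);
* explicit — remove and add arbitrary masses.

Seafood passes through the aquaculture-mass rule automatically: a food
record with ``aquaculture_fraction`` set charges only the farmed share of
the swapped mass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .model import (
    FoodRecord,
    SignedWFDelta,
    ValidationError,
    WFVector,
    ZERO_WF,
    effective_seafood_mass,
    wf_scale,
)
from .pattern import ClassificationError, DietaryPattern, DietEntry, classify_entry


class ScenarioError(ValueError):
    """Raised for infeasible swaps (missing data, insufficient mass)."""


def _charged_kg(food: FoodRecord, mass_g: float) -> float:
    """Consumed mass (g) -> production mass (kg) charged against WF/kg."""
    if food.aquaculture_fraction is not None:
        mass_g = effective_seafood_mass(mass_g, food.aquaculture_fraction)
    return mass_g / food.edible_fraction / 1000.0


def delta_equal_mass(remove: FoodRecord, add: FoodRecord, mass_g: float) -> SignedWFDelta:
    """WF saved per week by replacing ``mass_g`` of one food with another."""
    if mass_g < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_g!r}")
    a = wf_scale(remove.wf_per_kg, _charged_kg(remove, mass_g))
    b = wf_scale(add.wf_per_kg, _charged_kg(add, mass_g))
    return a - b


def delta_equal_protein(remove: FoodRecord, add: FoodRecord, mass_add_g: float) -> SignedWFDelta:
    """WF saved by an iso-protein swap: add ``mass_add_g`` of one food and
    remove the mass of the other that carries the same protein."""
    if mass_add_g < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_add_g!r}")
    for f in (remove, add):
        if not f.protein_per_100g or f.protein_per_100g <= 0:
            raise ScenarioError(f"equal-protein swap needs protein_per_100g > 0 for {f.name!r}")
    mass_remove_g = mass_add_g * add.protein_per_100g / remove.protein_per_100g
    a = wf_scale(remove.wf_per_kg, _charged_kg(remove, mass_remove_g))
    b = wf_scale(add.wf_per_kg, _charged_kg(add, mass_add_g))
    return a - b


def weekly_delta(a: WFVector, b: WFVector) -> SignedWFDelta:
    """Difference of two weekly WFs (e.g. one country's oil entry vs another's)."""
    return a - b


@dataclass(frozen=True)
class Swap:
    """A single substitution applied to a pattern.

    Masses are production-weight g/week removed from / added to the named
    categories. ``add_category`` may be absent from the pattern if
    ``add_food`` supplies its WF; ``constraint`` records how the masses
    were derived and, for equal_mass / equal_protein, fills ``add_g`` /
    ``remove_g`` from the other side.
    """

    remove_category: str
    remove_g: float
    add_category: Optional[str] = None
    add_g: Optional[float] = None
    constraint: str = "explicit"
    add_food: Optional[FoodRecord] = None

    def __post_init__(self) -> None:
        if self.remove_g < 0 or (self.add_g is not None and self.add_g < 0):
            raise ValidationError("swap masses must be >= 0")
        if self.constraint not in ("explicit", "equal_mass", "equal_protein"):
            raise ValidationError(f"unknown swap constraint {self.constraint!r}")


def _scale_entry_mass(e: DietEntry, new_mass_g: float) -> DietEntry:
    k = new_mass_g / e.g_per_week_production if e.g_per_week_production > 0 else 0.0
    return replace(
        e,
        g_per_week_production=new_mass_g,
        servings_per_week=e.servings_per_week * k if e.g_per_week_production > 0 else 0.0,
    )


def apply_swap(
    p: DietaryPattern,
    s: Swap,
    foods: Optional[Mapping[str, FoodRecord]] = None,
) -> tuple[DietaryPattern, SignedWFDelta]:
    """Apply a swap to a pattern; return the new pattern and the WF saved.

    The new pattern's weekly total equals the old total minus the returned
    delta (exactly, by construction; verified against full recomputation in
    the test-suite). Entries not named in the swap are untouched.
    """
    try:
        rem = p.entry(s.remove_category)
    except KeyError:
        raise ScenarioError(f"pattern has no category {s.remove_category!r}") from None
    if s.remove_g > rem.g_per_week_production + 1e-9:
        raise ScenarioError(
            f"cannot remove {s.remove_g} g/week from {s.remove_category!r}: "
            f"only {rem.g_per_week_production} g/week present"
        )

    add_g = s.add_g
    if s.constraint == "equal_mass":
        add_g = s.remove_g
    elif s.constraint == "equal_protein":
        if foods is None:
            raise ScenarioError("equal_protein swaps need a food-record mapping")
        try:
            f_rem = foods[s.remove_category]
            f_add = foods[s.add_category]
        except KeyError as exc:
            raise ScenarioError(f"no food record for {exc.args[0]!r}") from None
        for f in (f_rem, f_add):
            if not f.protein_per_100g:
                raise ScenarioError(f"missing protein density for {f.name!r}")
        add_g = s.remove_g * f_rem.protein_per_100g / f_add.protein_per_100g

    entries = list(p.entries)
    idx = {e.category: i for i, e in enumerate(entries)}
    entries[idx[rem.category]] = _scale_entry_mass(rem, rem.g_per_week_production - s.remove_g)
    removed_wf = wf_scale(rem.wf_per_kg, s.remove_g / 1000.0)

    added_wf = None
    if s.add_category is not None and add_g is not None and add_g > 0:
        if s.add_category in idx:
            tgt = entries[idx[s.add_category]]
            entries[idx[s.add_category]] = _scale_entry_mass(
                tgt, tgt.g_per_week_production + add_g
            )
            added_wf = wf_scale(tgt.wf_per_kg, add_g / 1000.0)
        else:
            food = s.add_food if s.add_food is not None else (foods or {}).get(s.add_category)
            if food is None:
                raise ScenarioError(
                    f"category {s.add_category!r} not in pattern and no food record given"
                )
            try:
                cls = classify_entry(s.add_category)
            except ClassificationError:
                cls = "plant"
            entries.append(
                DietEntry(
                    category=s.add_category,
                    serving_size_g_edible=add_g * food.edible_fraction,  # one weekly serving
                    servings_per_week=1.0,
                    g_per_week_production=add_g,
                    wf_per_kg=food.wf_per_kg,
                    classification=cls,
                )
            )
            added_wf = wf_scale(food.wf_per_kg, add_g / 1000.0)

    delta = removed_wf - added_wf if added_wf is not None else removed_wf - ZERO_WF
    new_pattern = replace(p, entries=tuple(entries))
    return new_pattern, delta
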